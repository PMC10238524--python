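# Methods

This note records the models, parameter choices and numerical conventions
behind `mvmar`, and what the synthetic experiments do and do not demonstrate.

## Projection model

All methods share one parallel-beam projector: angles evenly spaced over
[0, π), detector bins covering the image diagonal (no truncation), linear
interpolation, rotation about the image center. Forward projection and
filtered back-projection delegate to scikit-image's `radon`/`iradon`
(`circle=False`); line integrals carry units of value·mm (pixel values times
path length in mm). HU slices are projected as-is: the correction only ever
interprets *differences* of projections, and the projector is linear with no
offset, so any affine recalibration of the HU scale cancels. The ramp filter
is the default; the other ramp-family windows (`shepp-logan`, `cosine`,
`hamming`, `hann`) are selectable.

Fan- or cone-beam geometry, scatter and detector cross-talk are out of scope;
the correction operates on sinogram supports and differences, which the
parallel geometry represents faithfully at desk scale.

## Correction engine

One pass composes: metal trace (support of the forward-projected kV metal
mask, at a relative threshold of 1e-6 of the trace peak to discard projector
interpolation dust) → in-trace difference between the kV and template
sinograms → boundary ramps → filtered back-projection of the smoothed
difference → Gaussian low-pass → subtraction from the original kV slice.

Numerical conventions that the algorithm's verbal description leaves open:

* **Boundary ramps.** The in-trace difference is ramped *linearly to zero*
  over Δ₁ = Δ₂ = 4 bins outside each trace run (the value one bin outside a
  run edge with Δ = 2 is half the edge value; at the outer extension edge it
  is zero). Where extension zones of adjacent runs overlap, contributions are
  summed and clipped to the larger boundary magnitude; ramps are truncated at
  the detector edge. Ramps never overwrite another run's interior.
* **High-frequency filtering (HFF).** Realized as a Gaussian low-pass on the
  reconstructed artifact image, default σ = 0.75 px. The width trades two
  errors: a wide kernel leaves the high-frequency streak component of the
  artifact in the corrected image (the artifact estimate no longer matches
  what it must cancel), a zero-width kernel prints trace-boundary and
  (on real data) registration noise into the correction. 0.75 px suppresses
  single-pixel boundary noise while letting streaks be subtracted; it is
  configurable (`MarConfig.hff_sigma_px`).
* **Back-projection choice.** The artifact reconstruction uses *filtered*
  back-projection: the artifact estimate must live in HU to be subtracted
  from the kV image.
* **Iteration semantics.** Tissue masks (MV-derived) and the metal mask
  (kV-derived) are computed once and held fixed. Each iteration rebuilds the
  template with M1 pixels from the *original* kV slice and fill means from
  the *latest corrected* image, then corrects the original kV slice. Only
  the fill means update: feeding corrected M1 pixels back would re-inject the
  previous iteration's subtraction noise, and re-segmenting the unchanged MV
  prior would be a no-op. Default 3 iterations.
* **Metal pixels** in the corrected image are restored to the original kV
  values, so implants stay visible for delineation. The method makes no
  claim about gray values inside metal.
* **Identities.** An empty metal mask yields an exact identity (the zero-
  trace path never touches the image); a template equal to the input also
  yields an exact identity (the in-trace difference vanishes).

The inputs are assumed co-registered; registration is out of scope (the
simulator produces perfectly co-registered pairs by construction).

## Segmentation

The MV prior is split into M1 (bone + metal), M2 (soft tissue) and M3
(cavities + air) with block-wise multi-threshold Otsu on 8×8-pixel blocks
(trailing partial blocks stand alone). Otsu thresholds maximize between-class
variance over a 256-bin histogram spanning the sample's range; the search is
exhaustive over ordered bin pairs, ties break toward the smallest pair, and
the returned threshold is the upper *edge* of the last class bin — for
separated clusters this places the cut in the empty gap between them rather
than inside a cluster's tail, which matters for the block logic below.

A block rarely contains all three classes, so each block is first compared
against the global image thresholds: a block whose range straddles neither
global boundary (or spans < 10 HU, or has < 3 distinct values) is classified
by the global thresholds; a block straddling one boundary gets a local
2-class Otsu split assigned to the two classes that boundary separates; only
blocks straddling both get the full local 3-class split. All decisions are
relative to data-derived thresholds, so the segmentation is invariant to
adding a constant to the image. Pixels of a supplied metal mask (from the
co-registered kV slice) are excluded from global threshold estimation — the
far-out metal cluster would otherwise capture the high threshold — and are
forced into M1 afterwards.

Metal is segmented in the kV slice at a default 2500 HU (above any bone),
with connected components under 4 px removed as reconstruction speckle.

## Baselines

LIMAR linearly interpolates the sinogram across each trace run between the
flanking bins; NMAR divides the sinogram by the projection of a 3-class prior
(air −1000 HU below −500 HU, bone kept above 300 HU, soft tissue 0 HU
elsewhere and over metal), interpolates in the normalized domain, and
multiplies back (denominator floored at 1e-3 of its peak). Both project
HU + 1000 so interpolation acts on nonnegative values — unlike a projection
difference, interpolation is not offset-invariant. Two implementation
choices follow the classical recipes rather than the shortest description:

* The NMAR prior is thresholded on an initial LIMAR-corrected image,
  median-filtered over 3 px: thresholding the raw kV slice classifies severe
  dark streaks as air and bright streaks as bone, and the corrupted prior
  makes NMAR worse than LIMAR — the opposite of its design intent.
* Both baselines are applied in delta form,
  `corrected = kv − BP(FP(kv + 1000) − inpainted)`, which is algebraically
  the same correction but does not print the projector's FP∘BP round-trip
  error (about 2% of the offset image, i.e. tens of HU) into the output. A
  scanner applying these methods to raw detector data has no such error; the
  delta form is the faithful desk-scale equivalent.

Both baselines are exact identities for an empty metal mask.

## Metrics

Per ROI: mean CT value; noise as the population SD of ROI pixels; MRE
`|mean_cor − mean_ref| / |mean_ref|` on the ROI means; NRMSD
`sqrt(Σ(cor−ref)² / Σref²)`; MAD `Σ|cor−ref| / N`. MRE is reported at two
decimals in formatted tables (full precision kept internally); noise uses the
population (not sample) SD. NRMSD over a low-|HU| soft-tissue ROI is poorly
conditioned (the reference energy is small), which is why the benchmark ROIs
are fixed and reported together with their pixel counts.

## Simulator

The simulator exists to generate co-registered (kV artifact-laden, MV
near-clean, monochromatic ground-truth) triples with the two artifact
mechanisms that matter — photon starvation and beam hardening — not to model
any particular scanner.

* **Physics.** Materials carry μ(E) tables (1/mm, log-log interpolated) on a
  40 keV–1.5 MeV grid, assembled from standard mass-attenuation data; spectra
  are discrete (six bins 40–120 keV for kV, soft-leaning weights; two
  Compton-region bins at 0.5/1 MeV for the 1.5 MV beam). Detected counts are
  `N0·Σ w(E)·exp(−∫μ(E)dl)` with Poisson noise (N0 = 1e5/bin default) and a
  clamp at 1 count before the log — the starvation mechanism. Measured
  attenuation is water-linearized (the correction every scanner applies), so
  residual artifacts come only from materials that depart from water: bone
  and metal. HU calibration is two-point (water 0, air −1000) at the
  spectrum's mean energy; a no-metal water phantom reconstructs to ~0.04 HU
  in water and −1000.2 HU in air. The ground truth is the noiseless
  monochromatic reconstruction at the same mean energy, so truth and scans
  share the projector's discretization and view-aliasing signature and
  comparisons isolate the artifact physics.
* **Dental phantom** (the multi-metal benchmark): head-sized soft-tissue
  ellipse (+40 HU), oral air cavity, a mandible arc of nine trabecular-bone
  disks (arc radius 55 mm), and three amalgam inserts (r = 3.25 mm) along the
  tooth row at radius 45 mm — anatomically the teeth sit lingual of the jaw
  line, and this also routes the inter-metal streak corridors through soft
  tissue where they can be measured. The `inter_metal` ROI (r = 6 px) sits in
  that corridor. Trabecular (not cortical) bone in the arc is the realistic
  choice for a mandible interior and keeps the information the interpolation
  baselines destroy at a plausible level.
* **Rod phantom** (single-metal fixture): water-equivalent cylinder with an
  air cavity (ROI B), a cortical-bone insert, and a removable titanium rod
  (r = 8 mm) with ROI A in nearby soft tissue. Titanium is deliberately the
  rod material: its artifacts are dominated by soft-path beam hardening,
  which a template-difference correction can capture. For extremely dense
  alloys the measured deficit is dominated by the metal body's own
  attenuation error, a component the template cancels by construction (M1
  copies the kV values), and no correction of this family can remove it —
  a genuine limitation, documented rather than hidden. Method comparisons on
  this fixture run noise-free because the single-rod method differences at
  the ROIs are smaller than the Poisson noise at the default dose.
* **What passing tests do not show.** The simulator has no scatter, no
  detector energy response, no focal-spot or motion blur, 2-D slices only,
  and perfect registration; MV gray values are cleaner than a real MV-CBCT's.
  Passing benchmarks demonstrate the algorithmic behavior (template
  differencing removes what interpolation loses; iteration de-biases the
  fill means; orderings among methods) under controlled artifact physics —
  not clinical performance.

## Study conditions and what they were chosen for

Simulation severity (spectrum softness, N0, insert sizes) was set once so
that all four methods are meaningfully separated: artifacts severe enough
that discarding in-trace data (the baselines) beats doing nothing, and
structured (hardening-dominated) enough that subtracting a template-predicted
artifact beats both. At these conditions the benchmark ordering
(proposed < NMAR < original and proposed < LIMAR < original on the
inter-metal ROI) and the monotone per-iteration improvement hold across ten
consecutive seeds, with M1 Dice ≈ 0.89 and full metal coverage; the fixed
test seed is not special.

## Known limitations

* Metal-body attenuation error is out of reach of the template difference
  (see the rod-phantom discussion); in-metal gray values are simply the
  original kV values.
* Fill means are global per region; strongly heterogeneous soft tissue
  (beyond noise and streaks) violates the piecewise-constant template
  assumption, as does any tissue class outside {air-like, soft, dense}.
* The boundary-ramp overlap rule (sum, clip to larger magnitude) is a
  pragmatic tie-break; pathological mask geometries with many interleaved
  runs have no principled treatment here.
* NRMSD values are large wherever the reference ROI mean is near zero HU;
  compare methods, not absolute values, in those regions.
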