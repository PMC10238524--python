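# mvmar

Metal artifact reduction (MAR) for kilovoltage CT slices using a megavoltage
cone-beam CT (MV-CBCT) prior, for radiotherapy imaging workflows where
patients carry multiple dental implants or dentures.

## The problem

Dense metal nearly extinguishes a diagnostic (kV) X-ray beam: detectors see
almost no photons behind an implant (photon starvation), and the photons that
do get through are preferentially high-energy (beam hardening). Both effects
make the measured projections inconsistent with any real object, and filtered
back-projection turns that inconsistency into bright/dark streaks and shading
that can make the mouth region of a head-and-neck CT undiagnosable — worst of
all when several implants interact. At megavoltage energies the metal/tissue
attenuation contrast collapses, so an MV-CBCT of the same anatomy is nearly
artifact-free, just with different (but tissue-ordered) gray values.

## The method

Given a co-registered slice pair — `I_CT` (kV, with artifacts) and an MV
prior — one correction pass is:

1. **Segment** the MV prior into high/medium/low-density masks `M1/M2/M3`
   by block-wise (8×8 px) multi-threshold Otsu (maximum between-class
   variance), and segment the metal `M_metal` in the kV slice by an HU
   threshold.
2. **Template** (the artifact-free surrogate): copy `I_CT` on `M1`, fill `M2`
   and `M3` with their regional means of `I_CT`:

       I_template(i,j) = I_CT(i,j)            (i,j) ∈ M1
                         mean(I_CT over M2)   (i,j) ∈ M2
                         mean(I_CT over M3)   (i,j) ∈ M3

3. **Difference in the metal trace**: with `FP` the forward projector,

       P_MetalDiff(θ,k) = FP(I_CT) − FP(I_template),   (θ,k) ∈ FP(M_metal) ≠ 0

   Outside the projected metal support the template and kV projections agree,
   so the in-trace difference is (mostly) the artifact signal.
4. **Smooth the trace boundary**: ramp `P_MetalDiff` linearly to zero over
   Δ = 4 bins outside each trace run, so the reconstruction of the difference
   does not create new streaks.
5. **Reconstruct and subtract**: `I_correct = I_CT − HFF[BP(P_interp)]`, where
   `BP` is filtered back-projection and `HFF` a Gaussian low-pass (σ = 0.75 px)
   that suppresses boundary/registration noise in the artifact estimate.
6. **Iterate** (default 3×): the fill means in step 2 are recomputed from the
   latest corrected image — the first template's means are biased by the very
   artifacts being removed, and iterating de-biases them. Every iteration
   subtracts from the *original* kV slice.

The package also ships the classical projection-interpolation baselines
(**LIMAR** — linear interpolation across the trace; **NMAR** — interpolation
of the prior-normalized sinogram), the standard fidelity metrics (ROI mean CT
value, noise as ROI SD, MRE, NRMSD, MAD), and a polychromatic dual-energy
phantom simulator (Beer–Lambert over a discrete spectrum, Poisson counting
noise, photon-starvation clamp, water linearization) so the entire pipeline
is testable without scanner data.

## Worked example

```python
import mvmar as m

geometry = m.ScanGeometry((256, 256), pixel_spacing=1.0, n_angles=180)
pair = m.simulate_scan_pair(m.dental_phantom(), m.default_kv_spectrum(),
                            m.default_mv_spectrum(), geometry, seed=1)

metal = m.segment_metal(pair.kv_image)           # kV threshold at 2500 HU
result = m.iterate_mar(pair.kv_image, pair.mv_image, geometry,
                       m.MarConfig(), metal=metal,
                       truth=pair.ground_truth_kv,
                       roi=m.dental_rois()["inter_metal"])

roi = m.dental_rois()["inter_metal"]
for name, img in {"original": pair.kv_image,
                  "limar": m.limar(pair.kv_image, metal, geometry),
                  "nmar": m.nmar(pair.kv_image, metal, geometry),
                  "proposed": result.corrected}.items():
    print(name, round(m.nrmsd(img, pair.ground_truth_kv, roi), 3))
print("per-iteration:", [round(v, 4) for v in
                         result.diagnostics["nrmsd_per_iteration"]])
```

prints

```
original 1.869
limar 1.402
nmar 1.381
proposed 0.959
per-iteration: [0.9665, 0.9599, 0.9592]
```

NRMSD is measured against the noise-free monochromatic ground truth over the
region between the metal inserts, where the mutually interacting streaks
live. The corrected slice cuts the artifact level there nearly in half, beats
both interpolation baselines (which pay for discarding all in-trace
projection data), and improves monotonically over the three iterations.

The same pipeline is available from the shell:

```bash
mvmar demo --outdir demo_out --seed 1      # simulate → correct ×3 → evaluate
mvmar simulate --phantom dental --outdir sim --seed 1
mvmar correct --kv sim/kv.npz --mv sim/mv.npz --out corrected.npz
mvmar evaluate --images proposed=corrected.npz --reference sim/truth.npz \
               --rois rois.yaml --out report
```

Every output carries a JSON provenance sidecar (config hash, seed, versions).

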