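"""The MV-CBCT-prior correction engine.

One correction pass:

1. forward-project the metal mask; its nonzero support is the *metal trace*;
2. inside the trace, take the difference between the kV sinogram and the
   template sinogram — with a good template this difference is (mostly) the
   artifact signal;
3. ramp the difference smoothly to zero over a few bins outside each trace
   run, so the subsequent reconstruction does not itself create new streaks;
4. filtered-back-project the smoothed difference, suppress its highest
   spatial frequencies (Gaussian low-pass), and subtract the resulting
   artifact image from the original kV slice.

The pass is iterated: tissue masks (from the MV prior) and the metal mask
(from kV) stay fixed, but the template fill means are recomputed from the
latest corrected image, so each iteration works with a less artifact-biased
template.  Every iteration subtracts from the *original* kV image — artifact
estimates are never compounded on already-corrected images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ValidationError
from .geometry import ScanGeometry, SliceImage, Sinogram, back_project_fbp, forward_project
from .segmentation import MetalMask, TissueMasks, blockwise_segment, segment_metal
from .template import TemplateImage, build_template

log = logging.getLogger(__name__)


@dataclass
class MetalTrace:
    """Sinogram support of the projected metal mask.

    ``runs[theta]`` lists the maximal contiguous bin runs ``(k_first, k_last)``
    (inclusive) of the trace at that angle, sorted by bin index.
    """

    mask: np.ndarray
    runs: list[list[tuple[int, int]]]

    @property
    def is_empty(self) -> bool:
        return not self.mask.any()


@dataclass
class MarConfig:
    """Tunable parameters of the correction engine."""

    iterations: int = 3
    delta_n1: int = 4            # boundary ramp extension, bins (leading edge)
    delta_n2: int = 4            # boundary ramp extension, bins (trailing edge)
    hff_sigma_px: float = 0.75   # Gaussian low-pass width of the HFF step
    metal_threshold_hu: float = 2500.0
    block_size: int = 8
    trace_epsilon_rel: float = 1e-6
    filter_name: str = "ramp"

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")
        if self.delta_n1 < 1 or self.delta_n2 < 1:
            raise ValidationError("boundary extensions must be >= 1 bin")


@dataclass
class CorrectionResult:
    """Output of the iterative correction."""

    corrected: SliceImage
    artifacts: list[SliceImage] = field(default_factory=list)
    templates: list[TemplateImage] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)


def _runs_of(row: np.ndarray) -> list[tuple[int, int]]:
    """Maximal contiguous True runs of a 1-D boolean array, as (first, last)."""
    idx = np.flatnonzero(row)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def metal_trace(metal: MetalMask, geometry: ScanGeometry,
                trace_epsilon_rel: float = 1e-6) -> MetalTrace:
    """Forward-project the metal mask and extract its sinogram support."""
    if metal.mask.shape != geometry.image_shape:
        raise ValidationError("metal mask shape does not match the geometry")
    proj = forward_project(metal.mask.astype(np.float64), geometry)
    peak = proj.values.max()
    if peak <= 0:
        mask = np.zeros(geometry.sinogram_shape, dtype=bool)
        return MetalTrace(mask, [[] for _ in range(geometry.n_angles)])
    mask = proj.values > trace_epsilon_rel * peak
    runs = [_runs_of(mask[t]) for t in range(mask.shape[0])]
    return MetalTrace(mask, runs)


def sinogram_difference(kv_sino: Sinogram, template_sino: Sinogram,
                        trace: MetalTrace) -> Sinogram:
    """kV-minus-template projection difference, restricted to the metal trace."""
    if kv_sino.shape != template_sino.shape:
        raise ValidationError("sinogram shapes disagree")
    diff = np.zeros_like(kv_sino.values)
    diff[trace.mask] = kv_sino.values[trace.mask] - template_sino.values[trace.mask]
    return Sinogram(diff, kv_sino.geometry)


def smooth_boundaries(diff: Sinogram, trace: MetalTrace,
                      delta_n1: int = 4, delta_n2: int = 4) -> Sinogram:
    """Ramp the trace-restricted difference smoothly to zero at run boundaries.

    In-run values are kept.  Outside each run the boundary value is ramped
    linearly to zero over ``delta_n1`` bins before the first bin and
    ``delta_n2`` bins after the last.  Where extension zones of adjacent runs
    overlap, contributions are summed and clipped to the larger boundary
    magnitude; ramps running off the detector edge are truncated.
    """
    if delta_n1 < 1 or delta_n2 < 1:
        raise ValidationError("boundary extensions must be >= 1 bin")
    n_angles, n_bins = diff.shape
    out = np.where(trace.mask, diff.values, 0.0)
    for theta in range(n_angles):
        runs = trace.runs[theta]
        if not runs:
            continue
        ramp = np.zeros(n_bins)
        overlap = np.zeros(n_bins, dtype=np.int8)
        magnitude = np.zeros(n_bins)
        in_run = trace.mask[theta]
        for k1, k2 in runs:
            for edge_value, k_edge, delta, direction in (
                    (diff.values[theta, k1], k1, delta_n1, -1),
                    (diff.values[theta, k2], k2, delta_n2, +1)):
                for step in range(1, delta + 1):
                    k = k_edge + direction * step
                    if k < 0 or k >= n_bins:
                        log.debug("ramp truncated at detector edge (angle %d)", theta)
                        break
                    if in_run[k]:
                        continue  # never overwrite another run's interior
                    ramp[k] += edge_value * (1.0 - step / delta)
                    overlap[k] += 1
                    magnitude[k] = max(magnitude[k], abs(edge_value))
        clash = overlap >= 2
        ramp[clash] = np.clip(ramp[clash], -magnitude[clash], magnitude[clash])
        out[theta] += ramp
    return Sinogram(out, diff.geometry)


def reconstruct_artifact(p_interp: Sinogram, geometry: ScanGeometry | None = None,
                         hff_sigma_px: float = 0.75,
                         filter_name: str = "ramp") -> SliceImage:
    """FBP of the smoothed difference followed by high-frequency suppression.

    The Gaussian low-pass (width ``hff_sigma_px`` pixels) removes the
    high-frequency noise that the trace boundaries and any registration
    residual would otherwise print into the artifact estimate.
    """
    geometry = p_interp.geometry if geometry is None else geometry
    recon = back_project_fbp(p_interp, geometry, filter_name=filter_name)
    smoothed = gaussian_filter(recon.values, hff_sigma_px) if hff_sigma_px > 0 else recon.values
    return SliceImage(smoothed, geometry.pixel_spacing, modality="artifact")


def correct_once(kv: SliceImage, template: TemplateImage, metal: MetalMask,
                 geometry: ScanGeometry, config: MarConfig | None = None,
                 kv_sino: Sinogram | None = None,
                 trace: MetalTrace | None = None) -> tuple[SliceImage, SliceImage]:
    """One correction pass; returns (corrected, artifact estimate).

    ``kv_sino`` and ``trace`` may be passed in to reuse work across
    iterations.  Pixels inside the metal mask are restored to the original kV
    values so the implants stay visible for delineation.
    """
    config = config or MarConfig()
    if kv.shape != template.image.shape or kv.shape != metal.mask.shape:
        raise ValidationError("kV, template and metal mask must be co-registered")
    if trace is None:
        trace = metal_trace(metal, geometry, config.trace_epsilon_rel)
    if kv_sino is None:
        kv_sino = forward_project(kv, geometry)
    template_sino = forward_project(template.image, geometry)
    diff = sinogram_difference(kv_sino, template_sino, trace)
    p_interp = smooth_boundaries(diff, trace, config.delta_n1, config.delta_n2)
    artifact = reconstruct_artifact(p_interp, geometry, config.hff_sigma_px,
                                    config.filter_name)
    corrected_values = kv.values - artifact.values
    corrected_values[metal.mask] = kv.values[metal.mask]
    corrected = SliceImage(corrected_values, kv.pixel_spacing, modality="corrected")
    return corrected, artifact


def iterate_mar(kv: SliceImage, mv: SliceImage, geometry: ScanGeometry,
                config: MarConfig | None = None,
                masks: TissueMasks | None = None,
                metal: MetalMask | None = None,
                truth: SliceImage | None = None,
                roi=None) -> CorrectionResult:
    """Full iterative correction of one co-registered kV/MV slice pair.

    Tissue masks come from the MV prior (computed once), the metal mask from
    the kV slice (fixed).  Each iteration rebuilds the template fill means
    from the current corrected image and applies :func:`correct_once` to the
    original kV slice.  When ``truth`` (and optionally ``roi``) are supplied,
    per-iteration NRMSD diagnostics are recorded.
    """
    config = config or MarConfig()
    if kv.shape != mv.shape:
        raise ValidationError("kV and MV slices must be co-registered (same shape)")
    if metal is None:
        metal = segment_metal(kv, config.metal_threshold_hu)
    if masks is None:
        masks = blockwise_segment(mv, config.block_size, metal_hint=metal)
    trace = metal_trace(metal, geometry, config.trace_epsilon_rel)
    if trace.is_empty:
        # nothing to correct: exact identity (the zero-trace path)
        result = CorrectionResult(corrected=kv.copy(modality="corrected"))
        result.diagnostics["iterations_run"] = 0
        return result
    kv_sino = forward_project(kv, geometry)

    result = CorrectionResult(corrected=kv.copy(modality="corrected"))
    nrmsd_per_iter: list[float] = []
    source = kv
    for it in range(1, config.iterations + 1):
        # M1 keeps the original kV values throughout; only the fill means
        # are refreshed from the latest corrected image
        template = build_template(kv, masks, iteration=it, mean_source=source)
        corrected, artifact = correct_once(kv, template, metal, geometry, config,
                                           kv_sino=kv_sino, trace=trace)
        result.templates.append(template)
        result.artifacts.append(artifact)
        result.corrected = corrected
        source = corrected
        if truth is not None:
            from .metrics import nrmsd  # local import avoids a cycle
            value = (nrmsd(corrected, truth, roi) if roi is not None
                     else float(np.sqrt(((corrected.values - truth.values) ** 2).sum()
                                        / (truth.values ** 2).sum())))
            nrmsd_per_iter.append(value)
    result.diagnostics["iterations_run"] = config.iterations
    if nrmsd_per_iter:
        result.diagnostics["nrmsd_per_iteration"] = nrmsd_per_iter
    return result
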