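"""Classical projection-interpolation MAR baselines: LIMAR and NMAR.

LIMAR replaces the sinogram inside each metal-trace run with a straight line
between the flanking bins.  NMAR first divides the sinogram by the projection
of a piecewise-constant prior built from the kV image itself, interpolates in
the normalized domain (where anatomy is nearly flat, so interpolation loses
less information), then multiplies the prior projection back.

Both operate on HU + 1000 so the projections are nonnegative — interpolation,
unlike a projection difference, is not offset-invariant, so the offset
convention matters and is fixed here.  Both are exact identities when the
metal mask is empty.

Numerically, both are applied in delta form: the correction reconstructs
only the (in-trace) difference between the original and the inpainted
sinogram and subtracts it from the input image.  This is algebraically the
same correction but avoids printing the forward-project/reconstruct
round-trip error of the full image into the output — an error a scanner
working from raw detector data never sees.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import median_filter

from .errors import ValidationError
from .geometry import ScanGeometry, SliceImage, Sinogram, back_project_fbp, forward_project
from .mar import MetalTrace, metal_trace
from .segmentation import MetalMask

HU_OFFSET = 1000.0


def _interpolate_runs(values: np.ndarray, trace: MetalTrace) -> np.ndarray:
    """Linearly bridge every trace run between its flanking bins, per angle.

    When a run touches the detector edge the nearest available outside value
    serves for that side (both sides missing -> 0).
    """
    out = values.copy()
    n_bins = values.shape[1]
    for theta, runs in enumerate(trace.runs):
        for k1, k2 in runs:
            left = k1 - 1
            right = k2 + 1
            v_left = values[theta, left] if left >= 0 else None
            v_right = values[theta, right] if right < n_bins else None
            if v_left is None and v_right is None:
                v_left = v_right = 0.0
                left, right = k1 - 1, k2 + 1
            elif v_left is None:
                v_left, left = v_right, k1 - 1
            elif v_right is None:
                v_right, right = v_left, k2 + 1
            k = np.arange(k1, k2 + 1)
            out[theta, k1:k2 + 1] = v_left + (v_right - v_left) * (k - left) / (right - left)
    return out


def limar(kv: SliceImage, metal: MetalMask, geometry: ScanGeometry,
          filter_name: str = "ramp") -> SliceImage:
    """Linear-interpolation MAR."""
    if kv.shape != metal.mask.shape:
        raise ValidationError("kV image and metal mask must be co-registered")
    trace = metal_trace(metal, geometry)
    if trace.is_empty:
        return kv.copy(modality="corrected")
    sino = forward_project(SliceImage(kv.values + HU_OFFSET, kv.pixel_spacing), geometry)
    filled = _interpolate_runs(sino.values, trace)
    delta = back_project_fbp(Sinogram(sino.values - filled, geometry), geometry, filter_name)
    corrected = kv.values - delta.values
    corrected[metal.mask] = kv.values[metal.mask]
    return SliceImage(corrected, kv.pixel_spacing, modality="corrected")


def nmar(kv: SliceImage, metal: MetalMask, geometry: ScanGeometry,
         air_threshold_hu: float = -500.0, bone_threshold_hu: float = 300.0,
         soft_tissue_hu: float = 0.0, denominator_floor_rel: float = 1e-3,
         prior_source: str = "limar", prior_median_px: int = 3,
         filter_name: str = "ramp") -> SliceImage:
    """Normalized MAR with a 3-class thresholded prior.

    Prior: air (< ``air_threshold_hu``) -> -1000 HU; bone
    (> ``bone_threshold_hu``) keeps its values; everything else (and all
    metal pixels) -> ``soft_tissue_hu``.  Following the classical recipe the
    prior is thresholded on an initial LIMAR-corrected image
    (``prior_source="limar"``), median-filtered over ``prior_median_px``
    pixels first — both steps keep residual streaks from being misclassified
    as air or bone.  ``prior_source="kv"`` thresholds the raw kV slice.
    """
    if kv.shape != metal.mask.shape:
        raise ValidationError("kV image and metal mask must be co-registered")
    if prior_source not in ("limar", "kv"):
        raise ValidationError(f"unknown prior_source {prior_source!r}")
    trace = metal_trace(metal, geometry)
    if trace.is_empty:
        return kv.copy(modality="corrected")
    base = limar(kv, metal, geometry, filter_name) if prior_source == "limar" else kv
    base_values = (median_filter(base.values, prior_median_px)
                   if prior_median_px > 1 else base.values)
    prior = np.full_like(base_values, soft_tissue_hu)
    prior[base_values < air_threshold_hu] = -1000.0
    bone = base_values > bone_threshold_hu
    prior[bone] = base_values[bone]
    prior[metal.mask] = soft_tissue_hu

    sino_kv = forward_project(SliceImage(kv.values + HU_OFFSET, kv.pixel_spacing),
                              geometry).values
    sino_prior = forward_project(SliceImage(prior + HU_OFFSET, kv.pixel_spacing),
                                 geometry).values
    floor = denominator_floor_rel * sino_prior.max()
    denom = np.maximum(sino_prior, floor)
    normalized = sino_kv / denom
    filled = _interpolate_runs(normalized, trace) * denom
    delta = back_project_fbp(Sinogram(sino_kv - filled, geometry), geometry, filter_name)
    corrected = kv.values - delta.values
    corrected[metal.mask] = kv.values[metal.mask]
    return SliceImage(corrected, kv.pixel_spacing, modality="corrected")
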