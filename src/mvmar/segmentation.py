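"""Tissue and metal segmentation.

The MV prior is split into three density classes by block-wise multi-threshold
Otsu (maximum between-class variance): M1 high density (bone + metal), M2
medium density (soft tissue), M3 low density (cavities + air).  Working in
8 x 8-pixel blocks makes the thresholds local, which is what lets the method
cope with the residual shading that multi-metal cases leave even at MV energy.

Blocks rarely contain all three tissue classes, so each block is first tested
against the *global* Otsu thresholds of the whole image: a block whose value
range straddles neither global class boundary is classified globally (this is
also the fallback for degenerate, near-constant blocks); a block straddling
one boundary gets a local 2-class split; only blocks straddling both get the
full 3-class split.  All decisions are relative to data-derived thresholds,
so the segmentation is invariant to adding a constant to the image.

Metal is segmented in the kV image by a plain HU threshold with small-island
removal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as _connected_components

from .errors import DegenerateInputError, ValidationError
from .geometry import SliceImage

OTSU_BINS = 256


@dataclass
class TissueMasks:
    """Disjoint masks covering the slice: m1 high, m2 medium, m3 low density."""

    m1: np.ndarray
    m2: np.ndarray
    m3: np.ndarray

    def __post_init__(self) -> None:
        total = self.m1.astype(int) + self.m2.astype(int) + self.m3.astype(int)
        if not np.all(total == 1):
            raise ValidationError("TissueMasks must be pairwise disjoint and cover every pixel")


@dataclass
class MetalMask:
    """Boolean metal mask plus the HU threshold that produced it."""

    mask: np.ndarray
    threshold_hu: float
    min_area_px: int = 4


def _histogram(values: np.ndarray, bins: int = OTSU_BINS):
    counts, edges = np.histogram(values, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts.astype(np.float64), centers, edges


def otsu_threshold(values: np.ndarray, bins: int = OTSU_BINS) -> float:
    """Single Otsu threshold (2-class maximum between-class variance).

    Ties break toward the smallest threshold.  Raises
    :class:`DegenerateInputError` with fewer than 2 distinct values.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if np.unique(values).size < 2:
        raise DegenerateInputError("need >= 2 distinct values for a 2-class split")
    counts, centers, edges = _histogram(values, bins)
    p = np.cumsum(counts)
    s = np.cumsum(counts * centers)
    total, total_s = p[-1], s[-1]
    w1 = p[:-1]
    w2 = total - w1
    with np.errstate(invalid="ignore", divide="ignore"):
        mu1 = np.where(w1 > 0, s[:-1] / w1, 0.0)
        mu2 = np.where(w2 > 0, (total_s - s[:-1]) / w2, 0.0)
    var_b = w1 * w2 * (mu1 - mu2) ** 2
    # the class boundary is the upper edge of the last class-1 bin, which for
    # well-separated data falls in the empty gap between clusters
    return float(edges[int(np.argmax(var_b)) + 1])


def otsu_two_thresholds(values: np.ndarray, bins: int = OTSU_BINS) -> tuple[float, float]:
    """Threshold pair maximizing between-class variance over a 3-class split.

    Exhaustive search over all ordered histogram-bin pairs (vectorized);
    among ties the lexicographically smallest (t_low, t_high) wins, making
    the output deterministic.  Raises :class:`DegenerateInputError` with
    fewer than 3 distinct values.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if not np.all(np.isfinite(values)):
        raise ValidationError("cannot threshold non-finite values")
    if np.unique(values).size < 3:
        raise DegenerateInputError("need >= 3 distinct values for a 3-class split")
    counts, centers, edges = _histogram(values, bins)
    p = np.concatenate([[0.0], np.cumsum(counts)])          # p[i] = sum counts[:i]
    s = np.concatenate([[0.0], np.cumsum(counts * centers)])
    total, total_s = p[-1], s[-1]
    mean = total_s / total

    i = np.arange(1, bins)  # t_low candidate = centers[i-1] (classes split after bin i-1)
    j = np.arange(1, bins)
    # class sums for every (i, j): w1 = p[i], w2 = p[j]-p[i], w3 = total-p[j]
    w1 = p[i][:, None]
    s1 = s[i][:, None]
    w2 = p[j][None, :] - w1
    s2 = s[j][None, :] - s1
    w3 = total - p[j][None, :]
    s3 = total_s - s[j][None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        var_b = (np.where(w1 > 0, (s1 - w1 * mean) ** 2 / w1, 0.0)
                 + np.where(w2 > 0, (s2 - w2 * mean) ** 2 / w2, 0.0)
                 + np.where(w3 > 0, (s3 - w3 * mean) ** 2 / w3, 0.0))
    var_b[np.tril_indices(bins - 1, k=0)] = -np.inf  # require i < j (t_low < t_high)
    flat = int(np.argmax(var_b))  # row-major argmax = lexicographically smallest tie
    ii, jj = divmod(flat, bins - 1)
    return float(edges[ii + 1]), float(edges[jj + 1])


def _classify(values: np.ndarray, t_low: float, t_high: float) -> np.ndarray:
    """Labels 1 (low), 2 (medium), 3 (high) from a threshold pair."""
    labels = np.full(values.shape, 2, dtype=np.int8)
    labels[values <= t_low] = 1
    labels[values > t_high] = 3
    return labels


def blockwise_segment(mv_image: SliceImage, block: int = 8,
                      metal_hint: MetalMask | None = None,
                      degenerate_range_hu: float = 10.0) -> TissueMasks:
    """Block-wise multi-threshold Otsu segmentation of the MV prior.

    Splits the image into ``block`` x ``block`` pixel blocks (trailing partial
    blocks stand alone), thresholds each block locally as described in the
    module docstring, and splices the per-block labels into one mask set.
    ``metal_hint`` pixels (from the co-registered kV metal mask) are forced
    into M1.
    """
    if block < 2:
        raise ValidationError("block size must be >= 2")
    values = mv_image.values
    # Metal pixels are known a priori (kV threshold segmentation) and are
    # forced into M1 below; excluding them from threshold estimation keeps
    # the global 3-class split aligned with air | soft tissue | bone instead
    # of being captured by the far-out metal cluster.
    estimation = values[~metal_hint.mask] if metal_hint is not None else values.ravel()
    try:
        g_low, g_high = otsu_two_thresholds(estimation)
        global_ok = True
    except DegenerateInputError:
        global_ok = False

    labels = np.full(values.shape, 2, dtype=np.int8)
    if global_ok:
        rows, cols = values.shape
        for r0 in range(0, rows, block):
            for c0 in range(0, cols, block):
                sub = values[r0:r0 + block, c0:c0 + block]
                lo, hi = float(sub.min()), float(sub.max())
                straddles_low = lo < g_low < hi
                straddles_high = lo < g_high < hi
                sub_labels = None
                if hi - lo >= degenerate_range_hu and (straddles_low or straddles_high):
                    try:
                        if straddles_low and straddles_high:
                            t1, t2 = otsu_two_thresholds(sub)
                            sub_labels = _classify(sub, t1, t2)
                        elif straddles_low:
                            t = otsu_threshold(sub)
                            sub_labels = np.where(sub <= t, 1, 2).astype(np.int8)
                        else:
                            t = otsu_threshold(sub)
                            sub_labels = np.where(sub > t, 3, 2).astype(np.int8)
                    except DegenerateInputError:
                        sub_labels = None
                if sub_labels is None:  # single-tissue or degenerate block
                    sub_labels = _classify(sub, g_low, g_high)
                labels[r0:r0 + block, c0:c0 + block] = sub_labels

    if metal_hint is not None:
        labels[metal_hint.mask] = 3
    return TissueMasks(m1=labels == 3, m2=labels == 2, m3=labels == 1)


def segment_metal(kv_image: SliceImage, threshold_hu: float = 2500.0,
                  min_area_px: int = 4) -> MetalMask:
    """Threshold segmentation of metal in the kV image.

    Pixels at or above ``threshold_hu`` (which must sit above the bone range)
    form the mask; connected components smaller than ``min_area_px`` pixels
    are removed as reconstruction speckle.
    """
    mask = kv_image.values >= threshold_hu
    if min_area_px > 1 and mask.any():
        components = _connected_components(mask, connectivity=2)
        areas = np.bincount(components.ravel())
        mask = mask & (areas[components] >= min_area_px)
    return MetalMask(mask=mask, threshold_hu=threshold_hu, min_area_px=min_area_px)
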