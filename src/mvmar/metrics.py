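"""Image-quality metrics and the benchmark report.

Per ROI: mean CT value (HU), noise as the population SD of ROI pixels,
MRE = |mean_cor - mean_ref| / |mean_ref| (mean relative error of the ROI
means), NRMSD = sqrt(sum (cor - ref)^2 / sum ref^2), and MAD = mean absolute
pixelwise deviation.  ``benchmark_report`` tabulates all of them for a set of
corrected images against a reference, in the layout used for method
comparisons (methods as columns, metrics x ROIs as rows).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError, ValidationError
from .geometry import SliceImage


@dataclass(frozen=True)
class Roi:
    """Circular or rectangular region of interest, pixel coordinates.

    ``center_px`` is (row, col).  For rectangles ``center_px`` is the corner
    (top-left) and ``size_px`` the (height, width).
    """

    kind: str  # "circle" | "rectangle"
    center_px: tuple[int, int]
    radius_px: int = 0
    size_px: tuple[int, int] = (0, 0)
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("circle", "rectangle"):
            raise ValidationError(f"unknown ROI kind {self.kind!r}")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rows, cols = shape
        r0, c0 = self.center_px
        if self.kind == "circle":
            if not (self.radius_px <= r0 < rows - self.radius_px
                    and self.radius_px <= c0 < cols - self.radius_px):
                raise ValidationError(f"ROI {self.label!r} extends outside the image")
            rr, cc = np.ogrid[:rows, :cols]
            mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= self.radius_px ** 2
        else:
            h, w = self.size_px
            if not (0 <= r0 and r0 + h <= rows and 0 <= c0 and c0 + w <= cols):
                raise ValidationError(f"ROI {self.label!r} extends outside the image")
            mask = np.zeros(shape, dtype=bool)
            mask[r0:r0 + h, c0:c0 + w] = True
        if mask.sum() < 4:
            raise ValidationError(f"ROI {self.label!r} must contain at least 4 pixels")
        return mask


def roi_mean_and_noise(img: SliceImage, roi: Roi) -> tuple[float, float]:
    """Arithmetic mean and population SD of the ROI pixels."""
    pixels = img.values[roi.mask(img.shape)]
    return float(pixels.mean()), float(pixels.std(ddof=0))


def mre(mean_cor: float, mean_ref: float) -> float:
    """Mean relative error of ROI means: |mean_cor - mean_ref| / |mean_ref|."""
    if mean_ref == 0:
        raise UndefinedMetricError("MRE undefined for a zero reference mean")
    return abs(mean_cor - mean_ref) / abs(mean_ref)


def nrmsd(cor: SliceImage, ref: SliceImage, roi: Roi) -> float:
    """Normalized root-mean-square deviation over the ROI."""
    if cor.shape != ref.shape:
        raise ValidationError("image shapes disagree")
    mask = roi.mask(cor.shape)
    ref_energy = float((ref.values[mask] ** 2).sum())
    if ref_energy == 0:
        raise UndefinedMetricError("NRMSD undefined for a zero-energy reference ROI")
    return float(np.sqrt(((cor.values[mask] - ref.values[mask]) ** 2).sum() / ref_energy))


def mad(cor: SliceImage, ref: SliceImage, roi: Roi) -> float:
    """Mean absolute pixelwise deviation over the ROI, HU."""
    if cor.shape != ref.shape:
        raise ValidationError("image shapes disagree")
    mask = roi.mask(cor.shape)
    return float(np.abs(cor.values[mask] - ref.values[mask]).mean())


_FORMATS = {"ct_value_hu": "{:.1f}", "noise_hu": "{:.1f}", "mre": "{:.2f}",
            "nrmsd": "{:.4f}", "mad_hu": "{:.2f}"}


@dataclass
class MetricsReport:
    """Benchmark metric grid plus the reference ROI statistics."""

    table: pd.DataFrame           # full precision, MultiIndex (roi, metric) x method
    reference_stats: dict         # roi label -> {"mean": ..., "noise": ...}

    def formatted(self) -> pd.DataFrame:
        """Report-precision view (CT/noise 1 dp, MRE 2 dp)."""
        rows = {idx: [_FORMATS[idx[1]].format(v) for v in self.table.loc[idx]]
                for idx in self.table.index}
        out = pd.DataFrame.from_dict(rows, orient="index", columns=self.table.columns)
        out.index = pd.MultiIndex.from_tuples(out.index, names=["roi", "metric"])
        return out

    def to_csv(self, path: str | Path) -> None:
        self.formatted().to_csv(path)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "metrics": {f"{roi}/{metric}": dict(self.table.loc[(roi, metric)])
                        for (roi, metric) in self.table.index},
            "reference": self.reference_stats,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def benchmark_report(methods: dict[str, SliceImage], reference: SliceImage,
                     rois: list[Roi]) -> MetricsReport:
    """Full metric grid of every method image against the reference."""
    for name, img in methods.items():
        if img.shape != reference.shape:
            raise ValidationError(f"method {name!r} image shape disagrees with reference")
    ref_stats = {}
    rows = {}
    for roi in rois:
        ref_mean, ref_noise = roi_mean_and_noise(reference, roi)
        ref_stats[roi.label] = {"mean": ref_mean, "noise": ref_noise}
        for metric in _FORMATS:
            rows[(roi.label, metric)] = {}
        for name, img in methods.items():
            mean, noise = roi_mean_and_noise(img, roi)
            rows[(roi.label, "ct_value_hu")][name] = mean
            rows[(roi.label, "noise_hu")][name] = noise
            rows[(roi.label, "mre")][name] = mre(mean, ref_mean)
            rows[(roi.label, "nrmsd")][name] = nrmsd(img, reference, roi)
            rows[(roi.label, "mad_hu")][name] = mad(img, reference, roi)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index = pd.MultiIndex.from_tuples(table.index, names=["roi", "metric"])
    return MetricsReport(table, ref_stats)
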