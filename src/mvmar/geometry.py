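"""Parallel-beam projection geometry shared by the MAR core, baselines and simulator.

The forward projector computes discrete line integrals (Radon transform) of a
2-D slice; the reconstruction operator is standard filtered back-projection
(ramp-family filters).  Both delegate to scikit-image's ``radon``/``iradon``
with the padding convention ``circle=False``, so the detector always covers
the full image diagonal and nothing is truncated.

Conventions
-----------
* Angles are radians, evenly spaced over the half circle ``[0, pi)``.
* Sinograms are stored as ``(n_angles, n_bins)`` arrays.
* Pixel values are projected as-is (the MAR pipeline projects HU directly;
  only differences of projections are ever interpreted physically, so any
  affine offset cancels).  Line integrals carry units of value x mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import iradon, radon

from .errors import ConfigurationError, GeometryError, ValidationError

#: Filter names accepted by :func:`back_project_fbp` (the ramp family).
FBP_FILTERS = ("ramp", "shepp-logan", "cosine", "hamming", "hann")


def _diagonal_bins(n: int) -> int:
    """Detector bin count for an n x n image under skimage's circle=False padding."""
    diagonal = math.sqrt(2.0) * n
    return n + int(math.ceil(diagonal - n))


@dataclass(frozen=True)
class ScanGeometry:
    """Parallel-beam acquisition geometry.

    Parameters
    ----------
    image_shape : (rows, cols), must be square.
    pixel_spacing : mm per pixel (isotropic).
    n_angles : number of projection angles over ``[0, pi)``.
    """

    image_shape: tuple[int, int]
    pixel_spacing: float = 1.0
    n_angles: int = 180

    def __post_init__(self) -> None:
        rows, cols = self.image_shape
        if rows != cols or rows < 2:
            raise GeometryError(f"image_shape must be square and >= 2, got {self.image_shape}")
        if self.n_angles < 1:
            raise GeometryError("n_angles must be >= 1")
        if not (self.pixel_spacing > 0):
            raise GeometryError("pixel_spacing must be positive")

    @property
    def angles(self) -> np.ndarray:
        """Projection angles in radians, strictly increasing over [0, pi)."""
        return np.linspace(0.0, np.pi, self.n_angles, endpoint=False)

    @property
    def angles_deg(self) -> np.ndarray:
        return np.rad2deg(self.angles)

    @property
    def n_bins(self) -> int:
        """Detector bins; >= image diagonal so the support is never truncated."""
        return _diagonal_bins(self.image_shape[0])

    @property
    def bin_spacing(self) -> float:
        """Detector sampling pitch, mm (equals the pixel pitch for this projector)."""
        return self.pixel_spacing

    @property
    def sinogram_shape(self) -> tuple[int, int]:
        return (self.n_angles, self.n_bins)


@dataclass
class SliceImage:
    """A 2-D CT slice: HU (or attenuation) values plus pixel spacing."""

    values: np.ndarray
    pixel_spacing: float = 1.0
    modality: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("SliceImage requires a 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("SliceImage values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self, *, modality: str | None = None) -> "SliceImage":
        return SliceImage(self.values.copy(), self.pixel_spacing,
                          self.modality if modality is None else modality)


@dataclass
class Sinogram:
    """Line integrals on an (angle, detector-bin) grid, units value x mm."""

    values: np.ndarray
    geometry: ScanGeometry = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.geometry.sinogram_shape:
            raise GeometryError(
                f"sinogram shape {self.values.shape} does not match geometry "
                f"{self.geometry.sinogram_shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("Sinogram values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "Sinogram":
        return Sinogram(self.values.copy(), self.geometry)


def forward_project(image: SliceImage | np.ndarray, geometry: ScanGeometry) -> Sinogram:
    """Discrete line integrals of ``image`` under ``geometry``.

    The projector is linear in the pixel values and adds no offset, so
    projection differences are offset-free.  Output units: value x mm.
    """
    values = image.values if isinstance(image, SliceImage) else np.asarray(image, dtype=np.float64)
    if values.shape != geometry.image_shape:
        raise GeometryError(
            f"image shape {values.shape} does not match geometry {geometry.image_shape}")
    if not np.all(np.isfinite(values)):
        raise ValidationError("cannot project non-finite values")
    sino = radon(values, theta=geometry.angles_deg, circle=False)
    return Sinogram(sino.T * geometry.pixel_spacing, geometry)


def back_project_fbp(sino: Sinogram, geometry: ScanGeometry | None = None,
                     filter_name: str = "ramp") -> SliceImage:
    """Filtered back-projection of ``sino`` onto the geometry's image grid."""
    geometry = sino.geometry if geometry is None else geometry
    if sino.values.shape != geometry.sinogram_shape:
        raise GeometryError("sinogram shape does not match geometry")
    if filter_name not in FBP_FILTERS:
        raise ConfigurationError(
            f"unknown FBP filter {filter_name!r}; choose from {FBP_FILTERS}")
    recon = iradon(sino.values.T / geometry.pixel_spacing,
                   theta=geometry.angles_deg,
                   filter_name=filter_name,
                   circle=False,
                   output_size=geometry.image_shape[0])
    return SliceImage(recon, geometry.pixel_spacing, modality="unknown")
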