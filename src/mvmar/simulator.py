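"""Dual-energy phantom simulator.

Generates co-registered (kV artifact-laden, MV near-clean, ground-truth)
slice triples with the two physical mechanisms behind metal artifacts:

* **photon starvation** — rays through dense metal are attenuated to (almost)
  nothing; detected counts are Poisson and floored at a small clamp before the
  log, which is what turns starved rays into bright/dark streaks;
* **beam hardening** — a polychromatic spectrum hardens along the path, so
  the measured log-attenuation is a concave function of traversed thickness.

The acquisition chain applies the standard water-linearization every scanner
performs: measured polychromatic line integrals are mapped to water-equivalent
thickness (exact for water-like paths), so residual beam-hardening artifacts
come only from materials that depart from water (bone, metal) — which is the
clinically realistic situation.

This module is the only part of the package that works in physical
attenuation (1/mm); everything downstream operates on HU images.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.special import logsumexp

from .errors import ValidationError
from .geometry import ScanGeometry, SliceImage, Sinogram, back_project_fbp, forward_project

# ---------------------------------------------------------------------------
# Materials


@dataclass(frozen=True)
class MaterialTable:
    """Per-material linear attenuation mu(E) [1/mm] on a shared energy grid."""

    energies_kev: np.ndarray
    mu: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for label, values in self.mu.items():
            if len(values) != len(self.energies_kev):
                raise ValidationError(f"mu table for {label!r} does not match energy grid")
            if np.any(np.asarray(values) <= 0) and label != "air":
                raise ValidationError(f"mu must be positive for material {label!r}")
            if np.any(np.diff(values) > 0):
                raise ValidationError(f"mu must be non-increasing with E for {label!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.mu)

    def mu_at(self, label: str, energy_kev: float | np.ndarray) -> np.ndarray:
        """mu(E) by log-linear interpolation on the table grid."""
        if label not in self.mu:
            raise ValidationError(f"unknown material label {label!r}")
        return np.exp(np.interp(np.log(energy_kev), np.log(self.energies_kev),
                                np.log(self.mu[label])))

    def mu_map(self, labels: np.ndarray, energy_kev: float) -> np.ndarray:
        """Per-pixel mu at a single energy from a material-label grid."""
        out = np.empty(labels.shape, dtype=np.float64)
        for label in np.unique(labels):
            out[labels == label] = self.mu_at(str(label), energy_kev)
        return out


def load_materials() -> MaterialTable:
    """Load the packaged attenuation table."""
    text = (importlib.resources.files("mvmar") / "data" / "materials.yaml").read_text()
    raw = yaml.safe_load(text)
    return MaterialTable(
        energies_kev=np.asarray(raw["energies_kev"], dtype=np.float64),
        mu={k: np.asarray(v["mu_per_mm"], dtype=np.float64)
            for k, v in raw["materials"].items()},
    )


# ---------------------------------------------------------------------------
# Spectra


@dataclass(frozen=True)
class SpectrumModel:
    """Discrete X-ray spectrum: energy bins, fluence weights, photons per bin."""

    energies_kev: np.ndarray
    weights: np.ndarray
    n0: float = 1.0e6

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_kev, dtype=np.float64)
        w = np.asarray(self.weights, dtype=np.float64)
        object.__setattr__(self, "energies_kev", e)
        object.__setattr__(self, "weights", w)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValidationError("spectrum weights must be nonnegative and sum to 1")
        if not self.n0 > 0:
            raise ValidationError("incident photon count N0 must be positive")

    @property
    def mean_energy_kev(self) -> float:
        """Fluence-weighted mean energy; the reference energy for HU ground truth."""
        return float(np.sum(self.energies_kev * self.weights))


def default_kv_spectrum(n0: float = 1.0e5) -> SpectrumModel:
    """Diagnostic ~120 kVp tube spectrum collapsed to six bins over 40-120 keV.

    The weights lean toward the soft end of the spectrum (lightly filtered
    head protocol), which is what drives beam hardening behind dense metal;
    ``n0`` is photons per detector bin and sets the photon-starvation level.
    """
    return SpectrumModel(
        energies_kev=np.array([40.0, 50.0, 60.0, 80.0, 100.0, 120.0]),
        weights=np.array([0.35, 0.30, 0.18, 0.10, 0.05, 0.02]),
        n0=n0,
    )


def default_mv_spectrum(n0: float = 1.0e6) -> SpectrumModel:
    """1.5 MV treatment-beam imaging spectrum collapsed to two Compton-region bins."""
    return SpectrumModel(
        energies_kev=np.array([500.0, 1000.0]),
        weights=np.array([0.6, 0.4]),
        n0=n0,
    )


# ---------------------------------------------------------------------------
# Phantom specification and rasterization


@dataclass(frozen=True)
class Primitive:
    """One painted shape: an ellipse or an axis-defined rotated rectangle.

    ``center_mm`` is (x, y) from the canvas center, y increasing downward
    (same sense as row index).  For ellipses ``size_mm`` holds the two
    semi-axes; for rectangles the full (width, height).
    """

    kind: str  # "ellipse" | "rectangle"
    center_mm: tuple[float, float]
    size_mm: tuple[float, float]
    material: str
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("ellipse", "rectangle"):
            raise ValidationError(f"unknown primitive kind {self.kind!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Material-labelled geometric phantom: painter's-order primitives on air."""

    shape: tuple[int, int]
    pixel_spacing: float
    primitives: tuple[Primitive, ...]
    materials: MaterialTable = field(repr=False)
    background: str = "air"

    def __post_init__(self) -> None:
        known = set(self.materials.labels)
        for p in self.primitives:
            if p.material not in known:
                raise ValidationError(f"material {p.material!r} not in the material table")
        if self.background not in known:
            raise ValidationError(f"background material {self.background!r} unknown")


def rasterize_phantom(spec: PhantomSpec) -> np.ndarray:
    """Paint primitives in order onto an air canvas; returns a label grid."""
    rows, cols = spec.shape
    # pixel-center coordinates in mm, origin at the canvas center
    y = (np.arange(rows) - (rows - 1) / 2.0) * spec.pixel_spacing
    x = (np.arange(cols) - (cols - 1) / 2.0) * spec.pixel_spacing
    xx, yy = np.meshgrid(x, y)
    labels = np.full(spec.shape, spec.background, dtype="<U16")
    for p in spec.primitives:
        cx, cy = p.center_mm
        th = np.deg2rad(p.rotation_deg)
        xr = (xx - cx) * np.cos(th) + (yy - cy) * np.sin(th)
        yr = -(xx - cx) * np.sin(th) + (yy - cy) * np.cos(th)
        if p.kind == "ellipse":
            a, b = p.size_mm
            inside = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
        else:
            w, h = p.size_mm
            inside = (np.abs(xr) <= w / 2.0) & (np.abs(yr) <= h / 2.0)
        labels[inside] = p.material
    return labels


# ---------------------------------------------------------------------------
# Scanning


def polychromatic_scan(labels: np.ndarray, spec: PhantomSpec, spectrum: SpectrumModel,
                       geometry: ScanGeometry, seed: int | None = None,
                       count_clamp: float = 1.0) -> Sinogram:
    """Polychromatic acquisition of a material-label grid.

    Detected counts per bin are ``N0 * sum_E w(E) exp(-integral mu(E) dl)``,
    Poisson-distributed when ``seed`` is given, floored at ``count_clamp``
    before the log (the photon-starvation clamp).  Returns -log(count/N0).
    """
    # log-transmission per energy, combined with logsumexp for stability on
    # starved rays where individual exponentials underflow
    log_terms = np.empty((len(spectrum.energies_kev),) + geometry.sinogram_shape)
    for i, (e_kev, w) in enumerate(zip(spectrum.energies_kev, spectrum.weights)):
        line = forward_project(spec.materials.mu_map(labels, e_kev), geometry)
        log_terms[i] = np.log(w) - line.values if w > 0 else -np.inf
    log_trans = logsumexp(log_terms, axis=0)
    expected = spectrum.n0 * np.exp(log_trans)
    if seed is not None:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(np.float64)
    else:
        counts = expected
    counts = np.maximum(counts, count_clamp)
    return Sinogram(-np.log(counts / spectrum.n0), geometry)


def _water_linearization(p: np.ndarray, spectrum: SpectrumModel,
                         materials: MaterialTable) -> np.ndarray:
    """Map polychromatic log-attenuation to water-equivalent thickness (mm)."""
    mu_w = materials.mu_at("water", spectrum.energies_kev)
    t = np.linspace(0.0, 3000.0, 3001)
    p_of_t = -logsumexp(np.log(spectrum.weights)[:, None] - mu_w[:, None] * t[None, :], axis=0)
    # p_of_t is strictly increasing; extend linearly past the grid end
    out = np.interp(p, p_of_t, t)
    over = p > p_of_t[-1]
    if np.any(over):
        slope = (t[-1] - t[-2]) / (p_of_t[-1] - p_of_t[-2])
        out[over] = t[-1] + (p[over] - p_of_t[-1]) * slope
    return out


def _to_hu(mu_image: np.ndarray, materials: MaterialTable, energy_kev: float) -> np.ndarray:
    """Two-point HU calibration: water -> 0 HU, air -> -1000 HU."""
    mu_w = float(materials.mu_at("water", energy_kev))
    mu_a = float(materials.mu_at("air", energy_kev))
    return -1000.0 + 1000.0 * (mu_image - mu_a) / (mu_w - mu_a)


def _reconstruct_hu(raw: Sinogram, spectrum: SpectrumModel, materials: MaterialTable,
                    modality: str) -> SliceImage:
    """Water-linearize, scale to mu at the reference energy, FBP, calibrate HU."""
    e_ref = spectrum.mean_energy_kev
    t_water = _water_linearization(raw.values, spectrum, materials)
    mu_ref = float(materials.mu_at("water", e_ref))
    mu_sino = Sinogram(t_water * mu_ref, raw.geometry)
    recon = back_project_fbp(mu_sino)
    img = SliceImage(_to_hu(recon.values, materials, e_ref), raw.geometry.pixel_spacing, modality)
    return img


def monochromatic_reference(labels: np.ndarray, spec: PhantomSpec, energy_kev: float,
                            geometry: ScanGeometry, modality: str = "kV") -> SliceImage:
    """Noiseless single-energy reconstruction: the artifact-free ground truth."""
    mu = spec.materials.mu_map(labels, energy_kev)
    sino = forward_project(mu, geometry)
    recon = back_project_fbp(sino)
    return SliceImage(_to_hu(recon.values, spec.materials, energy_kev),
                      geometry.pixel_spacing, modality)


METAL_LABELS = ("titanium", "steel", "amalgam")


@dataclass
class ScanPair:
    """Perfectly co-registered kV / MV / truth triple from one phantom."""

    kv_image: SliceImage
    mv_image: SliceImage
    ground_truth_kv: SliceImage
    ground_truth_mv: SliceImage
    metal_truth_mask: np.ndarray
    labels: np.ndarray
    seed: int


def simulate_scan_pair(spec: PhantomSpec, kv_spectrum: SpectrumModel,
                       mv_spectrum: SpectrumModel, geometry: ScanGeometry,
                       seed: int = 0, noiseless: bool = False) -> ScanPair:
    """Acquire the kV and MV scans of one phantom plus monochromatic truths.

    ``noiseless=True`` disables Poisson counting noise (starvation clamping
    and beam hardening remain), exposing the deterministic artifact content.
    """
    if geometry.image_shape != spec.shape:
        raise ValidationError("geometry image_shape must match the phantom canvas")
    labels = rasterize_phantom(spec)
    kv_seed, mv_seed = (int(s.generate_state(1)[0] % (2 ** 31))
                        for s in np.random.SeedSequence(seed).spawn(2))
    if noiseless:
        kv_seed = mv_seed = None
    kv_raw = polychromatic_scan(labels, spec, kv_spectrum, geometry, seed=kv_seed)
    mv_raw = polychromatic_scan(labels, spec, mv_spectrum, geometry, seed=mv_seed)
    kv = _reconstruct_hu(kv_raw, kv_spectrum, spec.materials, "kV")
    mv = _reconstruct_hu(mv_raw, mv_spectrum, spec.materials, "MV")
    truth_kv = monochromatic_reference(labels, spec, kv_spectrum.mean_energy_kev, geometry, "kV")
    truth_mv = monochromatic_reference(labels, spec, mv_spectrum.mean_energy_kev, geometry, "MV")
    metal = np.isin(labels, METAL_LABELS)
    return ScanPair(kv, mv, truth_kv, truth_mv, metal, labels, seed)


# ---------------------------------------------------------------------------
# Canonical phantoms


def dental_phantom(shape: tuple[int, int] = (256, 256), pixel_spacing: float = 1.0,
                   n_metal: int = 3, metal_radius_mm: float = 3.25,
                   materials: MaterialTable | None = None) -> PhantomSpec:
    """Head-like phantom with a jaw arc of bone and dental metal inserts.

    A soft-tissue head ellipse, an oral air cavity, a mandible arc built from
    overlapping trabecular-bone disks, and ``n_metal`` amalgam inserts along
    the tooth row just inside the jaw line — the multi-metal denture
    situation whose crossing metal shadows produce mutually interacting
    streak and shading artifacts at kV.
    """
    materials = materials or load_materials()
    prims: list[Primitive] = [
        Primitive("ellipse", (0.0, 0.0), (80.0, 95.0), "soft_tissue"),
        Primitive("ellipse", (0.0, 25.0), (25.0, 14.0), "air"),
    ]
    arc_center = (0.0, 10.0)
    jaw_radius = 55.0
    tooth_radius = 45.0   # tooth row sits lingual of (inside) the mandible arc
    for phi_deg in np.linspace(30.0, 150.0, 9):
        phi = np.deg2rad(phi_deg)
        prims.append(Primitive(
            "ellipse",
            (arc_center[0] + jaw_radius * np.cos(phi), arc_center[1] + jaw_radius * np.sin(phi)),
            (7.0, 7.0), "bone_spongy"))
    metal_phis = np.linspace(60.0, 120.0, n_metal) if n_metal > 1 else np.array([90.0])
    for phi_deg in metal_phis[:n_metal]:
        phi = np.deg2rad(phi_deg)
        prims.append(Primitive(
            "ellipse",
            (arc_center[0] + tooth_radius * np.cos(phi), arc_center[1] + tooth_radius * np.sin(phi)),
            (metal_radius_mm, metal_radius_mm), "amalgam"))
    return PhantomSpec(shape, pixel_spacing, tuple(prims), materials)


def rod_phantom(shape: tuple[int, int] = (256, 256), pixel_spacing: float = 1.0,
                with_metal: bool = True, rod_radius_mm: float = 8.0,
                rod_material: str = "titanium",
                materials: MaterialTable | None = None) -> PhantomSpec:
    """Water-equivalent head cylinder with named inserts and a removable rod.

    Region A sits in soft tissue near the rod (where its hardening artifacts
    concentrate), region B inside a low-density cavity; the rod can be
    omitted to produce the artifact-free reference scan.
    """
    materials = materials or load_materials()
    prims: list[Primitive] = [
        Primitive("ellipse", (0.0, 0.0), (80.0, 80.0), "soft_tissue"),
        Primitive("ellipse", (35.0, 0.0), (12.0, 12.0), "air"),
        Primitive("ellipse", (-35.0, 0.0), (8.0, 8.0), "bone"),
    ]
    if with_metal:
        prims.append(Primitive("ellipse", (0.0, 30.0),
                               (rod_radius_mm, rod_radius_mm), rod_material))
    return PhantomSpec(shape, pixel_spacing, tuple(prims), materials)


def _px(coord_mm: float, n: int, pixel_spacing: float) -> int:
    """mm offset from the canvas center -> nearest pixel index."""
    return int(round(coord_mm / pixel_spacing + (n - 1) / 2.0))


def dental_rois(shape: tuple[int, int] = (256, 256),
                pixel_spacing: float = 1.0) -> dict[str, "object"]:
    """Named evaluation ROIs for the dental phantom (lazy import avoids cycles)."""
    from .metrics import Roi
    n = shape[0]
    # between the metal inserts, interior to the tooth row: where the
    # mutually interacting streaks live
    inter = Roi("circle", (_px(48.5, n, pixel_spacing), _px(-9.5, n, pixel_spacing)),
                radius_px=int(round(6.0 / pixel_spacing)), label="inter_metal")
    soft = Roi("circle", (_px(-40.0, n, pixel_spacing), _px(0.0, n, pixel_spacing)),
               radius_px=int(round(10.0 / pixel_spacing)), label="soft_tissue")
    return {"inter_metal": inter, "soft_tissue": soft}


def rod_phantom_rois(shape: tuple[int, int] = (256, 256),
                     pixel_spacing: float = 1.0) -> dict[str, "object"]:
    """Named ROIs A (soft tissue near the rod) and B (low density) for the rod phantom."""
    from .metrics import Roi
    n = shape[0]
    roi_a = Roi("circle", (_px(30.5, n, pixel_spacing), _px(20.5, n, pixel_spacing)),
                radius_px=int(round(7.0 / pixel_spacing)), label="A")
    roi_b = Roi("circle", (_px(0.0, n, pixel_spacing), _px(35.0, n, pixel_spacing)),
                radius_px=int(round(7.0 / pixel_spacing)), label="B")
    return {"A": roi_a, "B": roi_b}
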