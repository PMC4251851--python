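"""Synthetic PET phantoms and synthetic cohorts with known ground truth.

The raw scans behind the packaged cohort are not available, so every
image-quantification stage is exercised on voxel phantoms that emulate the
acquisition geometry: a static FDG-SUV volume (45-60 min window) and a
late-frame (90-120 min) hypoxia-tracer activity volume with a plasma
reference, an ellipsoidal tumor containing a contiguous hypoxic
sub-region of known fractional size, and normal-tissue reference ROIs
(brain / muscle / lung analogues) spanning three adjacent planes each.

The cohort generator draws rank-correlated patient tables through a
latent-Gaussian (Gaussian copula) construction.  Because every statistic
downstream is rank-based, only the rank-correlation structure matters and
the copula family is immaterial; the usual mapping between a target
Spearman correlation rho_s and the latent Pearson correlation,
r = 2 sin(pi * rho_s / 6), makes the targets exact in the large-sample
limit.

Everything is driven by a single integer seed; identical specs and seeds
give bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .data_model import (
    DEFAULT_PIXEL_MM,
    DEFAULT_PLANE_MM,
    CohortTable,
    PlasmaReference,
    RoiLabel,
    RoiMask,
    Units,
    VoxelImage,
    BIOMARKER_COLUMNS,
    PET_COLUMNS,
)

__all__ = [
    "PhantomSpec",
    "PhantomResult",
    "CohortSpec",
    "GeometryError",
    "generate_phantom",
    "generate_cohort",
    "spearman_to_latent",
    "default_marginal_ranges",
    "save_image",
    "load_image",
    "save_mask",
    "load_mask",
]


class GeometryError(ValueError):
    """Requested phantom geometry does not fit the voxel grid."""


# Normal-tissue analogues: (ratio mean, ratio sd) of the tissue-to-plasma
# distribution each reference ROI is drawn from.  Chosen so that the pooled
# mean + 3 SD lands near the study's normal-tissue threshold (~0.9).
DEFAULT_NORMAL_TISSUES: Mapping[str, tuple[float, float]] = {
    "brain": (0.70, 0.05),
    "muscle": (0.60, 0.06),
    "lung": (0.50, 0.05),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and signal levels of one synthetic patient.

    Signal defaults follow the study's cohort medians: FDG lesion peak
    SUV 13, late-window tumor T/P around 1 with a hypoxic sub-region at
    1.5 and normoxic tissue at 0.6, hypoxic fraction 0.48.
    """

    shape: tuple[int, int, int] = (24, 48, 48)
    spacing_mm: tuple[float, float, float] = (
        DEFAULT_PLANE_MM,
        DEFAULT_PIXEL_MM,
        DEFAULT_PIXEL_MM,
    )
    tumor_center: tuple[int, int, int] = (12, 24, 24)
    tumor_radii: tuple[float, float, float] = (5.0, 8.0, 8.0)
    hypoxic_fraction: float = 0.48
    normoxic_ratio: float = 0.6
    hypoxic_ratio: float = 1.5
    background_ratio: float = 0.4
    normal_tissues: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_NORMAL_TISSUES)
    )
    background_suv: float = 1.0
    tumor_suv_plateau: float = 6.0
    lesion_suv_peak: float = 13.0
    plasma_kbq_per_ml: float = 5.0
    injected_dose_mbq: float = 370.0
    body_weight_kg: float = 74.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.hypoxic_fraction <= 1.0):
            raise ValueError("hypoxic fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not (self.plasma_kbq_per_ml > 0):
            raise ValueError("plasma activity must be > 0")
        for c, r, n in zip(self.tumor_center, self.tumor_radii, self.shape):
            if r <= 0:
                raise GeometryError("tumor radii must be > 0")
            if c - r < 0 or c + r > n - 1:
                raise GeometryError(
                    f"tumor (center {self.tumor_center}, radii {self.tumor_radii}) "
                    f"exceeds grid {self.shape}"
                )


@dataclass(frozen=True)
class PhantomResult:
    """Images, masks, plasma reference and the ground-truth record."""

    fdg_suv: VoxelImage
    fdg_activity: VoxelImage
    tp_image: VoxelImage
    tumor_mask: RoiMask
    normal_masks: dict[str, RoiMask]
    plasma: PlasmaReference
    truth: dict


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = (
        ((zz - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((xx - center[2]) / radii[2]) ** 2
    )
    return d2 <= 1.0


def _contiguous_subregion(tumor: np.ndarray, center, n_voxels: int) -> np.ndarray:
    """The n tumor voxels nearest to ``center``: a contiguous ball grown
    inside the tumor, deterministic tie-break by (plane, row, col)."""
    idx = np.argwhere(tumor)
    d2 = ((idx - np.asarray(center)) ** 2).sum(axis=1)
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], d2))
    chosen = idx[order[:n_voxels]]
    out = np.zeros_like(tumor)
    out[chosen[:, 0], chosen[:, 1], chosen[:, 2]] = True
    return out


def _normal_roi_boxes(shape) -> dict[str, tuple[slice, slice, slice]]:
    """Three reference boxes, each spanning three adjacent planes, placed
    in the first planes away from the central tumor."""
    n_rows, n_cols = shape[1], shape[2]
    q_r, q_c = n_rows // 4, n_cols // 4
    return {
        "brain": (slice(0, 3), slice(2, 2 + q_r), slice(2, 2 + q_c)),
        "muscle": (slice(0, 3), slice(2, 2 + q_r), slice(n_cols - 2 - q_c, n_cols - 2)),
        "lung": (slice(0, 3), slice(n_rows - 2 - q_r, n_rows - 2), slice(2, 2 + q_c)),
    }


def default_input_curve(
    peak_time_s: float = 30.0, peak_kbq_per_ml: float = 40.0, duration_s: float = 300.0
) -> tuple[np.ndarray, np.ndarray]:
    """A gamma-variate-like arterial bolus with a recirculation plateau:
    Ca(t) = A t exp(-t/tau) + 0.2 * peak * (1 - exp(-t/45))."""
    t = np.linspace(0.0, duration_s, 301)
    tau = peak_time_s
    a = peak_kbq_per_ml / (tau * np.exp(-1.0))
    return t, a * t * np.exp(-t / tau) + 0.2 * peak_kbq_per_ml * (1.0 - np.exp(-t / 45.0))


def generate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Build one synthetic patient from ``spec`` (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape

    tumor = _ellipsoid_mask(shape, spec.tumor_center, spec.tumor_radii)
    n_tumor = int(tumor.sum())
    n_hyp = int(round(spec.hypoxic_fraction * n_tumor))
    hypoxic = _contiguous_subregion(tumor, spec.tumor_center, n_hyp)

    boxes = _normal_roi_boxes(shape)
    normal_masks = {}
    for name, sl in boxes.items():
        m = np.zeros(shape, dtype=bool)
        m[sl] = True
        if (m & tumor).any():
            raise GeometryError(f"normal ROI {name!r} overlaps the tumor")
        normal_masks[name] = RoiMask(m, RoiLabel(name))

    # late-frame hypoxia-tracer ratio image
    tp_vals = np.full(shape, spec.background_ratio, dtype=float)
    tp_vals[tumor] = spec.normoxic_ratio
    tp_vals[hypoxic] = spec.hypoxic_ratio
    for name, (mean, sd) in spec.normal_tissues.items():
        m = normal_masks[name].mask
        tp_vals[m] = rng.normal(mean, sd, size=int(m.sum()))
    if spec.noise_sd > 0:
        tp_vals = tp_vals + rng.normal(0.0, spec.noise_sd, size=shape)
    tp_image = VoxelImage(tp_vals, spec.spacing_mm, Units.RATIO)

    # static FDG image: plateau over the tumor, a 3x3 single-plane peak
    # block at the tumor center (so the 3x3 window mean recovers the peak)
    suv_vals = np.full(shape, spec.background_suv, dtype=float)
    suv_vals[tumor] = spec.tumor_suv_plateau
    pz, py, px = spec.tumor_center
    suv_vals[pz, py - 1 : py + 2, px - 1 : px + 2] = spec.lesion_suv_peak
    if spec.noise_sd > 0:
        suv_vals = suv_vals + rng.normal(0.0, spec.noise_sd, size=shape)
    fdg_suv = VoxelImage(suv_vals, spec.spacing_mm, Units.SUV)
    # corresponding activity image so SUV computation can be exercised
    suv_scale = (spec.injected_dose_mbq * 1000.0) / (spec.body_weight_kg * 1000.0)
    fdg_activity = VoxelImage(suv_vals * suv_scale, spec.spacing_mm, Units.KBQ_PER_ML)

    t, ca = default_input_curve()
    plasma = PlasmaReference(
        activity_kbq_per_ml=spec.plasma_kbq_per_ml,
        input_times_s=t,
        input_activities=ca,
    )

    voxel_ml = fdg_suv.voxel_volume_ml
    truth = {
        "n_tumor_voxels": n_tumor,
        "n_hypoxic_voxels": n_hyp,
        "fhv_pct": 100.0 * n_hyp / n_tumor if n_tumor else 0.0,
        "tumor_volume_cm3": n_tumor * voxel_ml,
        "suv_plateau": spec.tumor_suv_plateau,
        "suv_peak": spec.lesion_suv_peak,
        "normoxic_ratio": spec.normoxic_ratio,
        "hypoxic_ratio": spec.hypoxic_ratio,
        "injected_dose_mbq": spec.injected_dose_mbq,
        "body_weight_kg": spec.body_weight_kg,
        "seed": spec.seed,
    }
    return PhantomResult(
        fdg_suv=fdg_suv,
        fdg_activity=fdg_activity,
        tp_image=tp_image,
        tumor_mask=RoiMask(tumor, RoiLabel.TUMOR),
        normal_masks=normal_masks,
        plasma=plasma,
        truth=truth,
    )


# --- synthetic cohorts ------------------------------------------------------

def default_marginal_ranges() -> dict[str, tuple[float, float]]:
    """Study-scale marginal ranges for the standard variable registry."""
    return {
        "suv": (5.3, 28.8),
        "tumor_volume_cm3": (1.4, 401.6),
        "fhv_pct": (9.5, 63.2),
        "tp_ratio": (0.72, 1.98),
        "blood_flow": (12.4, 63.1),
        "ki67_pct": (17.0, 87.0),
        "glut1_pct": (0.0, 60.0),
        "p53_pct": (2.0, 95.0),
        "hif1a_pct": (0.0, 68.0),
        "cd68_pct": (5.0, 44.0),
        "cd31_pct": (0.4, 14.9),
        "tunel_pct": (0.3, 20.0),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic cohort with a target pairwise Spearman structure.

    ``target_spearman`` maps variable pairs (frozenset-like 2-tuples) to
    target rank correlations; unspecified pairs default to 0.  Marginals
    are monotone maps of the latent Gaussians onto ``ranges``.
    """

    n_patients: int = 15
    variables: tuple[str, ...] = PET_COLUMNS + BIOMARKER_COLUMNS
    target_spearman: Mapping[tuple[str, str], float] = field(default_factory=dict)
    ranges: Mapping[str, tuple[float, float]] | None = None
    missing_prob: float = 0.0
    dead_prob: float = 0.6
    vegf_probs: tuple[float, float, float] = (0.4, 0.4, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 3:
            raise ValueError("n_patients must be >= 3")
        if not (0.0 <= self.missing_prob < 1.0):
            raise ValueError("missing_prob must be in [0, 1)")
        for (a, b), r in self.target_spearman.items():
            if a not in self.variables or b not in self.variables:
                raise ValueError(f"unknown variable in target pair ({a}, {b})")
            if not (-1.0 <= r <= 1.0):
                raise ValueError(f"target correlation out of [-1, 1]: {r}")

    def target_matrix(self) -> np.ndarray:
        k = len(self.variables)
        m = np.eye(k)
        index = {v: i for i, v in enumerate(self.variables)}
        for (a, b), r in self.target_spearman.items():
            i, j = index[a], index[b]
            if i == j:
                continue
            if m[i, j] not in (0.0, r):
                raise ValueError(f"conflicting targets for pair ({a}, {b})")
            m[i, j] = m[j, i] = r
        return m


def spearman_to_latent(rho_s: np.ndarray) -> np.ndarray:
    """Map target Spearman correlations to latent Gaussian correlations."""
    return 2.0 * np.sin(np.pi * np.asarray(rho_s) / 6.0)


def _nearest_psd(matrix: np.ndarray) -> tuple[np.ndarray, float]:
    """Eigenvalue-clipped nearest correlation matrix; returns (matrix, shift)."""
    vals, vecs = np.linalg.eigh(matrix)
    if vals.min() >= 1e-10:
        return matrix, 0.0
    clipped = np.clip(vals, 1e-10, None)
    fixed = vecs @ np.diag(clipped) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    return fixed, float(np.abs(fixed - matrix).max())


def generate_cohort(spec: CohortSpec) -> CohortTable:
    """Draw a synthetic :class:`CohortTable` with the requested rank-correlation
    structure (latent-Gaussian copula, monotone marginal maps).

    If the implied latent correlation matrix is not positive semidefinite it
    is replaced by the nearest valid one and a warning reports the largest
    entry adjustment.
    """
    rng = np.random.default_rng(spec.seed)
    variables = list(spec.variables)
    k = len(variables)
    latent = spearman_to_latent(spec.target_matrix())
    np.fill_diagonal(latent, 1.0)
    latent, shift = _nearest_psd(latent)
    if shift > 1e-8:
        warnings.warn(
            f"target correlation structure adjusted to nearest valid matrix "
            f"(max entry change {shift:.4g})",
            stacklevel=2,
        )
    chol = np.linalg.cholesky(latent + 1e-12 * np.eye(k))
    z = rng.standard_normal((spec.n_patients, k)) @ chol.T
    u = ndtr(z)  # standard normal CDF, strictly monotone

    ranges = dict(default_marginal_ranges())
    if spec.ranges:
        ranges.update(spec.ranges)
    data = {}
    for j, name in enumerate(variables):
        lo, hi = ranges.get(name, (0.0, 1.0))
        data[name] = lo + (hi - lo) * u[:, j]

    ids = np.arange(1, spec.n_patients + 1)
    df = pd.DataFrame(data, index=pd.Index(ids, name="patient_id"))

    # categorical columns from independent draws
    pv = np.asarray(spec.vegf_probs, dtype=float)
    pv = pv / pv.sum()
    df["vegf_intensity"] = rng.choice([1, 2, 3], size=spec.n_patients, p=pv)
    df["vital_status"] = np.where(
        rng.random(spec.n_patients) < spec.dead_prob, "dead", "alive"
    )

    # fill any registry column the spec did not simulate
    for name in PET_COLUMNS + BIOMARKER_COLUMNS:
        if name not in df.columns:
            lo, hi = ranges.get(name, (0.0, 1.0))
            df[name] = lo + (hi - lo) * rng.random(spec.n_patients)

    if spec.missing_prob > 0:
        numeric = list(PET_COLUMNS + BIOMARKER_COLUMNS)
        drop = rng.random((spec.n_patients, len(numeric))) < spec.missing_prob
        for j, name in enumerate(numeric):
            df.loc[drop[:, j], name] = np.nan

    return CohortTable(df)


# --- NIfTI I/O --------------------------------------------------------------

def _affine(spacing_mm) -> np.ndarray:
    # array axes are (plane, row, col); zooms follow the array order
    return np.diag(list(spacing_mm) + [1.0])


def save_image(image: VoxelImage, path: str | Path) -> None:
    """Write a :class:`VoxelImage` as NIfTI; spacing goes into the header
    zooms and the units tag into the ``descrip`` field."""
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(image.values, dtype=np.float64), _affine(image.spacing_mm))
    img.header["descrip"] = f"units={image.units.value}".encode()
    nib.save(img, str(path))


def load_image(path: str | Path, units: Units | None = None) -> VoxelImage:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if units is None:
        descrip = bytes(img.header["descrip"]).decode(errors="ignore")
        tag = descrip.split("units=")[-1].strip("\x00 ")
        units = Units(tag) if tag else Units.KBQ_PER_ML
    return VoxelImage(data, zooms, units)


def save_mask(mask: RoiMask, path: str | Path, spacing_mm=None) -> None:
    import nibabel as nib

    spacing = spacing_mm or (DEFAULT_PLANE_MM, DEFAULT_PIXEL_MM, DEFAULT_PIXEL_MM)
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), _affine(spacing))
    img.header["descrip"] = f"label={mask.label.value}".encode()
    nib.save(img, str(path))


def load_mask(path: str | Path, label: RoiLabel | None = None) -> RoiMask:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj) > 0
    if label is None:
        descrip = bytes(img.header["descrip"]).decode(errors="ignore")
        tag = descrip.split("label=")[-1].strip("\x00 ")
        label = RoiLabel(tag) if tag else RoiLabel.OTHER
    return RoiMask(data, label)
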