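"""Domain types and cohort table I/O.

The package operates on two kinds of data:

* voxel images (late-frame PET volumes, tumor/normal-tissue masks, a plasma
  reference activity), represented by :class:`VoxelImage`, :class:`RoiMask`
  and :class:`PlasmaReference`;
* a patient-indexed cohort table joining five image-derived PET indices
  (:class:`PatientPetIndices`) with seven continuous immunohistochemistry /
  TUNEL percentages, an ordinal VEGF staining intensity and vital status
  (:class:`BiomarkerProfile`), collected in a :class:`CohortTable`.

A 15-patient head-and-neck squamous-cell carcinoma cohort transcribed from
the published patient tables is packaged as a CSV fixture and loaded with
:func:`load_packaged_cohort`.

Missing values ("not determined" in the source tables) are a first-class
state: ``NA`` in CSV, ``NaN`` inside the table, never 0.  All statistics
downstream use pairwise deletion.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Units",
    "RoiLabel",
    "VitalStatus",
    "VoxelImage",
    "RoiMask",
    "PlasmaReference",
    "PatientPetIndices",
    "BiomarkerProfile",
    "HypoxiaThreshold",
    "CohortTable",
    "SchemaError",
    "CohortValidationError",
    "UnitsError",
    "COHORT_COLUMNS",
    "PET_COLUMNS",
    "BIOMARKER_COLUMNS",
    "load_cohort",
    "load_packaged_cohort",
    "write_results",
    "read_results",
]

# Default in-plane pixel pitch: a 3x3 pixel neighbourhood spans 7.04 mm,
# so one pixel is 7.04/3 mm.
DEFAULT_PIXEL_MM = 7.04 / 3.0
DEFAULT_PLANE_MM = 4.25


class SchemaError(ValueError):
    """A table file does not match the documented column schema."""


class CohortValidationError(ValueError):
    """A cohort cell violates its domain invariant (range, enumeration)."""


class UnitsError(ValueError):
    """An image carries the wrong units tag for the requested operation."""


class Units(str, enum.Enum):
    KBQ_PER_ML = "kBq_per_ml"
    SUV = "suv"
    RATIO = "ratio"
    ML_PER_100G_PER_MIN = "ml_per_100g_per_min"


class RoiLabel(str, enum.Enum):
    TUMOR = "tumor"
    BRAIN = "brain"
    MUSCLE = "muscle"
    LUNG = "lung"
    OTHER = "other"


class VitalStatus(str, enum.Enum):
    ALIVE = "alive"
    DEAD = "dead"


@dataclass(frozen=True)
class VoxelImage:
    """A 3-D scalar grid indexed ``(plane, row, col)`` with voxel spacing.

    Parameters
    ----------
    values
        Scalar grid, one value per voxel.
    spacing_mm
        ``(plane_thickness, pixel_dy, pixel_dx)`` in millimetres.
    units
        Physical units tag of the voxel values.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (
        DEFAULT_PLANE_MM,
        DEFAULT_PIXEL_MM,
        DEFAULT_PIXEL_MM,
    )
    units: Units = Units.KBQ_PER_ML

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3 or values.size == 0:
            raise ValueError("image grid must be a non-empty 3-D array")
        object.__setattr__(self, "values", values)
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing components must be > 0, got {spacing}")
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "units", Units(self.units))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_planes(self) -> int:
        return self.values.shape[0]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (= cm^3)."""
        dz, dy, dx = self.spacing_mm
        return dz * dy * dx / 1000.0

    def plane(self, index: int) -> np.ndarray:
        return self.values[index]

    def with_values(self, values: np.ndarray, units: Units) -> "VoxelImage":
        return VoxelImage(values, self.spacing_mm, units)


@dataclass(frozen=True)
class RoiMask:
    """Per-plane boolean mask aligned to a :class:`VoxelImage`."""

    mask: np.ndarray
    label: RoiLabel = RoiLabel.OTHER

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 3:
            raise ValueError("ROI mask must be 3-D (plane, row, col)")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "label", RoiLabel(self.label))

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    def check_aligned(self, image: VoxelImage) -> None:
        if self.mask.shape != image.values.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match image shape "
                f"{image.values.shape}"
            )
        inside = image.values[self.mask]
        if inside.size and not np.all(np.isfinite(inside)):
            raise CohortValidationError(
                f"image contains undefined values inside {self.label.value} ROI"
            )


@dataclass(frozen=True)
class PlasmaReference:
    """Plasma activity in the late imaging window, plus an optional
    sampled arterial input curve for blood-flow estimation.

    ``activity_kbq_per_ml`` is the scalar plasma activity concentration used
    as the denominator of tissue-to-plasma ratios.  ``input_times_s`` /
    ``input_activities`` sample the arterial activity Ca(t) from injection.
    """

    activity_kbq_per_ml: float
    input_times_s: np.ndarray | None = None
    input_activities: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (self.activity_kbq_per_ml > 0):
            raise ValueError("plasma activity must be > 0")
        if (self.input_times_s is None) != (self.input_activities is None):
            raise ValueError("input curve needs both times and activities")
        if self.input_times_s is not None:
            t = np.asarray(self.input_times_s, dtype=float)
            a = np.asarray(self.input_activities, dtype=float)
            if t.shape != a.shape or t.ndim != 1 or t.size < 2:
                raise ValueError("input curve must be two equal 1-D arrays")
            if np.any(np.diff(t) <= 0):
                raise ValueError("input-curve times must be strictly increasing")
            if np.any(a < 0):
                raise ValueError("input-curve activities must be >= 0")
            object.__setattr__(self, "input_times_s", t)
            object.__setattr__(self, "input_activities", a)


def _check_pct(name: str, value: float | None, patient: object = None) -> None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return
    if not (0.0 <= value <= 100.0):
        where = f" (patient {patient})" if patient is not None else ""
        raise CohortValidationError(
            f"{name}={value} outside [0, 100]{where}"
        )


@dataclass(frozen=True)
class PatientPetIndices:
    """One patient's five image-derived PET scalars; any may be missing.

    ``suv`` is the highest 3x3-pixel window-mean SUV of the FDG scan,
    ``tumor_volume_cm3`` the metabolically active volume inside the SUV-4
    isocontour, ``fhv_pct`` the fractional hypoxic volume in percent,
    ``tp_ratio`` the maximum tumor-to-plasma ratio at 90-120 min, and
    ``blood_flow`` perfusion in ml/100 g/min.
    """

    suv: float | None = None
    tumor_volume_cm3: float | None = None
    fhv_pct: float | None = None
    tp_ratio: float | None = None
    blood_flow: float | None = None

    def __post_init__(self) -> None:
        _check_pct("fhv_pct", self.fhv_pct)
        for name in ("suv", "tumor_volume_cm3", "tp_ratio", "blood_flow"):
            v = getattr(self, name)
            if v is None or math.isnan(v):
                continue
            if not math.isfinite(v):
                raise CohortValidationError(f"{name} must be finite, got {v}")
            if name == "tumor_volume_cm3" and v < 0:
                raise CohortValidationError(f"tumor volume must be >= 0, got {v}")


@dataclass(frozen=True)
class BiomarkerProfile:
    """One patient's immunohistochemistry / TUNEL readout.

    Seven continuous percentages (positive cells, or vessels/apoptotic cells
    per area), an ordinal VEGF staining intensity (1 weak, 2 moderate,
    3 intense) and the vital status at end of follow-up.
    """

    ki67_pct: float | None = None
    glut1_pct: float | None = None
    p53_pct: float | None = None
    hif1a_pct: float | None = None
    cd68_pct: float | None = None
    cd31_pct: float | None = None
    tunel_pct: float | None = None
    vegf_intensity: int | None = None
    vital_status: VitalStatus = VitalStatus.ALIVE

    def __post_init__(self) -> None:
        for name in (
            "ki67_pct", "glut1_pct", "p53_pct", "hif1a_pct",
            "cd68_pct", "cd31_pct", "tunel_pct",
        ):
            _check_pct(name, getattr(self, name))
        v = self.vegf_intensity
        if v is not None and not (isinstance(v, float) and math.isnan(v)):
            if int(v) not in (1, 2, 3):
                raise CohortValidationError(
                    f"vegf_intensity must be 1 (weak), 2 (moderate) or "
                    f"3 (intense), got {v}"
                )
            object.__setattr__(self, "vegf_intensity", int(v))
        object.__setattr__(self, "vital_status", VitalStatus(self.vital_status))


@dataclass(frozen=True)
class HypoxiaThreshold:
    """Normal-tissue-derived hypoxia threshold: pool mean + 3 pooled SD.

    The study derived its threshold (0.93) by pooling the tissue-to-plasma
    ratios of 10,968 normal-tissue pixels (brain, muscle, lung) and taking
    three standard deviations above their mean.
    """

    value: float
    n_pixels_pooled: int
    pool_mean: float
    pool_sd: float

    def __post_init__(self) -> None:
        if self.n_pixels_pooled < 2:
            raise ValueError("pooled pixel count must be >= 2")
        expected = self.pool_mean + 3.0 * self.pool_sd
        if not math.isclose(self.value, expected, rel_tol=0, abs_tol=1e-12):
            raise ValueError(
                f"threshold {self.value} != pool_mean + 3*pool_sd = {expected}"
            )


# --- cohort table -----------------------------------------------------------

PET_COLUMNS = ("suv", "tumor_volume_cm3", "fhv_pct", "tp_ratio", "blood_flow")
BIOMARKER_COLUMNS = (
    "ki67_pct", "glut1_pct", "p53_pct", "hif1a_pct",
    "cd68_pct", "cd31_pct", "tunel_pct",
)
COHORT_COLUMNS = (
    ("patient_id",)
    + PET_COLUMNS
    + BIOMARKER_COLUMNS
    + ("vegf_intensity", "vital_status")
)

_PCT_COLUMNS = BIOMARKER_COLUMNS + ("fhv_pct",)
_NUMERIC_COLUMNS = PET_COLUMNS + BIOMARKER_COLUMNS + ("vegf_intensity",)
MISSING_TOKEN = "NA"


@dataclass
class CohortTable:
    """Aligned patient-indexed cohort: PET indices + biomarker profiles.

    Thin wrapper over a :class:`pandas.DataFrame` indexed by ``patient_id``
    with the fixed column registry :data:`COHORT_COLUMNS`.  Missing cells are
    ``NaN`` (the CSV representation is the literal ``NA``), and round-trip
    through :meth:`to_csv` / :func:`load_cohort` unchanged.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        expected = [c for c in COHORT_COLUMNS if c != "patient_id"]
        missing = [c for c in expected if c not in df.columns]
        if missing:
            raise SchemaError(f"cohort table missing column(s): {missing}")
        extra = [c for c in df.columns if c not in expected]
        if extra:
            raise SchemaError(f"cohort table has unknown column(s): {extra}")
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].tolist()
            raise SchemaError(f"duplicate patient identifiers: {dupes}")
        if len(df) == 0:
            raise SchemaError("cohort table has no patients")
        self.frame = df[expected].copy()
        self._validate_cells()

    def _validate_cells(self) -> None:
        df = self.frame
        for col in _NUMERIC_COLUMNS:
            try:
                df[col] = pd.to_numeric(df[col])
            except (TypeError, ValueError) as exc:
                raise SchemaError(f"column {col!r} is not numeric: {exc}") from exc
        for col in _PCT_COLUMNS:
            bad = df.index[(df[col] < 0) | (df[col] > 100)]
            if len(bad):
                raise CohortValidationError(
                    f"{col} outside [0, 100] for patient {bad[0]}"
                )
        bad = df.index[df["tumor_volume_cm3"] < 0]
        if len(bad):
            raise CohortValidationError(
                f"negative tumor volume for patient {bad[0]}"
            )
        vegf = df["vegf_intensity"].dropna()
        bad_vegf = vegf.index[~vegf.isin((1, 2, 3))]
        if len(bad_vegf):
            raise CohortValidationError(
                f"vegf_intensity not in {{1,2,3}} for patient {bad_vegf[0]}"
            )
        status = df["vital_status"]
        if status.isna().any():
            raise CohortValidationError(
                f"vital_status missing for patient {status.index[status.isna()][0]}"
            )
        allowed = {s.value for s in VitalStatus}
        bad_status = status.index[~status.isin(allowed)]
        if len(bad_status):
            raise CohortValidationError(
                f"vital_status must be one of {sorted(allowed)} "
                f"(patient {bad_status[0]})"
            )

    # -- access ---------------------------------------------------------

    @property
    def patient_ids(self) -> list:
        return list(self.frame.index)

    @property
    def n_patients(self) -> int:
        return len(self.frame)

    def column(self, name: str) -> np.ndarray:
        """Numeric column as float array with NaN for missing."""
        return self.frame[name].to_numpy(dtype=float)

    def pet_indices(self, patient_id) -> PatientPetIndices:
        row = self.frame.loc[patient_id]
        kw = {c: None if pd.isna(row[c]) else float(row[c]) for c in PET_COLUMNS}
        return PatientPetIndices(**kw)

    def biomarkers(self, patient_id) -> BiomarkerProfile:
        row = self.frame.loc[patient_id]
        kw = {c: None if pd.isna(row[c]) else float(row[c]) for c in BIOMARKER_COLUMNS}
        vegf = row["vegf_intensity"]
        return BiomarkerProfile(
            vegf_intensity=None if pd.isna(vegf) else int(vegf),
            vital_status=VitalStatus(row["vital_status"]),
            **kw,
        )

    def vital_status(self) -> pd.Series:
        return self.frame["vital_status"]

    def drop_patients(self, patient_ids: Iterable) -> "CohortTable":
        return CohortTable(self.frame.drop(index=list(patient_ids)))

    # -- I/O -------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.insert(0, "patient_id", out.index)
        out.to_csv(path, index=False, na_rep=MISSING_TOKEN)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self.frame, other.frame, check_dtype=False)
        except AssertionError:
            return False
        return True


def load_cohort(path: str | Path) -> CohortTable:
    """Read a cohort CSV (missing = literal ``NA``) into a :class:`CohortTable`.

    Raises :class:`SchemaError` for malformed headers and
    :class:`CohortValidationError` for out-of-range cells.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            keep_default_na=False,
            na_values=[MISSING_TOKEN],
            dtype={"vital_status": str},
        )
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty cohort file") from exc
    if "patient_id" not in df.columns:
        raise SchemaError(f"{path}: header must include 'patient_id'")
    df = df.set_index("patient_id")
    df.index.name = "patient_id"
    return CohortTable(df)


def load_packaged_cohort() -> CohortTable:
    """The packaged 15-patient HNSCC cohort (published Tables 1-3, joined)."""
    with resources.as_file(
        resources.files("hypoxiq").joinpath("data/cohort_hnscc.csv")
    ) as p:
        return load_cohort(p)


# --- structured results I/O -------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def write_results(results: Mapping, path: str | Path) -> None:
    """Serialize a (possibly nested) result mapping to JSON at full precision."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(_jsonable(results), fh, indent=2, allow_nan=False)
        fh.write("\n")


def read_results(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
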