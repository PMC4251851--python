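"""Image-derived PET statistics for the tumor microenvironment.

The five quantities this module computes per patient:

* **SUV** — standardized uptake value, tissue concentration normalized by
  injected dose per body weight (:func:`compute_suv`), summarized as the
  highest 3x3-pixel window-mean SUV (:func:`max_suv_3x3`);
* **metabolically active tumor volume** — volume enclosed by an SUV
  isocontour, default threshold 4 (:func:`isocontour_rois`,
  :func:`metabolic_volume`);
* **T/P ratio** — per-voxel tissue-to-plasma activity ratio in the late
  (90-120 min) window (:func:`tp_ratio_map`), summarized per patient as
  the tumor maximum (:func:`tumor_tp_ratio`);
* **FHV** — fractional hypoxic volume, the percentage of tumor voxels with
  T/P ratio above a threshold derived from pooled normal-tissue pixels as
  mean + 3 SD (:func:`derive_hypoxia_threshold`,
  :func:`fractional_hypoxic_volume`).  The study's pooled normal pixels
  (n = 10,968) gave 0.93, packaged as :data:`STUDY_FHV_THRESHOLD`;
* **blood flow** — a simplified one-tissue autoradiographic estimator
  inverting the Kety forward model on a flow lookup grid
  (:func:`autoradiographic_flow`).

Conventions that the source description leaves open are fixed here and
documented: SUV uses the body-weight convention with tissue density
1 g/ml and no extra decay correction; the isocontour is inclusive
(SUV >= threshold); "3x3 pixel maximum SUV" is the maximum over
3x3-window *means* (the standard averaged hot-spot reading of the
7.04 x 7.04 mm geometry); FHV counts voxels strictly above the threshold;
the threshold SD uses the n-1 sample denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .data_model import (
    HypoxiaThreshold,
    PlasmaReference,
    RoiLabel,
    RoiMask,
    Units,
    UnitsError,
    VoxelImage,
)

__all__ = [
    "SuvParams",
    "FlowModelParams",
    "STUDY_FHV_THRESHOLD",
    "DEFAULT_SUV_ISOCONTOUR",
    "compute_suv",
    "isocontour_rois",
    "metabolic_volume",
    "max_suv_3x3",
    "tp_ratio_map",
    "tumor_tp_ratio",
    "derive_hypoxia_threshold",
    "fractional_hypoxic_volume",
    "kety_forward_integral",
    "autoradiographic_flow",
]

#: Hypoxia threshold the study derived from 10,968 pooled normal-tissue
#: pixels (mean + 3 SD of normal tissue-to-plasma ratios).  The raw pixel
#: pool is not recoverable, so the constant is packaged as the default.
STUDY_FHV_THRESHOLD = 0.93

#: Default SUV isocontour threshold for the metabolically active volume.
DEFAULT_SUV_ISOCONTOUR = 4.0


@dataclass(frozen=True)
class SuvParams:
    """Injection/patient parameters entering the SUV normalization."""

    injected_dose_mbq: float
    body_weight_kg: float
    tissue_density_g_ml: float = 1.0

    def __post_init__(self) -> None:
        if not (self.injected_dose_mbq > 0):
            raise ValueError("injected dose must be > 0")
        if not (self.body_weight_kg > 0):
            raise ValueError("body weight must be > 0")
        if not (self.tissue_density_g_ml > 0):
            raise ValueError("tissue density must be > 0")


def compute_suv(activity: VoxelImage, params: SuvParams) -> VoxelImage:
    """Per-voxel SUV = C_t [kBq/g] / (injected dose [kBq] / body weight [g]).

    ``activity`` must be tagged kBq/ml; voxel concentration is converted to
    kBq/g through the tissue density.  Doubling dose and weight together
    leaves the result unchanged.
    """
    if activity.units is not Units.KBQ_PER_ML:
        raise UnitsError(
            f"SUV needs a kBq/ml activity image, got units={activity.units.value}"
        )
    dose_kbq = params.injected_dose_mbq * 1000.0
    weight_g = params.body_weight_kg * 1000.0
    c_t = activity.values / params.tissue_density_g_ml  # kBq/g
    suv = c_t / (dose_kbq / weight_g)
    return activity.with_values(suv, Units.SUV)


def isocontour_rois(
    suv: VoxelImage,
    threshold: float = DEFAULT_SUV_ISOCONTOUR,
    seed: RoiMask | None = None,
) -> RoiMask:
    """Tumor mask from an SUV isocontour: voxels with SUV >= threshold.

    When a seed region is supplied the mask is restricted to the
    26-connected components intersecting the seed, mirroring how the tumor
    area was confirmed against anatomy when the contour tool alone was
    ambiguous.  An empty mask is a valid result.
    """
    if suv.units is not Units.SUV:
        raise UnitsError(f"isocontour needs an SUV image, got {suv.units.value}")
    mask = suv.values >= threshold
    if seed is not None:
        seed.check_aligned(suv)
        labels, n_comp = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
        wanted = np.unique(labels[seed.mask & mask])
        wanted = wanted[wanted > 0]
        mask = np.isin(labels, wanted)
    return RoiMask(mask, RoiLabel.TUMOR)


def metabolic_volume(mask: RoiMask, image: VoxelImage) -> float:
    """Summed volume of masked voxels in cm^3, across all planes."""
    mask.check_aligned(image)
    return mask.voxel_count * image.voxel_volume_ml


def _window_mean_3x3(plane: np.ndarray) -> np.ndarray:
    """In-plane 3x3 window means; windows clipped at the image edge
    average only the in-bounds voxels."""
    kernel = np.ones((3, 3))
    sums = ndimage.convolve(plane, kernel, mode="constant", cval=0.0)
    counts = ndimage.convolve(np.ones_like(plane), kernel, mode="constant", cval=0.0)
    return sums / counts


def max_suv_3x3(
    suv: VoxelImage, roi: RoiMask, *, clip_at_edge: bool = False
) -> tuple[float, int]:
    """Highest 3x3-pixel window-mean SUV over windows centred on ROI voxels.

    Returns ``(value, plane_index)`` of the global maximum.  With the
    default ``clip_at_edge=False`` out-of-bounds window cells contribute
    zeros (mean over 9 cells); with ``clip_at_edge=True`` edge windows
    average only their in-bounds cells.
    """
    if suv.units is not Units.SUV:
        raise UnitsError(f"max_suv_3x3 needs an SUV image, got {suv.units.value}")
    roi.check_aligned(suv)
    if roi.voxel_count == 0:
        raise ValueError("ROI is empty")
    best = -np.inf
    best_plane = -1
    for p in range(suv.n_planes):
        pm = roi.mask[p]
        if not pm.any():
            continue
        if clip_at_edge:
            means = _window_mean_3x3(suv.values[p])
        else:
            means = ndimage.convolve(
                suv.values[p], np.ones((3, 3)) / 9.0, mode="constant", cval=0.0
            )
        m = float(means[pm].max())
        if m > best:
            best, best_plane = m, p
    return best, best_plane


def tp_ratio_map(tissue: VoxelImage, plasma: PlasmaReference) -> VoxelImage:
    """Per-voxel tissue-to-plasma activity ratio (late static window)."""
    if tissue.units is not Units.KBQ_PER_ML:
        raise UnitsError(
            f"T/P ratio needs a kBq/ml tissue image, got {tissue.units.value}"
        )
    return tissue.with_values(
        tissue.values / plasma.activity_kbq_per_ml, Units.RATIO
    )


def tumor_tp_ratio(
    tp: VoxelImage, tumor: RoiMask, statistic: str = "max"
) -> float:
    """Per-patient T/P ratio over the tumor ROI.

    The study reports the tumor *maximum*; the ROI mean is also exposed
    but the pipeline default follows the published convention.
    """
    if tp.units is not Units.RATIO:
        raise UnitsError(f"needs a ratio image, got {tp.units.value}")
    tumor.check_aligned(tp)
    if tumor.voxel_count == 0:
        raise ValueError("tumor ROI is empty")
    vals = tp.values[tumor.mask]
    if statistic == "max":
        return float(vals.max())
    if statistic == "mean":
        return float(vals.mean())
    raise ValueError(f"unknown statistic {statistic!r}")


def derive_hypoxia_threshold(normal_ratios) -> HypoxiaThreshold:
    """Hypoxia threshold from pooled normal-tissue T/P pixel ratios.

    threshold = pooled mean + 3 x sample SD (n-1 denominator).  The pool
    must hold at least two pixels.
    """
    pool = np.asarray(normal_ratios, dtype=float).ravel()
    if pool.size < 2:
        raise ValueError("need >= 2 pooled normal-tissue ratios")
    if not np.all(np.isfinite(pool)):
        raise ValueError("pooled ratios must be finite")
    mean = float(pool.mean())
    sd = float(pool.std(ddof=1))
    return HypoxiaThreshold(
        value=mean + 3.0 * sd,
        n_pixels_pooled=int(pool.size),
        pool_mean=mean,
        pool_sd=sd,
    )


def fractional_hypoxic_volume(
    tp: VoxelImage, tumor: RoiMask, threshold: float = STUDY_FHV_THRESHOLD
) -> float:
    """FHV: percentage of tumor voxels with T/P ratio strictly above threshold."""
    if tp.units is not Units.RATIO:
        raise UnitsError(f"FHV needs a ratio image, got {tp.units.value}")
    tumor.check_aligned(tp)
    n = tumor.voxel_count
    if n == 0:
        raise ValueError("tumor ROI is empty")
    above = int((tp.values[tumor.mask] > threshold).sum())
    return 100.0 * above / n


# --- simplified autoradiographic blood flow --------------------------------

@dataclass(frozen=True)
class FlowModelParams:
    """One-tissue Kety autoradiographic model parameters.

    ``partition_coefficient`` is the tissue:blood partition coefficient of
    water (ml/g), ``integration_time_s`` the accumulation time of the
    autoradiographic readout, and ``flow_grid`` the candidate flows
    (ml/100 g/min) on which the forward model is tabulated.
    """

    partition_coefficient: float = 0.9
    integration_time_s: float = 250.0
    flow_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 150.0, 601)
    )

    def __post_init__(self) -> None:
        if not (self.partition_coefficient > 0):
            raise ValueError("partition coefficient must be > 0")
        if not (self.integration_time_s > 0):
            raise ValueError("integration time must be > 0")
        grid = np.asarray(self.flow_grid, dtype=float)
        if grid.size < 2 or np.any(np.diff(grid) <= 0):
            raise ValueError("flow lookup grid must be strictly increasing, >= 2 points")
        object.__setattr__(self, "flow_grid", grid)


def kety_forward_integral(
    flow_ml_per_100g_min: float,
    input_curve: PlasmaReference,
    params: FlowModelParams,
) -> float:
    """Accumulated tissue counts of the one-tissue Kety model (kBq*s/ml).

    The tissue response to an arterial input Ca(t) is
    ``dC/dt = f Ca(t) - (f/p) C(t)``; the autoradiographic observation is
    the scan-accumulated activity ``A(f) = int_0^T C(u) du``, which after
    switching the order of integration has the closed form

        A(f) = p * int_0^T Ca(t) * (1 - exp(-(f/p)(T - t))) dt.

    ``f`` is converted from ml/100 g/min to ml/g/s and the integral is
    evaluated on the sampled curve restricted to [0, T] by the trapezoid
    rule.  The integrand increases pointwise in f, so A is strictly
    increasing (saturating at p * int Ca): the lookup is invertible over
    the whole physiological range.
    """
    if input_curve.input_times_s is None:
        raise ValueError("flow estimation needs a sampled arterial input curve")
    T = params.integration_time_s
    t = input_curve.input_times_s
    ca = input_curve.input_activities
    if t[0] > 0 or t[-1] < T:
        raise ValueError(
            f"input curve must cover [0, {T}] s, got [{t[0]}, {t[-1]}]"
        )
    # restrict to [0, T], interpolating the endpoint
    keep = t <= T
    tt = np.append(t[keep], T) if t[keep][-1] < T else t[keep]
    cc = np.interp(tt, t, ca)
    p = params.partition_coefficient
    f = flow_ml_per_100g_min / 100.0 / 60.0  # ml/g/s
    integrand = p * cc * (1.0 - np.exp(-(f / p) * (T - tt)))
    return float(np.trapezoid(integrand, tt))


def autoradiographic_flow(
    tissue_integral: float,
    input_curve: PlasmaReference,
    params: FlowModelParams | None = None,
) -> float:
    """Invert the Kety forward model: observed accumulated tissue activity
    (kBq*s/ml) -> flow (ml/100 g/min), by table lookup with linear
    interpolation between grid points.

    Raises a range error naming the bracketing forward values when the
    observed integral falls outside the tabulated span.
    """
    params = params or FlowModelParams()
    if tissue_integral == 0.0:
        return 0.0
    table = np.array(
        [kety_forward_integral(f, input_curve, params) for f in params.flow_grid]
    )
    if np.any(np.diff(table) <= 0):
        raise ValueError(
            "forward table is not strictly increasing on the flow grid; "
            "shorten the grid or supply a longer input curve"
        )
    lo, hi = table[0], table[-1]
    if not (lo <= tissue_integral <= hi):
        raise ValueError(
            f"tissue integral {tissue_integral} outside lookup range "
            f"[{lo}, {hi}] (flows {params.flow_grid[0]}..{params.flow_grid[-1]} "
            "ml/100 g/min)"
        )
    return float(np.interp(tissue_integral, table, params.flow_grid))
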