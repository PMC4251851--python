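"""End-to-end biomarker-association analysis of a cohort table.

Reproduces the study's statistical analysis from a :class:`CohortTable`:

1. per-column cohort summary (median, range, n);
2. the 7 x 5 Spearman correlation matrix between biomarkers
   (GLUT-1, HIF-1a, Ki-67, p53, CD31, CD68, TUNEL) and PET indices
   (SUV, metabolic tumor volume, FHV, T/P ratio, blood flow), with
   pairwise deletion of missing values;
3. median-split comparisons: each PET index dichotomized at its median
   (<= median = LOW), biomarkers compared between LOW and HIGH groups by
   Wilcoxon rank-sum;
4. VEGF staining-intensity comparisons: weak vs moderate/intense tumors
   compared on each PET index;
5. outcome comparisons: each biomarker compared between patients alive
   and dead at end of follow-up.

VEGF intensity is ordinal and is analyzed only through its two-group
split, never in the continuous correlation matrix.  Every cell carries
the pairwise n it was computed from.  No multiple-testing adjustment is
applied (the analysis mirrors the original, which performed none); the
report counts the comparisons it made.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    CohortTable,
    load_cohort,
    write_results,
)
from .rank_stats import (
    CorrelationResult,
    DegenerateDataError,
    GroupComparisonResult,
    InsufficientDataError,
    dichotomize_by_median,
    spearman,
    wilcoxon_rank_sum,
)

__all__ = [
    "BIOMARKERS",
    "PET_INDICES",
    "PipelineConfig",
    "AssociationReport",
    "summarize_cohort",
    "correlation_matrix",
    "median_split_associations",
    "vegf_group_associations",
    "outcome_associations",
    "run_pipeline",
]

# Table layout of the original report: biomarker rows x PET columns.
BIOMARKERS = (
    "glut1_pct",
    "hif1a_pct",
    "ki67_pct",
    "p53_pct",
    "cd31_pct",
    "cd68_pct",
    "tunel_pct",
)
PET_INDICES = ("suv", "tumor_volume_cm3", "fhv_pct", "tp_ratio", "blood_flow")

_LABELS = {
    "glut1_pct": "GLUT-1",
    "hif1a_pct": "HIF-1a",
    "ki67_pct": "Ki-67",
    "p53_pct": "p53",
    "cd31_pct": "CD31",
    "cd68_pct": "CD68",
    "tunel_pct": "TUNEL",
    "suv": "SUV",
    "tumor_volume_cm3": "Tumor volume",
    "fhv_pct": "FHV",
    "tp_ratio": "T/P ratio",
    "blood_flow": "Blood flow",
}


@dataclass(frozen=True)
class PipelineConfig:
    """Statistical method choices for one pipeline run.

    Defaults follow the original software's conventions: t-approximation
    for Spearman p-values, exact enumeration for the rank-sum test (both
    are feasible and reported at the 15-patient study scale).
    """

    spearman_method: str = "t_approx"
    ranksum_method: str = "exact"
    seed: int = 0
    min_pairs: int = 3

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _result_dict(r: CorrelationResult | GroupComparisonResult | None, **extra):
    if r is None:
        return None
    d = dataclasses.asdict(r)
    d.update(extra)
    return d


def summarize_cohort(cohort: CohortTable) -> dict[str, dict]:
    """Median, range and n of every numeric cohort column (missing excluded)."""
    out: dict[str, dict] = {}
    for col in PET_INDICES + BIOMARKERS:
        vals = cohort.column(col)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            out[col] = {"median": None, "min": None, "max": None, "n": 0,
                        "flag": "empty column"}
            continue
        out[col] = {
            "median": float(np.median(vals)),
            "min": float(vals.min()),
            "max": float(vals.max()),
            "n": int(vals.size),
        }
    return out


def correlation_matrix(
    cohort: CohortTable, config: PipelineConfig | None = None
) -> dict[str, dict[str, dict | None]]:
    """Spearman correlations biomarker x PET index with pairwise deletion.

    Cells with fewer complete pairs than ``config.min_pairs`` (or with a
    constant variable) are reported as missing with the reason instead of
    a number.
    """
    config = config or PipelineConfig()
    grid: dict[str, dict[str, dict | None]] = {}
    for bio in BIOMARKERS:
        row: dict[str, dict | None] = {}
        x = cohort.column(bio)
        for pet in PET_INDICES:
            y = cohort.column(pet)
            try:
                r = spearman(x, y, method=config.spearman_method, seed=config.seed)
                row[pet] = _result_dict(r)
            except (InsufficientDataError, DegenerateDataError) as exc:
                row[pet] = {"missing": True, "reason": str(exc)}
        grid[bio] = row
    return grid


def median_split_associations(
    cohort: CohortTable, config: PipelineConfig | None = None
) -> dict[str, dict]:
    """For each PET index: dichotomize patients at the median (LOW = value
    <= median), then rank-sum compare every biomarker between groups."""
    config = config or PipelineConfig()
    out: dict[str, dict] = {}
    for pet in PET_INDICES:
        labels, median = dichotomize_by_median(cohort.column(pet))
        low = labels == "low"
        high = labels == "high"
        entry: dict = {
            "median": median,
            "n_low": int(low.sum()),
            "n_high": int(high.sum()),
            "tests": {},
        }
        if entry["n_high"] == 0 or entry["n_low"] == 0:
            entry["flag"] = "degenerate split"
            out[pet] = entry
            continue
        for bio in BIOMARKERS:
            vals = cohort.column(bio)
            a, b = vals[low], vals[high]
            a, b = a[np.isfinite(a)], b[np.isfinite(b)]
            if a.size == 0 or b.size == 0:
                entry["tests"][bio] = {"missing": True, "reason": "empty group"}
                continue
            r = wilcoxon_rank_sum(a, b, method=config.ranksum_method)
            entry["tests"][bio] = _result_dict(
                r,
                median_low=float(np.median(a)),
                median_high=float(np.median(b)),
            )
        out[pet] = entry
    return out


def vegf_group_associations(
    cohort: CohortTable, config: PipelineConfig | None = None
) -> dict:
    """PET indices compared between VEGF weak (intensity 1) and
    moderate/intense (2-3) tumors; patients with unknown intensity excluded."""
    config = config or PipelineConfig()
    vegf = cohort.column("vegf_intensity")
    weak = vegf == 1
    intense = vegf >= 2
    out: dict = {"n_weak": int(weak.sum()), "n_intense": int(intense.sum()),
                 "tests": {}}
    if out["n_weak"] < 2 or out["n_intense"] < 2:
        out["flag"] = "intensity groups too small"
        return out
    for pet in PET_INDICES:
        vals = cohort.column(pet)
        a, b = vals[weak], vals[intense]
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if a.size == 0 or b.size == 0:
            out["tests"][pet] = {"missing": True, "reason": "empty group"}
            continue
        r = wilcoxon_rank_sum(a, b, method=config.ranksum_method)
        out["tests"][pet] = _result_dict(
            r, median_weak=float(np.median(a)), median_intense=float(np.median(b))
        )
    return out


def outcome_associations(
    cohort: CohortTable, config: PipelineConfig | None = None
) -> dict:
    """Biomarkers compared between patients alive and dead at follow-up."""
    config = config or PipelineConfig()
    status = cohort.vital_status()
    alive = (status == "alive").to_numpy()
    dead = (status == "dead").to_numpy()
    if alive.sum() == 0 or dead.sum() == 0:
        raise InsufficientDataError("outcome comparison needs both survival classes")
    out: dict = {"n_alive": int(alive.sum()), "n_dead": int(dead.sum()), "tests": {}}
    for bio in BIOMARKERS:
        vals = cohort.column(bio)
        a, b = vals[alive], vals[dead]
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if a.size == 0 or b.size == 0:
            out["tests"][bio] = {"missing": True, "reason": "empty group"}
            continue
        try:
            r = wilcoxon_rank_sum(a, b, method=config.ranksum_method)
        except DegenerateDataError as exc:
            out["tests"][bio] = {"missing": True, "reason": str(exc)}
            continue
        out["tests"][bio] = _result_dict(
            r, median_alive=float(np.median(a)), median_dead=float(np.median(b))
        )
    return out


@dataclass
class AssociationReport:
    """Full output of one pipeline run (stable key schema)."""

    summary: dict
    correlations: dict
    median_split: dict
    vegf_groups: dict
    outcome: dict
    config: dict
    n_comparisons: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save_json(self, path: str | Path) -> None:
        write_results(self.to_dict(), path)

    @classmethod
    def from_json(cls, path: str | Path) -> "AssociationReport":
        with open(path) as fh:
            return cls(**json.load(fh))

    def render_table(self) -> str:
        """Human-readable correlation table mirroring the published layout."""
        lines = []
        header = ["biomarker"] + [_LABELS[p] for p in PET_INDICES]
        widths = [10] + [18] * len(PET_INDICES)
        lines.append("".join(h.ljust(w) for h, w in zip(header, widths)))
        lines.append("-" * sum(widths))
        for bio in BIOMARKERS:
            cells = [_LABELS[bio].ljust(widths[0])]
            for pet in PET_INDICES:
                cell = self.correlations[bio][pet]
                if cell is None or cell.get("missing"):
                    cells.append("n/a".ljust(18))
                else:
                    cells.append(
                        f"r={cell['rho']:+.3f} p={cell['p_value']:.3f}".ljust(18)
                    )
            lines.append("".join(cells))
        lines.append("")
        lines.append(f"comparisons performed (unadjusted): {self.n_comparisons}")
        return "\n".join(lines)


def run_pipeline(
    cohort: CohortTable | str | Path,
    config: PipelineConfig | None = None,
    *,
    out_json: str | Path | None = None,
    out_table: str | Path | None = None,
) -> AssociationReport:
    """Execute every analysis stage on a cohort (path or table) and
    optionally write the JSON report and a human-readable table.

    Deterministic for a fixed config/seed.
    """
    if not isinstance(cohort, CohortTable):
        cohort = load_cohort(cohort)
    config = config or PipelineConfig()

    report = AssociationReport(
        summary=summarize_cohort(cohort),
        correlations=correlation_matrix(cohort, config),
        median_split=median_split_associations(cohort, config),
        vegf_groups=vegf_group_associations(cohort, config),
        outcome=outcome_associations(cohort, config),
        config=dataclasses.asdict(config),
    )
    n = 0
    for row in report.correlations.values():
        n += sum(1 for c in row.values() if c and not c.get("missing"))
    for entry in report.median_split.values():
        n += sum(1 for c in entry.get("tests", {}).values() if not c.get("missing"))
    n += sum(1 for c in report.vegf_groups.get("tests", {}).values()
             if not c.get("missing"))
    n += sum(1 for c in report.outcome.get("tests", {}).values()
             if not c.get("missing"))
    report.n_comparisons = n

    if out_json is not None:
        report.save_json(out_json)
    if out_table is not None:
        Path(out_table).write_text(report.render_table() + "\n")
    return report
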