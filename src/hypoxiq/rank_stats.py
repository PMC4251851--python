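"""Rank-based statistics: midranks, Spearman correlation, Wilcoxon rank-sum.

Implemented from first principles rather than delegating to
``scipy.stats`` because the exact small-sample behaviour — midrank tie
handling, full-enumeration permutation null for Spearman, full-enumeration
rank-sum null with ties, two-sided p by tail doubling — is the contract of
this package (it must be auditable against brute-force oracles at the
15-patient study scale).  ``scipy`` is used only for distribution tail
functions (t, normal).

Conventions
-----------
* Two-sided p-values double the smaller tail and are capped at 1
  (classical SAS behaviour, no mid-p).
* Missing values (``None``/``NaN``) are removed pairwise before ranking.
* Spearman rho is the Pearson correlation of midranks; the default p-value
  is the t approximation on n-2 degrees of freedom (the default of the
  software used for the original analysis), with a seeded
  enumeration/Monte-Carlo permutation alternative.
* The exact Wilcoxon rank-sum null enumerates all C(n, n_a) group
  assignments of the pooled midranks (feasible at study scale,
  C(15,8) = 6435), honouring ties.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "CorrelationResult",
    "GroupComparisonResult",
    "InsufficientDataError",
    "DegenerateDataError",
    "midranks",
    "spearman",
    "wilcoxon_rank_sum",
    "dichotomize_by_median",
]

SpearmanMethod = Literal["t_approx", "exact_permutation"]
RankSumMethod = Literal["exact", "normal_approx_tie_corrected"]

# full enumeration limits: 8! = 40320 Spearman permutations,
# C(20,10) = 184756 rank-sum assignments
_SPEARMAN_ENUM_MAX_N = 8
_DEFAULT_MC_PERMUTATIONS = 10_000


class InsufficientDataError(ValueError):
    """Too few complete pairs/observations for the requested statistic."""


class DegenerateDataError(ValueError):
    """A variable has zero variance; the rank statistic is undefined."""


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman correlation with its p-value and the pairwise n used."""

    rho: float
    p_value: float
    n_pairs: int
    method: SpearmanMethod

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12):
            raise ValueError(f"|rho| > 1: {self.rho}")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value outside (0, 1]: {self.p_value}")


@dataclass(frozen=True)
class GroupComparisonResult:
    """Wilcoxon rank-sum comparison of two independent groups.

    ``statistic`` is the sum of pooled-sample midranks of group *a*.
    """

    statistic: float
    p_value: float
    n_a: int
    n_b: int
    method: RankSumMethod

    def __post_init__(self) -> None:
        if self.n_a < 1 or self.n_b < 1:
            raise ValueError("both group sizes must be >= 1")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value outside (0, 1]: {self.p_value}")


def _clean(values: Sequence) -> np.ndarray:
    arr = np.asarray(
        [np.nan if v is None else float(v) for v in np.ravel(values)], dtype=float
    )
    return arr


def midranks(values: Sequence[float]) -> np.ndarray:
    """Ranks 1..n with tied values receiving the mean of the ranks they span.

    The ranks always sum to n(n+1)/2 exactly (ties are averaged, and
    midranks of k tied values are multiples of 1/2).
    """
    arr = _clean(values)
    if arr.size == 0:
        raise InsufficientDataError("midranks of an empty sequence")
    if not np.all(np.isfinite(arr)):
        raise ValueError("midranks require finite values")
    order = np.argsort(arr, kind="stable")
    ranks = np.empty(arr.size, dtype=float)
    sorted_vals = arr[order]
    i = 0
    while i < arr.size:
        j = i
        while j + 1 < arr.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        # positions i..j (0-based) share ranks i+1..j+1 -> mean (i+j)/2 + 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _pairwise_complete(x: Sequence, y: Sequence) -> tuple[np.ndarray, np.ndarray]:
    xa, ya = _clean(x), _clean(y)
    if xa.shape != ya.shape:
        raise ValueError(f"length mismatch: {xa.size} vs {ya.size}")
    keep = np.isfinite(xa) & np.isfinite(ya)
    return xa[keep], ya[keep]


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    return float(rx @ ry) / denom


def spearman(
    x: Sequence,
    y: Sequence,
    method: SpearmanMethod = "t_approx",
    *,
    seed: int | None = None,
    n_permutations: int = _DEFAULT_MC_PERMUTATIONS,
) -> CorrelationResult:
    """Spearman rank correlation with pairwise deletion of missing entries.

    rho is the Pearson correlation of the midranks.  Two p-value methods:

    ``t_approx``
        two-sided p from t = rho * sqrt((n-2) / (1-rho^2)) on n-2 df.
        For perfectly monotone data (|rho| = 1) the t statistic diverges;
        the permutation probability of a perfectly monotone arrangement,
        2/n!, is reported instead.
    ``exact_permutation``
        permutation null of the y-ranks; full n! enumeration for n <= 8,
        otherwise seeded Monte-Carlo with an add-one correction.  Two-sided
        via |rho_perm| >= |rho_obs|.
    """
    xa, ya = _pairwise_complete(x, y)
    n = xa.size
    if n < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, got {n}")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise DegenerateDataError("zero variance: correlation undefined")
    rx, ry = midranks(xa), midranks(ya)
    rho = _rank_corr(rx, ry)
    rho = float(np.clip(rho, -1.0, 1.0))
    if math.isclose(abs(rho), 1.0, abs_tol=1e-12):
        rho = math.copysign(1.0, rho)

    if method == "t_approx":
        if abs(rho) == 1.0:
            p = min(1.0, 2.0 / math.factorial(n))
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * float(_sps.t.sf(abs(t), df=n - 2))
            p = min(1.0, max(p, np.finfo(float).tiny))
        return CorrelationResult(rho, p, n, "t_approx")

    if method == "exact_permutation":
        tol = 1e-12
        target = abs(rho) - tol
        if n <= _SPEARMAN_ENUM_MAX_N:
            total = math.factorial(n)
            hits = sum(
                abs(_rank_corr(rx, np.asarray(perm))) >= target
                for perm in itertools.permutations(ry)
            )
            p = hits / total
        else:
            rng = np.random.default_rng(seed)
            hits = 0
            for _ in range(n_permutations):
                perm = rng.permutation(ry)
                if abs(_rank_corr(rx, perm)) >= target:
                    hits += 1
            p = (hits + 1) / (n_permutations + 1)
        return CorrelationResult(rho, min(1.0, p), n, "exact_permutation")

    raise ValueError(f"unknown Spearman method: {method!r}")


# --- Wilcoxon rank-sum ------------------------------------------------------

def _ranksum_null_exact(pooled_ranks: np.ndarray, n_a: int):
    """Exact null distribution of the group-a rank sum over all C(n, n_a)
    equally likely assignments, as (support, counts) on doubled ranks.

    Dynamic program over items; 2*midrank is always an integer, so the
    doubled rank-sum support is exact integer arithmetic.
    """
    doubled = np.rint(2.0 * pooled_ranks).astype(np.int64)
    if not np.allclose(doubled, 2.0 * pooled_ranks, atol=1e-9):
        raise ValueError("midranks are not multiples of 1/2")
    n = doubled.size
    max_sum = int(doubled.sum())
    # dp[k, s] = number of k-subsets with doubled-rank sum s
    dp = np.zeros((n_a + 1, max_sum + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in doubled:
        upper = min(n_a, n)
        for k in range(upper - 1, -1, -1):
            row = dp[k]
            nz = np.nonzero(row)[0]
            if nz.size:
                dp[k + 1, nz + r] += row[nz]
    counts = dp[n_a]
    support = np.nonzero(counts)[0]
    return support, counts[support]


def wilcoxon_rank_sum(
    a: Sequence,
    b: Sequence,
    method: RankSumMethod = "exact",
) -> GroupComparisonResult:
    """Two-sample Wilcoxon rank-sum test with midrank tie handling.

    The statistic is the sum of group-*a* midranks in the pooled sample.
    ``exact`` enumerates the permutation null over all C(n_a+n_b, n_a)
    group assignments; ``normal_approx_tie_corrected`` uses the standard
    tie-corrected normal approximation with a 0.5 continuity correction.
    Two-sided p doubles the smaller tail, capped at 1.
    """
    aa = _clean(a)
    ba = _clean(b)
    aa = aa[np.isfinite(aa)]
    ba = ba[np.isfinite(ba)]
    n_a, n_b = aa.size, ba.size
    if n_a < 1 or n_b < 1:
        raise InsufficientDataError("both groups must be non-empty")
    pooled = np.concatenate([aa, ba])
    n = n_a + n_b
    ranks = midranks(pooled)
    w = float(ranks[:n_a].sum())

    if method == "exact":
        support, counts = _ranksum_null_exact(ranks, n_a)
        total = counts.sum()
        w2 = int(round(2.0 * w))
        lower = counts[support <= w2].sum() / total
        upper = counts[support >= w2].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
        return GroupComparisonResult(w, p, n_a, n_b, "exact")

    if method == "normal_approx_tie_corrected":
        mean = n_a * (n + 1) / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
        var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            # all pooled values identical: no evidence either way
            return GroupComparisonResult(w, 1.0, n_a, n_b, method)
        diff = w - mean
        # continuity correction toward the mean
        z = (diff - math.copysign(0.5, diff)) / math.sqrt(var) if diff != 0 else 0.0
        p = min(1.0, 2.0 * float(_sps.norm.sf(abs(z))))
        return GroupComparisonResult(w, p, n_a, n_b, method)

    raise ValueError(f"unknown rank-sum method: {method!r}")


def dichotomize_by_median(values: Sequence) -> tuple[np.ndarray, float]:
    """Split values at their median: LOW iff value <= median, HIGH otherwise.

    For even n the median is the midpoint of the two central order
    statistics.  Missing entries get the label ``None``.  Returns
    ``(labels, median)`` where labels is an object array of
    ``"low"``/``"high"``/``None``.

    A degenerate split (everyone LOW) is allowed and left to callers to flag.
    """
    arr = _clean(values)
    finite = arr[np.isfinite(arr)]
    if finite.size == 0:
        raise InsufficientDataError("all values missing")
    med = float(np.median(finite))
    labels = np.empty(arr.size, dtype=object)
    for i, v in enumerate(arr):
        if not math.isfinite(v):
            labels[i] = None
        else:
            labels[i] = "low" if v <= med else "high"
    return labels, med
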