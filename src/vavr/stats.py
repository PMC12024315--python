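"""Rank-based cohort statistics.

Paired (Wilcoxon signed-rank) and unpaired (Wilcoxon-Mann-Whitney) tests
with exact small-sample p-values, the relative effect p_rel as the effect
size, Benjamini-Hochberg multiplicity adjustment, and per-cell median
summaries of a cohort results table.

Exact p-values are computed from the full permutation distribution on
midranks (sign-flip distribution for the signed-rank test, subset
distribution for the rank-sum test), which handles ties correctly; large
samples fall back to the tie-corrected normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError

__all__ = [
    "StatResult",
    "relative_effect",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "bh_adjust",
    "summarize_cohort",
]

# exact-enumeration size limits; beyond these the normal approximation is used
_WSR_EXACT_MAX_N = 25
_MWU_EXACT_MAX_N = 40


@dataclass
class StatResult:
    """Outcome of one hypothesis test."""

    test: str
    statistic: float
    p_value: float
    relative_effect: float
    n1: int
    n2: int
    p_adjusted: float | None = None


def relative_effect(sample1, sample2) -> float:
    """Probability that a random value of sample2 exceeds one of sample1.

    Ties count one half:
    ``(#{x2 > x1} + 0.5 * #{x2 == x1}) / (n1 * n2)`` over all cross pairs.
    0.5 means stochastic equality; values above 0.5 mean sample2 tends to
    be larger.
    """
    x1 = np.asarray(sample1, dtype=float)
    x2 = np.asarray(sample2, dtype=float)
    if x1.size == 0 or x2.size == 0:
        raise InputError("relative_effect requires two nonempty samples")
    diff = x2[:, None] - x1[None, :]
    greater = np.count_nonzero(diff > 0)
    ties = np.count_nonzero(diff == 0)
    return (greater + 0.5 * ties) / (x1.size * x2.size)


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _signflip_counts(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of each doubled rank-sum over all 2^n sign assignments."""
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(x, y) -> StatResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    The statistic W is the sum of the ranks (midranks under ties) of the
    absolute differences ``y - x`` for pairs where y > x; zero differences
    are dropped before ranking.  The p-value is exact (full sign-flip
    distribution on midranks) for up to 25 nonzero pairs, otherwise the
    tie-aware normal approximation is used.  With all differences zero the
    test degenerates to W = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("paired samples must be 1-D and of equal length")
    d = y - x
    d = d[d != 0]
    n = d.size
    p_rel = relative_effect(x, y)
    if n == 0:
        return StatResult("wilcoxon_signed_rank", 0.0, 1.0, p_rel,
                          x.size, y.size)
    ranks = _midranks(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= _WSR_EXACT_MAX_N:
        doubled = np.rint(2 * ranks).astype(int)
        counts = _signflip_counts(doubled)
        total = counts.sum()
        w2 = int(round(2 * w))
        p_le = counts[: w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mean = ranks.sum() / 2.0
        sd = np.sqrt(np.sum(ranks ** 2) / 4.0)
        z = (w - mean) / sd
        p = 2.0 * sps.norm.sf(abs(z))
    return StatResult("wilcoxon_signed_rank", w, float(p), p_rel,
                      x.size, y.size)


def _subset_counts(doubled_ranks: np.ndarray, k: int) -> np.ndarray:
    """Counts of doubled rank-sums over all size-k subsets of the pool."""
    total = int(doubled_ranks.sum())
    f = np.zeros((k + 1, total + 1))
    f[0, 0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        # iterate subset size downwards to add each item once
        for size in range(k, 0, -1):
            f[size, r:] += f[size - 1, : total + 1 - r]
    return f[k]


def mann_whitney_u(sample1, sample2) -> StatResult:
    """Two-sided Wilcoxon-Mann-Whitney test on independent samples.

    The reported statistic is ``U = #{x2 > x1} + 0.5 * #ties`` over all
    cross pairs, so ``U / (n1 * n2)`` equals the relative effect and
    ``U + U' = n1 * n2``.  The p-value is exact (full subset permutation
    distribution on pooled midranks) for pooled sizes up to 40, otherwise
    the tie-corrected normal approximation is used.
    """
    x1 = np.asarray(sample1, dtype=float)
    x2 = np.asarray(sample2, dtype=float)
    if x1.size == 0 or x2.size == 0:
        raise InputError("mann_whitney_u requires two nonempty samples")
    n1, n2 = x1.size, x2.size
    p_rel = relative_effect(x1, x2)
    u = p_rel * n1 * n2
    mid = n1 * n2 / 2.0
    pooled = np.concatenate([x1, x2])
    ranks = _midranks(pooled)
    if n1 + n2 <= _MWU_EXACT_MAX_N:
        doubled = np.rint(2 * ranks).astype(int)
        counts = _subset_counts(doubled, n2)
        total = counts.sum()
        # map each achievable doubled rank-sum back to a U value
        sums2 = np.nonzero(counts)[0]
        u_vals = sums2 / 2.0 - n2 * (n2 + 1) / 2.0
        extreme = np.abs(u_vals - mid) >= abs(u - mid) - 1e-9
        p = float(counts[sums2][extreme].sum() / total)
    else:
        nn = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(tie_counts ** 3 - tie_counts) / (nn * (nn - 1))
        var = n1 * n2 / 12.0 * ((nn + 1) - tie_term)
        if var == 0:
            p = 1.0
        else:
            z = (u - mid) / np.sqrt(var)
            p = float(2.0 * sps.norm.sf(abs(z)))
    return StatResult("mann_whitney_u", float(u), min(1.0, p), p_rel, n1, n2)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sort ascending, scale ``p_(i) * m / i``, enforce monotonicity from the
    largest rank down, cap at 1, and restore the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InputError("bh_adjust expects a nonempty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


_KEY_COLS = ("patient_id", "size_class", "state")


def summarize_cohort(results: pd.DataFrame,
                     metrics: list[str] | None = None) -> pd.DataFrame:
    """Per-(metric, size class, state) medians of a cohort results table.

    Parameters
    ----------
    results : DataFrame
        Long-format table with columns ``patient_id``, ``size_class``,
        ``state`` and one column per metric.
    metrics : list of str, optional
        Metric columns to summarize; default: every numeric non-key
        column present.

    Returns
    -------
    DataFrame
        Columns ``metric, size_class, state, median, n``.  The even-n
        median is the mean of the two central values (numpy convention).

    Raises
    ------
    InputError
        If a (size_class, state) cell is missing or the cells are
        unbalanced, naming the offending cell.
    """
    for col in _KEY_COLS:
        if col not in results.columns:
            raise InputError(f"results table missing column '{col}'")
    if metrics is None:
        metrics = [c for c in results.columns
                   if c not in _KEY_COLS
                   and pd.api.types.is_numeric_dtype(results[c])]
    if not metrics:
        raise InputError("no metric columns to summarize")
    sizes = sorted(results["size_class"].unique())
    states = sorted(results["state"].unique())
    n_patients = results["patient_id"].nunique()
    rows = []
    for metric in metrics:
        if metric not in results.columns:
            raise InputError(f"results table missing metric column '{metric}'")
        for size in sizes:
            for state in states:
                cell = results[(results["size_class"] == size)
                               & (results["state"] == state)][metric].dropna()
                if len(cell) != n_patients:
                    raise InputError(
                        f"cell (metric={metric}, size_class={size}, "
                        f"state={state}) has {len(cell)} values, "
                        f"expected {n_patients}")
                rows.append({"metric": metric, "size_class": size,
                             "state": state,
                             "median": float(np.median(cell.to_numpy())),
                             "n": int(len(cell))})
    return pd.DataFrame(rows)
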