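"""Class-wise medians, signed fold-changes and Wilcoxon rank-sum testing.

Per-cell total intensities V are grouped by cell class; each non-reference
class is compared to the reference by the ratio of class medians, reported
with the signed-reciprocal convention (fold = +r for r ≥ 1, −1/r for
r < 1, so |fold| ≥ 1 and the sign encodes direction), and by a two-sided
Wilcoxon rank-sum (Mann–Whitney) test of the equality of the two samples'
medians. Significance stars follow the usual convention: ** for p < 0.01,
* for 0.01 ≤ p < 0.05, NS otherwise.

The exact null distribution of the rank-sum statistic is enumerated by
dynamic programming (counts of size-m subsets of ranks {1..N} by sum) when
the pooled sample is small (N ≤ 20) and tie-free; otherwise a normal
approximation with midranks, tie-corrected variance and continuity
correction is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .quantify import QuantTable

__all__ = [
    "GroupComparison",
    "ReplicateSummary",
    "class_median",
    "fold_change",
    "wilcoxon_rank_sum",
    "rank_sum_null_distribution",
    "stars_for",
    "compare_classes",
    "experiment_comparisons",
    "aggregate_replicates",
    "comparisons_to_frame",
    "summaries_to_frame",
    "EXACT_POOLED_LIMIT",
]

#: exact enumeration is used up to this pooled sample size (tie-free data)
EXACT_POOLED_LIMIT = 20


@dataclass
class GroupComparison:
    """One class-vs-reference comparison of total-intensity distributions."""

    class_label: str
    reference_label: str
    median_class: float
    median_ref: float
    ratio: float
    fold_change: float
    p_value: float
    stars: str
    n_class: int
    n_ref: int


@dataclass
class ReplicateSummary:
    """Mean ± sample SD of a class's fold-change across experiments."""

    class_label: str
    mean_fold: float
    sd_fold: float
    n_experiments: int


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, QuantTable):
        return records.to_frame()
    if isinstance(records, pd.DataFrame):
        return records
    return QuantTable(records=list(records)).to_frame()


def class_median(records, class_label: str) -> float:
    """Median V of a class; even n averages the two central order statistics."""
    frame = _as_frame(records)
    values = frame.loc[frame["class_label"] == class_label, "V"].to_numpy()
    if values.size == 0:
        raise KeyError(f"no records for class {class_label!r}")
    return float(np.median(values))


def fold_change(median_class: float, median_ref: float) -> float:
    """Signed-reciprocal fold: +r if r = class/ref ≥ 1, else −1/r."""
    if median_class <= 0 or median_ref <= 0:
        raise ValueError("medians must be positive for a fold-change")
    r = median_class / median_ref
    return r if r >= 1.0 else -1.0 / r


def rank_sum_null_distribution(m: int, n: int) -> np.ndarray:
    """Counts of size-m subsets of {1..N}, N=m+n, by rank sum.

    Index w of the returned array is the rank sum (0..N(N+1)/2); entries
    sum to C(N, m). This is the exact null distribution of W = Σ ranks of
    the first sample under random rank assignment.
    """
    N = m + n
    max_sum = N * (N + 1) // 2
    f = np.zeros((m + 1, max_sum + 1), dtype=np.float64)
    f[0, 0] = 1.0
    for r in range(1, N + 1):
        for j in range(min(r, m), 0, -1):
            f[j, r:] += f[j - 1, : max_sum + 1 - r]
    return f[m]


def _exact_p(w: int, m: int, n: int) -> float:
    dist = rank_sum_null_distribution(m, n)
    total = comb(m + n, m)
    cdf = np.cumsum(dist)
    lo = cdf[w] / total                      # P(W ≤ w)
    hi = (total - (cdf[w] - dist[w])) / total  # P(W ≥ w)
    return min(1.0, 2.0 * min(lo, hi))


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float],
                      mode: str = "auto") -> float:
    """Two-sided p-value of the Wilcoxon rank-sum test.

    ``mode='auto'`` enumerates the exact null distribution when the pooled
    sample has at most ``EXACT_POOLED_LIMIT`` observations and no ties,
    otherwise uses the normal approximation with midranks, tie-corrected
    variance and continuity correction. ``mode='exact'`` forces enumeration
    (and rejects tied data); ``mode='normal'`` forces the approximation.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    pooled = np.concatenate([a, b])
    m, n = a.size, b.size
    N = m + n
    has_ties = np.unique(pooled).size < N

    if mode == "exact" and has_ties:
        raise ValueError("exact mode requires tie-free samples")
    use_exact = mode == "exact" or (
        mode == "auto" and N <= EXACT_POOLED_LIMIT and not has_ties
    )
    ranks = rankdata(pooled)  # midranks under ties
    w = float(ranks[:m].sum())
    if use_exact:
        return _exact_p(int(round(w)), m, n)

    mean = m * (N + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts))
    var = m * n / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:  # all observations identical
        return 1.0
    d = abs(w - mean)
    z = max(d - 0.5, 0.0) / np.sqrt(var)  # continuity correction
    p = 2.0 * norm.sf(z)
    return float(min(1.0, p))


def stars_for(p: float) -> str:
    """Significance label: ``**`` for p < 0.01, ``*`` for p < 0.05, else NS."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def compare_classes(records, reference_label: str,
                    mode: str = "auto") -> list[GroupComparison]:
    """One :class:`GroupComparison` per non-reference class in the records.

    Classes are compared in first-appearance order of the input table.
    """
    frame = _as_frame(records)
    if not (frame["class_label"] == reference_label).any():
        raise ValueError(f"reference class {reference_label!r} has no records")
    ref_v = frame.loc[frame["class_label"] == reference_label, "V"].to_numpy()
    median_ref = float(np.median(ref_v))
    out: list[GroupComparison] = []
    for label in frame["class_label"].unique():
        if label == reference_label:
            continue
        cls_v = frame.loc[frame["class_label"] == label, "V"].to_numpy()
        median_cls = float(np.median(cls_v))
        p = wilcoxon_rank_sum(cls_v, ref_v, mode=mode)
        out.append(
            GroupComparison(
                class_label=str(label),
                reference_label=reference_label,
                median_class=median_cls,
                median_ref=median_ref,
                ratio=median_cls / median_ref,
                fold_change=fold_change(median_cls, median_ref),
                p_value=p,
                stars=stars_for(p),
                n_class=int(cls_v.size),
                n_ref=int(ref_v.size),
            )
        )
    return out


def experiment_comparisons(records, reference_label: str,
                           mode: str = "auto") -> dict[str, list[GroupComparison]]:
    """Per-experiment class comparisons (cells pooled across scenes within
    each (class, experiment) before testing)."""
    frame = _as_frame(records)
    out: dict[str, list[GroupComparison]] = {}
    for exp in frame["experiment_id"].unique():
        out[str(exp)] = compare_classes(
            frame[frame["experiment_id"] == exp], reference_label, mode=mode
        )
    return out


def aggregate_replicates(
    comparisons_by_experiment: Sequence[Sequence[GroupComparison]],
) -> list[ReplicateSummary]:
    """Mean and sample SD (n−1) of fold-change per class across experiments."""
    if len(comparisons_by_experiment) == 0:
        raise ValueError("need at least one experiment")
    class_order = [c.class_label for c in comparisons_by_experiment[0]]
    folds: dict[str, list[float]] = {lbl: [] for lbl in class_order}
    for comps in comparisons_by_experiment:
        labels = [c.class_label for c in comps]
        if set(labels) != set(class_order):
            raise ValueError(
                f"inconsistent class sets across experiments: "
                f"{sorted(labels)} vs {sorted(class_order)}"
            )
        for c in comps:
            folds[c.class_label].append(c.fold_change)
    out: list[ReplicateSummary] = []
    for lbl in class_order:
        vals = np.asarray(folds[lbl])
        if vals.size == 1:
            warnings.warn(
                f"single experiment for class {lbl!r}: SD undefined, reported as 0",
                stacklevel=2,
            )
            sd = 0.0
        else:
            sd = float(np.std(vals, ddof=1))
        out.append(ReplicateSummary(
            class_label=lbl,
            mean_fold=float(vals.mean()),
            sd_fold=sd,
            n_experiments=int(vals.size),
        ))
    return out


def comparisons_to_frame(comparisons: Iterable[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in comparisons])


def summaries_to_frame(summaries: Iterable[ReplicateSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])
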