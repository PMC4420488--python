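"""Summary metrics for deviation of normalized reads from expectation.

The working quantity is the per-sequence ratio normalized_reads / expected.
A library with no representation bias has every ratio at 1; real single-
sequence-adaptor libraries show spreads of several orders of magnitude. The
headline numbers are the percentage of sequences within 2-fold of expectation
(ratio in [0.5, 2]) and the percentage more than 10-fold under-represented
(ratio < 0.1, zero included).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


@dataclass
class BiasReport:
    pct_within_2fold: float
    pct_over_10fold_under: float
    pct_other: float
    log10_spread: float  # NaN when fewer than 2 positive ratios
    n_sequences: int
    group_breakdown: dict = field(default_factory=dict)
    comparisons: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "pct_within_2fold": self.pct_within_2fold,
            "pct_over_10fold_under": self.pct_over_10fold_under,
            "pct_other": self.pct_other,
            "log10_spread": None if math.isnan(self.log10_spread) else self.log10_spread,
            "n_sequences": self.n_sequences,
            "group_breakdown": self.group_breakdown,
            "comparisons": self.comparisons,
        }


def fold_deviation_metrics(ratios: Sequence[float]) -> BiasReport:
    """Partition expectation ratios into within-2-fold / >10-fold-under / other.

    Boundaries: within 2-fold is the closed interval [0.5, 2]; >10-fold under
    is strict r < 0.1, with ratio 0 (zero reads) counted there as the limit of
    under-representation. The log10 spread covers positive ratios only.
    """
    r = np.asarray(list(ratios), dtype=float)
    if r.size == 0:
        raise ValueError("no ratios supplied")
    if (r < 0).any():
        raise ValueError("ratios must be non-negative")
    n = r.size
    within = ((r >= 0.5) & (r <= 2.0)).sum()
    under = (r < 0.1).sum()
    other = n - within - under
    pos = r[r > 0]
    spread = (
        float(np.log10(pos.max()) - np.log10(pos.min())) if pos.size >= 2 else math.nan
    )
    return BiasReport(
        pct_within_2fold=100.0 * within / n,
        pct_over_10fold_under=100.0 * under / n,
        pct_other=100.0 * other / n,
        log10_spread=spread,
        n_sequences=int(n),
    )


def compare_distributions(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-tailed Mann-Whitney p for two ratio sets.

    Exact null distribution for small groups (n <= 8 each, no ties across the
    pooled sample); otherwise the normal approximation with average-rank tie
    correction.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    small = a.size <= 8 and b.size <= 8
    method = "exact" if (small and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def replicate_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation of paired normalized reads."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValueError("replicate vectors must be paired")
    if x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a replicate vector")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


def replicate_discrepancy(x: Sequence[float], y: Sequence[float]) -> float:
    """Percent of sequences whose replicate values disagree >= 2-fold.

    Pairs where both values are 0 are excluded; a pair with exactly one zero
    is discrepant by definition (infinite fold change).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValueError("replicate vectors must be paired")
    keep = ~((x == 0) & (y == 0))
    if not keep.any():
        raise ValueError("no pairs with a nonzero value")
    x, y = x[keep], y[keep]
    hi = np.maximum(x, y)
    lo = np.minimum(x, y)
    with np.errstate(divide="ignore"):
        fold = np.where(lo > 0, hi / lo, np.inf)
    return float(100.0 * (fold >= 2.0).sum() / x.size)


def grouped_deviation(
    ratios: Mapping[str, float], groups: Mapping[str, int]
) -> dict[int, BiasReport]:
    """Fold-deviation metrics per group (e.g. by number of unfavorable attributes)."""
    by_group: dict[int, list[float]] = {}
    for seq_id, g in groups.items():
        if seq_id in ratios:
            by_group.setdefault(g, []).append(ratios[seq_id])
    return {g: fold_deviation_metrics(v) for g, v in sorted(by_group.items())}
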