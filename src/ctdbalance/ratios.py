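"""The K7me/K7ac promoter ratio statistic and its group comparisons.

The per-gene ratio is the quotient of depth-scaled promoter read counts of
a K7 methylation mark over K7 acetylation (both per 10 million mapped
tags). Genes are stratified into low/medium/high ratio tertiles; groups are
compared by Wilcoxon rank-sum tests on marks or expression, and by a 2x2
Fisher's exact test of TSA (deacetylase-inhibitor) response for the high
versus low groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import scale_per_10M

__all__ = [
    "k7_ratio",
    "ratio_table",
    "ratio_tertiles",
    "wilcoxon_rank_sum",
    "tsa_contingency",
    "ContingencyResult",
]


def k7_ratio(me_count: float, ac_count: float, me_total: int, ac_total: int) -> float:
    """(me per 10M) / (ac per 10M); NaN when the acetylation count is zero."""
    if me_count < 0 or ac_count < 0:
        raise ValueError("counts must be non-negative")
    if ac_count == 0:
        return float("nan")
    return scale_per_10M(me_count, me_total) / scale_per_10M(ac_count, ac_total)


def ratio_table(
    me_counts: pd.Series, ac_counts: pd.Series, me_total: int, ac_total: int
) -> pd.DataFrame:
    """Per-gene ratios with tertile labels (RatioRecord table)."""
    me_counts, ac_counts = me_counts.align(ac_counts, join="inner")
    ratios = pd.Series(
        [k7_ratio(m, a, me_total, ac_total) for m, a in zip(me_counts, ac_counts)],
        index=me_counts.index,
        name="ratio",
    )
    labels = ratio_tertiles(ratios)
    return pd.DataFrame({"ratio": ratios, "quantile": labels})


def ratio_tertiles(ratios: pd.Series) -> pd.Series:
    """Rank-based thirds: low / medium / high by ascending ratio.

    Ties are broken by stable input order; group sizes differ by at most
    one, with any remainder assigned from the low group upward. Non-finite
    ratios get the label NA.
    """
    ratios = pd.Series(ratios)
    finite = ratios[np.isfinite(ratios)]
    if len(finite) < 3:
        raise ValueError("need at least 3 finite ratios to form tertiles")
    order = np.argsort(finite.to_numpy(), kind="stable")
    n = len(finite)
    sizes = [n // 3 + (1 if i < n % 3 else 0) for i in range(3)]
    labels = np.empty(n, dtype=object)
    names = ["low", "medium", "high"]
    start = 0
    for name, size in zip(names, sizes):
        labels[order[start : start + size]] = name
        start += size
    out = pd.Series("NA", index=ratios.index, name="quantile", dtype=object)
    out[finite.index] = labels
    return out


def wilcoxon_rank_sum(group_a, group_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null enumeration when the smaller group has <= 10 observations
    and there are no ties; otherwise the normal approximation with
    tie-corrected variance and continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(min(1.0, res.pvalue))


@dataclass
class ContingencyResult:
    """2x2 ratio-group x TSA-response table with Fisher's exact test.

    Rows are (high, low) ratio groups, columns (up, down) regulation. The
    odds ratio is the sample cross-product a*d / (b*c); when b*c = 0 it is
    reported as inf (or NaN for an empty margin).
    """

    table: np.ndarray
    odds_ratio: float
    p_two_sided: float
    n_genes: int


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test by the probability-mass method
    (sum of hypergeometric probabilities <= that of the observed table)."""
    table = np.asarray(table, dtype=np.int64)
    if table.min() < 0:
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("empty margin: Fisher p undefined")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def tsa_contingency(
    fold_changes: pd.Series,
    quantiles: pd.Series,
    min_fold: float = 2.0,
) -> ContingencyResult:
    """High-vs-low ratio contingency of TSA response.

    Genes with fold change >= min_fold count as up, <= 1/min_fold as down;
    all others are excluded (the paper's symmetric 2-fold cut). The 2x2
    table is [[high_up, high_down], [low_up, low_down]].
    """
    fold_changes, quantiles = fold_changes.align(quantiles, join="inner")
    up = fold_changes >= min_fold
    down = fold_changes <= 1.0 / min_fold
    rows = []
    for grp in ("high", "low"):
        in_grp = quantiles == grp
        rows.append([int((in_grp & up).sum()), int((in_grp & down).sum())])
    table = np.array(rows, dtype=np.int64)
    odds, p = fisher_exact_2x2(table)
    return ContingencyResult(table, odds, p, int(table.sum()))
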