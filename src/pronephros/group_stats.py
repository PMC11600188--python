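"""Between-group testing of profile summaries.

Groups (e.g. toxin exposure levels) are compared per metric with the
Kruskal-Wallis test across all groups, followed by all pairwise two-sided
Wilcoxon rank-sum tests with Bonferroni adjustment over the pairs of that
metric.  Group sizes in this assay are small (around nine fish per group),
so pairwise p-values are exact whenever both groups have <= 10 values and
no ties; the tie-corrected normal approximation is used otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PairwiseResult", "GroupComparison", "compare_groups"]

ALPHA = 0.05
EXACT_MAX_N = 10


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    u_statistic: float
    p_raw: float
    p_adjusted: float
    significant: bool
    method: str


@dataclass
class GroupComparison:
    metric: str
    groups: list
    n_per_group: dict
    h_statistic: float
    kruskal_p: float
    pairwise: list
    n_comparisons: int

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "groups": list(self.groups),
            "n_per_group": dict(self.n_per_group),
            "kruskal_wallis": {"H": self.h_statistic, "p": self.kruskal_p},
            "n_comparisons": self.n_comparisons,
            "pairwise": [
                {
                    "groups": [p.group_a, p.group_b],
                    "U": p.u_statistic,
                    "p_raw": p.p_raw,
                    "p_adjusted": p.p_adjusted,
                    "significant": p.significant,
                    "method": p.method,
                }
                for p in self.pairwise
            ],
        }


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Exact for small tie-free samples, tie-corrected normal approximation
    otherwise (without continuity correction, matching the classical
    rank-sum test).
    """
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    if not ties and max(len(a), len(b)) <= EXACT_MAX_N:
        method = "exact"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        method = "asymptotic"
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return float(res.statistic), float(res.pvalue), method


def compare_groups(
    data: pd.DataFrame | dict,
    metric: str = "value",
    group_col: str = "group",
    alpha: float = ALPHA,
) -> GroupComparison:
    """Kruskal-Wallis plus Bonferroni-adjusted pairwise rank-sum tests.

    Parameters
    ----------
    data : DataFrame with ``group_col`` and ``metric`` columns, or a mapping
        ``{group_label: values}``.
    metric : name of the value column (and of the comparison in the report).

    Requires >= 2 groups, each with >= 2 values.  Deterministic.
    """
    if isinstance(data, dict):
        groups = {str(k): np.asarray(v, dtype=float) for k, v in data.items()}
    else:
        if group_col not in data or metric not in data:
            raise ValueError(f"data needs columns {group_col!r} and {metric!r}")
        groups = {
            str(g): sub[metric].to_numpy(dtype=float)
            for g, sub in data.groupby(group_col, sort=True)
        }
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for label, values in groups.items():
        if len(values) < 2:
            raise ValueError(f"group {label!r} has < 2 values")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"group {label!r} contains non-finite values")

    labels = list(groups)
    samples = [groups[l] for l in labels]
    try:
        h_stat, kw_p = stats.kruskal(*samples)
    except ValueError:
        # all pooled values identical: no evidence against exchangeability
        h_stat, kw_p = 0.0, 1.0

    pairs = list(itertools.combinations(labels, 2))
    m = len(pairs)
    pairwise = []
    for ga, gb in pairs:
        u, p_raw, method = _rank_sum_p(groups[ga], groups[gb])
        p_adj = min(1.0, m * p_raw)
        pairwise.append(
            PairwiseResult(
                group_a=ga,
                group_b=gb,
                u_statistic=u,
                p_raw=p_raw,
                p_adjusted=p_adj,
                significant=p_adj < alpha,
                method=method,
            )
        )
    return GroupComparison(
        metric=metric,
        groups=labels,
        n_per_group={l: int(len(groups[l])) for l in labels},
        h_statistic=float(h_stat),
        kruskal_p=float(kw_p),
        pairwise=pairwise,
        n_comparisons=m,
    )
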