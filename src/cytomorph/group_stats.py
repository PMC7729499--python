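"""Group statistics for per-cell descriptor tables.

Reporting layer used to compare substrate/timepoint/serum groups: percent
change versus a control group, one-way ANOVA, Dunn's rank-based multiple
comparison test, Pearson correlation, and boxplot five-number summaries with
Tukey outlier flagging.

Dunn's test ranks all observations jointly (mid-ranks for ties) and compares
pairs of groups by

    z_ij = (Rbar_i - Rbar_j) / sqrt( (N(N+1)/12 - T) * (1/n_i + 1/n_j) )

with the tie correction ``T = sum(t^3 - t) / (12 (N - 1))`` over tied value
groups; two-sided p-values come from the normal distribution and are
adjusted by Bonferroni (default) or Holm.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "ComparisonResult",
    "BoxplotSummary",
    "percent_change",
    "one_way_anova",
    "dunn_test",
    "pearson_correlation",
    "boxplot_summary",
    "plot_boxplots",
    "significance_stars",
]


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int


@dataclass
class ComparisonResult:
    """Pairwise post-hoc comparisons with an omnibus one-way ANOVA."""

    pairs: pd.DataFrame  # columns: group_i, group_j, z, p_raw, p_adj
    omnibus_f: float
    omnibus_p: float
    n_per_group: dict[str, int]
    adjustment: str


@dataclass
class BoxplotSummary:
    """Five-number boxplot summary with Tukey 1.5*IQR outlier flagging.

    Quartiles use linear interpolation between order statistics; whiskers
    extend to the most extreme observations within 1.5*IQR of the quartiles.
    """

    n: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[float]

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def percent_change(
    group_mean: float, control_mean: float, direction: str = "reduction"
) -> float:
    """Percent change of a group versus control, in the reporting convention.

    ``reduction`` returns ``(control - group) / control * 100`` (how much the
    descriptor dropped relative to control); ``increase`` returns
    ``(group - control) / control * 100``.
    """
    if control_mean == 0:
        raise ValueError("control mean must be nonzero")
    if direction == "reduction":
        return (control_mean - group_mean) / control_mean * 100.0
    if direction == "increase":
        return (group_mean - control_mean) / control_mean * 100.0
    raise ValueError("direction must be 'reduction' or 'increase'")


def _as_groups(groups: Sequence[np.ndarray]) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float).ravel() for g in groups]
    for g in out:
        if not np.all(np.isfinite(g)):
            raise ValueError("group values must be finite")
    return out


def one_way_anova(groups: Sequence[np.ndarray]) -> AnovaResult:
    """Standard one-way fixed-effects ANOVA across two or more groups."""
    gs = _as_groups(groups)
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    n_total = sum(len(g) for g in gs)
    grand = np.concatenate(gs).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b = len(gs) - 1
    df_w = n_total - len(gs)
    if ss_within == 0 and ss_between == 0:
        return AnovaResult(0.0, 1.0, df_b, df_w)
    if ss_within == 0:
        raise ValueError(
            "degenerate data: zero within-group variance in every group"
        )
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), p, df_b, df_w)


def _adjust_p(p_raw: np.ndarray, method: str) -> np.ndarray:
    m = len(p_raw)
    if method == "bonferroni":
        return np.minimum(p_raw * m, 1.0)
    if method == "holm":
        order = np.argsort(p_raw)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p_raw[idx])
            adj[idx] = min(running, 1.0)
        return adj
    raise ValueError("adjustment must be 'bonferroni' or 'holm'")


def dunn_test(
    groups: Sequence[np.ndarray],
    labels: Sequence[str] | None = None,
    adjustment: str = "bonferroni",
) -> ComparisonResult:
    """Dunn's multiple-comparison test on jointly ranked observations."""
    gs = _as_groups(groups)
    if any(len(g) == 0 for g in gs):
        raise ValueError("every group must contain at least one observation")
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(gs))]
    if len(labels) != len(gs):
        raise ValueError("labels length must match the number of groups")
    pooled = np.concatenate(gs)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)  # mid-ranks for ties
    mean_ranks = []
    start = 0
    for g in gs:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        start += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for i, j in combinations(range(len(gs)), 2):
        se = np.sqrt(base_var * (1.0 / len(gs[i]) + 1.0 / len(gs[j])))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p = float(2.0 * sps.norm.sf(abs(z)))
        rows.append({"group_i": labels[i], "group_j": labels[j], "z": z, "p_raw": p})
    pairs = pd.DataFrame(rows, columns=["group_i", "group_j", "z", "p_raw"])
    pairs["p_adj"] = _adjust_p(pairs["p_raw"].to_numpy(), adjustment)
    try:
        omnibus = one_way_anova(gs)
        of, op = omnibus.f_statistic, omnibus.p_value
    except ValueError:  # e.g. a group of size 1: post-hoc still defined
        of, op = float("nan"), float("nan")
    return ComparisonResult(
        pairs=pairs,
        omnibus_f=of,
        omnibus_p=op,
        n_per_group={lab: len(g) for lab, g in zip(labels, gs)},
        adjustment=adjustment,
    )


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson's r and its two-sided p-value (t transform)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def boxplot_summary(values: np.ndarray) -> BoxplotSummary:
    """Median, quartiles, whiskers and explicit outliers for one sample."""
    v = np.asarray(values, dtype=float).ravel()
    if len(v) == 0:
        raise ValueError("empty input")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])  # linear interpolation
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = sorted(v[(v < lo_fence) | (v > hi_fence)].tolist())
    return BoxplotSummary(
        n=len(v),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=outliers,
    )


def plot_boxplots(
    groups: Sequence[np.ndarray],
    labels: Sequence[str],
    path: str,
    ylabel: str = "",
    title: str = "",
) -> None:
    """Write a boxplot figure (PNG/SVG by extension); outliers drawn as red
    circles, whiskers at 1.5*IQR, matching :func:`boxplot_summary`."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 + 0.9 * len(groups), 3.2))
    ax.boxplot(
        [np.asarray(g, dtype=float).ravel() for g in groups],
        tick_labels=list(labels),
        whis=1.5,
        flierprops={"marker": "o", "markerfacecolor": "red", "markersize": 4},
    )
    ax.set_ylabel(ylabel)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def significance_stars(p: float) -> str:
    """Figure-legend star annotation for a p-value.

    ``*`` p<0.05, ``**`` p<0.01, ``***`` p<0.005, ``****`` p<0.0001,
    ``ns`` otherwise.
    """
    if p < 0.0001:
        return "****"
    if p < 0.005:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
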