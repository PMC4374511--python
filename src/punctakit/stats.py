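"""Group summaries and pairwise two-sample comparisons.

Reporting layer for per-animal PN/SE metrics: per-genotype mean ± SD with
sample size, and pairwise Student's t-tests with the conventional
significance labels (** for p < 0.01, * for p < 0.05, NS otherwise).
Comparisons are two-sided; the default t statistic pools variances
(classical Student), with Welch's unequal-variance form as an option. No
multiple-testing correction is applied — comparisons are reported pairwise
as is customary for per-panel genotype contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "PairwiseTest",
    "significance_label",
    "summarize_group",
    "compare_groups",
    "summarize_frame",
    "compare_frame",
]


@dataclass(frozen=True)
class GroupSummary:
    genotype: str
    metric: str
    n: int
    mean: float
    sd: float


@dataclass(frozen=True)
class PairwiseTest:
    group_a: str
    group_b: str
    t_stat: float
    df: float
    p_value: float
    label: str


def significance_label(p: float, star=0.05, double_star=0.01) -> str:
    """Map a p-value to its figure label (pure function of the thresholds)."""
    if not np.isfinite(p):
        return "NS"
    if p < double_star:
        return "**"
    if p < star:
        return "*"
    return "NS"


def summarize_group(values, genotype: str = "", metric: str = "") -> GroupSummary:
    """Mean ± sample SD (n − 1 denominator) of one group; requires n >= 2."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("at least two animals are required for mean ± SD")
    constant = bool(np.all(x == x[0]))
    return GroupSummary(
        genotype=genotype,
        metric=metric,
        n=int(x.size),
        mean=float(x[0]) if constant else float(x.mean()),
        sd=0.0 if constant else float(x.std(ddof=1)),
    )


def compare_groups(a, b, variant: str = "pooled", group_a: str = "a", group_b: str = "b") -> PairwiseTest:
    """Two-sided two-sample t-test between groups ``a`` and ``b``.

    ``variant="pooled"`` (default) is the classical equal-variance Student
    test with df = n_a + n_b − 2; ``variant="welch"`` uses the
    Welch–Satterthwaite form. Two identical zero-variance groups are the
    degenerate no-evidence case and report t = 0, p = 1.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two values")
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")

    if np.all(x == x[0]) and np.all(y == y[0]):
        df = float(x.size + y.size - 2)
        if x[0] == y[0]:
            t, p = 0.0, 1.0
        else:
            t = float(np.inf) if x[0] > y[0] else float(-np.inf)
            p = 0.0
        return PairwiseTest(group_a, group_b, t, df, p, significance_label(p))

    res = sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
    t = float(res.statistic)
    p = float(res.pvalue)
    df = float(res.df)
    return PairwiseTest(group_a, group_b, t, df, p, significance_label(p))


def summarize_frame(quant: pd.DataFrame, metric: str, group_col: str = "genotype") -> pd.DataFrame:
    """Per-group summaries of one metric column of a per-animal table."""
    rows = []
    for name, grp in quant.groupby(group_col, sort=False):
        vals = grp[metric].dropna()
        s = summarize_group(vals, genotype=str(name), metric=metric)
        rows.append({"genotype": s.genotype, "metric": s.metric, "n": s.n, "mean": s.mean, "sd": s.sd})
    return pd.DataFrame(rows)


def compare_frame(
    quant: pd.DataFrame,
    metric: str,
    reference: str,
    group_col: str = "genotype",
    variant: str = "pooled",
) -> pd.DataFrame:
    """Each non-reference group against the reference group, one row apiece."""
    if reference not in set(quant[group_col]):
        raise ValueError(f"reference group {reference!r} not present in {group_col!r}")
    ref_vals = quant.loc[quant[group_col] == reference, metric].dropna()
    rows = []
    for name, grp in quant.groupby(group_col, sort=False):
        if str(name) == reference:
            continue
        res = compare_groups(
            ref_vals, grp[metric].dropna(), variant=variant, group_a=reference, group_b=str(name)
        )
        rows.append(
            {
                "group_a": res.group_a,
                "group_b": res.group_b,
                "metric": metric,
                "t_stat": res.t_stat,
                "df": res.df,
                "p_value": res.p_value,
                "label": res.label,
            }
        )
    return pd.DataFrame(rows)
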