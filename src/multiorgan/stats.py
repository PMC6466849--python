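"""Histology scoring and the group-comparison / correlation layer.

Group comparisons use one-way ANOVA for any number of groups (for two
groups this is equivalent to the pooled-variance t test, F = t²), followed
by Tukey's HSD post hoc when more than two groups are present.
Associations are quantified by Pearson's r with R² = r² and a two-sided P.
Significance is flagged at P < 0.05 throughout; no correction across
metrics is applied.

Histology aggregation: kidney injury is the mean of ten 0-5 field scores;
liver injury is a single 0-4 grade binned from the percentage of section
area affected (0 -> 0; (0, 25] -> 1; (25, 50] -> 2; (50, 75] -> 3;
(75, 100] -> 4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

ALPHA = 0.05


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    p_adj: float
    significant: bool


@dataclass
class GroupComparison:
    """One-way ANOVA across groups with optional Tukey post hoc."""

    metric: str
    group_means: dict[str, float]
    group_sizes: dict[str, int]
    anova_f: float
    anova_p: float
    significant: bool
    pairwise: list[PairwiseResult] = field(default_factory=list)


@dataclass
class CorrelationResult:
    x_metric: str
    y_metric: str
    r: float
    r_squared: float
    p: float
    n: int
    significant: bool


def liver_grade(percent_area_affected: float) -> int:
    """Semiquantitative liver injury grade from % section area affected."""
    p = float(percent_area_affected)
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"percent area must lie in [0, 100], got {p}")
    if p == 0.0:
        return 0
    return int(np.ceil(p / 25.0))


def kidney_score_aggregate(field_scores) -> float:
    """Mean of exactly ten integer field scores, each in 0-5."""
    scores = np.asarray(field_scores)
    if scores.shape != (10,):
        raise ValueError(f"expected exactly 10 field scores, got {scores.shape}")
    if not np.all((scores == np.rint(scores)) & (scores >= 0) & (scores <= 5)):
        raise ValueError("field scores must be integers in 0-5")
    return float(scores.mean())


def compare_groups(values_by_group: dict, metric: str = "", alpha: float = ALPHA,
                   posthoc: bool = True) -> GroupComparison:
    """One-way ANOVA (plus Tukey HSD for >2 groups) over named groups.

    Each group needs n >= 2; a degenerate input (fewer than two groups,
    tiny groups, or zero variance everywhere) raises with a description.
    ``posthoc=False`` skips the Tukey step (useful in calibration studies
    that only consume the ANOVA flag).
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    for name, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"group {name!r} has n={vals.size} < 2")
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"group {name!r} contains non-finite values")
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        # all observations identical: no between- or within-group variance
        f, p = 0.0, 1.0
    else:
        f, p = scipy.stats.f_oneway(*groups.values())
        f, p = float(f), float(p)
    comp = GroupComparison(
        metric=metric,
        group_means={k: float(v.mean()) for k, v in groups.items()},
        group_sizes={k: int(v.size) for k, v in groups.items()},
        anova_f=f,
        anova_p=p,
        significant=bool(p < alpha),
    )
    if posthoc and len(groups) > 2 and np.ptp(pooled) > 0:
        names = list(groups)
        res = scipy.stats.tukey_hsd(*groups.values())
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                p_adj = float(res.pvalue[i, j])
                comp.pairwise.append(
                    PairwiseResult(
                        group_a=names[i], group_b=names[j],
                        p_adj=p_adj, significant=bool(p_adj < alpha),
                    )
                )
    return comp


def correlate(x, y, x_metric: str = "x", y_metric: str = "y", alpha: float = ALPHA) -> CorrelationResult:
    """Pearson correlation with R² and a two-sided P value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = scipy.stats.pearsonr(x, y)
    r = float(res.statistic)
    p = float(res.pvalue)
    return CorrelationResult(
        x_metric=x_metric,
        y_metric=y_metric,
        r=r,
        r_squared=r * r,
        p=p,
        n=int(x.size),
        significant=bool(p < alpha),
    )
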