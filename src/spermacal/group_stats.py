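"""Group statistics: exact 2x2 test and one-way ANOVA.

Population assays and transit phenotypes are compared between conditions by
a two-sided Fisher exact test on the 2x2 table (unoccupied vs pooled rest,
or exited vs pooled rest); continuous metrics by the one-way ANOVA omnibus
F.  The Fisher p uses the probability-mass convention: the sum of
hypergeometric probabilities of all tables with the observed margins whose
probability does not exceed the observed table's (with a 1e-7 relative tie
tolerance).  Factorials are handled in log space so large margins stay
stable.

Post-hoc comparisons beyond the omnibus F are exposed as pairwise tests
with an optional Bonferroni correction; studentized-range (Tukey HSD)
quantiles are deliberately out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .transit_annotation import PopulationTable

__all__ = [
    "ContingencyTable2x2",
    "AnovaResult",
    "fisher_exact",
    "anova_oneway",
    "significance_stars",
    "compare_populations",
    "compare_metric_groups",
]

_TIE_RTOL = 1e-7

#: significance thresholds and their star labels
STAR_LEVELS = ((1e-4, "****"), (5e-3, "***"), (1e-2, "**"), (5e-2, "*"))


@dataclass
class ContingencyTable2x2:
    """Counts (a, b) for the first condition and (c, d) for the second."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"count {name}={v} must be a non-negative integer")
            setattr(self, name, int(v))
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all counts are zero; at least one margin must be positive")


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def _log_hypergeom_pmf(k: int, n: int, c1: int, r1: int) -> float:
    """log P(a = k) for a 2x2 table with total n, column margin c1, row margin r1."""
    return (
        math.lgamma(c1 + 1) - math.lgamma(k + 1) - math.lgamma(c1 - k + 1)
        + math.lgamma(n - c1 + 1) - math.lgamma(r1 - k + 1) - math.lgamma(n - c1 - r1 + k + 1)
        + math.lgamma(r1 + 1) + math.lgamma(n - r1 + 1) - math.lgamma(n + 1)
    )


def fisher_exact(table: ContingencyTable2x2 | tuple) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Enumerates every table with the observed margins and sums the
    probabilities of those at most as probable as the observed one.
    Symmetric under row swap, column swap, and transposition.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(a, b, c, d)
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    k_lo = max(0, r1 + c1 - n)
    k_hi = min(r1, c1)
    log_obs = _log_hypergeom_pmf(a, n, c1, r1)
    p_obs = math.exp(log_obs)
    total = 0.0
    for k in range(k_lo, k_hi + 1):
        p_k = math.exp(_log_hypergeom_pmf(k, n, c1, r1))
        if p_k <= p_obs * (1.0 + _TIE_RTOL):
            total += p_k
    return min(total, 1.0)


def anova_oneway(groups) -> AnovaResult:
    """One-way ANOVA omnibus F over two or more numeric samples.

    F = (SSB/df_B) / (SSW/df_W) with p from the upper tail of the F
    distribution.  All-identical data carry no variance information and are
    rejected; zero within-group variance with nonzero between-group spread
    is reported as F = +inf with p = 0.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    if any(g.size == 0 for g in groups):
        raise ValueError("every group must contain at least one value")
    k = len(groups)
    n = sum(g.size for g in groups)
    if n <= k:
        raise ValueError(f"total n={n} must exceed the number of groups k={k}")
    allv = np.concatenate(groups)
    if np.all(allv == allv[0]):
        raise ValueError("all values identical: no variance to partition")
    grand = allv.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n - k
    if ssw == 0.0:
        return AnovaResult(F=math.inf, df_between=df_b, df_within=df_w, p=0.0)
    F = (ssb / df_b) / (ssw / df_w)
    p = float(_stats.f.sf(F, df_b, df_w))
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w, p=p)


def significance_stars(p: float) -> str:
    """Star annotation at the 0.0001 / 0.005 / 0.01 / 0.05 thresholds."""
    for threshold, stars in STAR_LEVELS:
        if p < threshold:
            return stars
    return "ns"


def compare_populations(
    table: PopulationTable,
    control: str,
    bonferroni: bool = False,
):
    """Fisher tests of unoccupied-vs-rest for every condition against control.

    Returns a list of dicts (comparison, unoccupied counts, p,
    p_adjusted when requested, stars).
    """
    if control not in table.counts:
        raise KeyError(f"control condition {control!r} not in table")
    ctrl = table.unoccupied_vs_rest(control)
    others = [c for c in table.conditions if c != control]
    rows = []
    for cond in others:
        u, rest = table.unoccupied_vs_rest(cond)
        p = fisher_exact(ContingencyTable2x2(ctrl[0], ctrl[1], u, rest))
        row = {
            "comparison": f"{control} vs {cond}",
            "control_unoccupied": ctrl[0],
            "control_rest": ctrl[1],
            "unoccupied": u,
            "rest": rest,
            "p": p,
        }
        if bonferroni:
            row["p_adjusted"] = min(1.0, p * len(others))
            row["stars"] = significance_stars(row["p_adjusted"])
        else:
            row["stars"] = significance_stars(p)
        rows.append(row)
    return rows


def compare_metric_groups(groups: dict, bonferroni: bool = True):
    """Omnibus ANOVA over named groups plus pairwise F tests.

    `groups` maps condition name -> sequence of metric values.  The pairwise
    p-values carry a Bonferroni correction by default (Tukey HSD is not
    provided).
    """
    names = list(groups)
    omnibus = anova_oneway([groups[nm] for nm in names])
    pairs = []
    m = len(names) * (len(names) - 1) // 2
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            res = anova_oneway([groups[names[i]], groups[names[j]]])
            p = res.p
            row = {
                "comparison": f"{names[i]} vs {names[j]}",
                "F": res.F,
                "p": p,
            }
            if bonferroni:
                row["p_adjusted"] = min(1.0, p * m)
                row["stars"] = significance_stars(row["p_adjusted"])
            else:
                row["stars"] = significance_stars(p)
            pairs.append(row)
    return omnibus, pairs
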