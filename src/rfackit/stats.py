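"""Cohort statistics: contrast ANOVAs, repeated measures with Holm,
sector-by-sector t-tests, two-sample power, and Kaplan-Meier / log-rank.

The battery mirrors a three-arm (sham / MI / MI+Val) longitudinal design:
at the pre-treatment timepoint a Helmert-contrast ANOVA separates the surgery
effect (sham vs the average of the infarcted arms) from the randomization
check (MI vs MI+Val); after treatment, treatment contrasts compare MI against
each other arm; sham time-constancy uses repeated-measures ANOVA with Holm-
adjusted pairwise tests; and regional maps are compared cell-by-cell on the
resampled 10-slice grid with unpaired t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.api import OLS
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests

from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "ContrastResult",
    "PowerSpec",
    "TestResultMap",
    "helmert_anova",
    "holm_adjust",
    "km_logrank",
    "rm_anova_holm",
    "sectorwise_tests",
    "treatment_anova",
    "two_sample_power",
]


@dataclass
class ContrastResult:
    """Per-contrast estimate with t, F = t^2 and p, plus the overall ANOVA."""

    contrasts: pd.DataFrame  # index: contrast name; estimate, t, F, p
    f_overall: float
    p_overall: float
    degenerate: bool = False


def _cell_means_fit(values, groups, levels):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    X = np.column_stack([(groups == g).astype(float) for g in levels])
    if np.any(X.sum(axis=0) < 2):
        raise ValueError("every group needs n >= 2")
    res = OLS(values, X).fit()
    scale = max(1.0, float(np.mean(values**2)))
    degenerate = res.mse_resid < 1e-12 * scale
    return res, degenerate


def _contrast_table(res, rows: dict) -> pd.DataFrame:
    recs = {}
    for name, c in rows.items():
        tt = res.t_test(np.asarray(c, dtype=float))
        recs[name] = {
            "estimate": float(np.squeeze(tt.effect)),
            "t": float(np.squeeze(tt.tvalue)),
            "F": float(np.squeeze(tt.tvalue)) ** 2,
            "p": float(np.squeeze(tt.pvalue)),
        }
    return pd.DataFrame(recs).T


def helmert_anova(values, groups, levels=("sham", "MI", "MI+Val")) -> ContrastResult:
    """One-way ANOVA with the two orthogonal Helmert contrasts.

    Contrast ``surgery`` compares the first level (sham) against the mean of
    the other two; contrast ``randomization`` compares the second against the
    third (MI vs MI+Val).  With zero within-group variance everywhere the
    p-values are undefined and the result is flagged degenerate.
    """
    if len(levels) != 3:
        raise ValueError("helmert_anova expects exactly 3 groups")
    res, degenerate = _cell_means_fit(values, groups, levels)
    if degenerate:
        table = pd.DataFrame(
            np.nan, index=["surgery", "randomization"], columns=["estimate", "t", "F", "p"]
        )
        return ContrastResult(table, np.nan, np.nan, degenerate=True)
    table = _contrast_table(
        res, {"surgery": [1.0, -0.5, -0.5], "randomization": [0.0, 1.0, -1.0]}
    )
    groups_arr = np.asarray(groups)
    f, p = sps.f_oneway(*[np.asarray(values)[groups_arr == g] for g in levels])
    return ContrastResult(table, float(f), float(p))


def treatment_anova(values, groups, reference: str = "MI",
                    levels=("sham", "MI", "MI+Val")) -> ContrastResult:
    """One-way ANOVA with treatment contrasts against a reference group.

    Each non-reference group is compared with the reference (default MI) via
    a GLM contrast on the cell means; p-values share the pooled error term.
    """
    if reference not in levels:
        raise ValueError(f"reference '{reference}' not in levels")
    res, degenerate = _cell_means_fit(values, groups, levels)
    if degenerate:
        others = [g for g in levels if g != reference]
        table = pd.DataFrame(np.nan, index=[f"{reference} vs {g}" for g in others],
                             columns=["estimate", "t", "F", "p"])
        return ContrastResult(table, np.nan, np.nan, degenerate=True)
    ref_i = levels.index(reference)
    rows = {}
    for j, g in enumerate(levels):
        if g == reference:
            continue
        c = np.zeros(len(levels))
        c[ref_i], c[j] = 1.0, -1.0
        rows[f"{reference} vs {g}"] = c
    table = _contrast_table(res, rows)
    groups_arr = np.asarray(groups)
    f, p = sps.f_oneway(*[np.asarray(values)[groups_arr == g] for g in levels])
    return ContrastResult(table, float(f), float(p))


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, never below raw)."""
    return multipletests(np.asarray(pvals, dtype=float), method="holm")[1]


def rm_anova_holm(df: pd.DataFrame, subject: str = "subject",
                  within: str = "timepoint", value: str = "value"):
    """Repeated-measures ANOVA over timepoints with Holm-adjusted pairwise tests.

    Requires a complete subject x timepoint grid (no imputation).  Returns
    (overall p, DataFrame of pairwise paired t-tests with raw and Holm p).
    A single timepoint pair reduces to the paired t-test.
    """
    grid = df.pivot(index=subject, columns=within, values=value)
    if grid.isna().any().any():
        raise ValueError("incomplete subject x timepoint grid")
    tps = list(grid.columns)
    if len(tps) < 2:
        raise ValueError("need >= 2 timepoints")
    res = AnovaRM(df, depvar=value, subject=subject, within=[within]).fit()
    p_overall = float(res.anova_table["Pr > F"].iloc[0])
    pairs, raw = [], []
    for i in range(len(tps)):
        for j in range(i + 1, len(tps)):
            t, p = sps.ttest_rel(grid[tps[i]], grid[tps[j]])
            pairs.append((tps[i], tps[j], float(t)))
            raw.append(float(p))
    adj = holm_adjust(raw)
    pairwise = pd.DataFrame(
        [(a, b, t, p, q) for (a, b, t), p, q in zip(pairs, raw, adj)],
        columns=["level_a", "level_b", "t", "p_raw", "p_holm"],
    )
    return p_overall, pairwise


@dataclass
class TestResultMap:
    """Cell-wise two-sample test over a (slice, sector) grid."""

    p_value: np.ndarray  # (n_slices, n_sectors), NaN where undefined
    t_stat: np.ndarray
    mean_a: np.ndarray
    mean_b: np.ndarray
    test_name: str
    adjustment: str | None = None


def sectorwise_tests(maps_a, maps_b, equal_var: bool = True,
                     adjust: str | None = None) -> TestResultMap:
    """Unpaired t-test per (slice, sector) cell between two groups of maps.

    ``maps_a`` / ``maps_b`` are stacks shaped (n_subjects, n_slices,
    n_sectors) or lists of RFACMap.  Pooled-variance by default
    (``equal_var=False`` for Welch); raw p-values by default, with optional
    Benjamini-Hochberg (``adjust="bh"``) across the grid.  Cells with fewer
    than 2 finite values in either group get NaN.
    """
    a = np.stack([m.rfac_pct if hasattr(m, "rfac_pct") else m for m in maps_a])
    b = np.stack([m.rfac_pct if hasattr(m, "rfac_pct") else m for m in maps_b])
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("groups must share the (slice, sector) grid")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(a, b, axis=0, equal_var=equal_var, nan_policy="omit")
    t, p = np.asarray(t, dtype=float), np.asarray(p, dtype=float)
    thin = (np.sum(np.isfinite(a), axis=0) < 2) | (np.sum(np.isfinite(b), axis=0) < 2)
    p[thin] = np.nan
    t[thin] = np.nan
    if adjust == "bh":
        ok = np.isfinite(p)
        p_adj = p.copy()
        p_adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
        p = p_adj
    elif adjust is not None:
        raise ValueError("adjust must be None or 'bh'")
    return TestResultMap(
        p_value=p, t_stat=t,
        mean_a=np.nanmean(a, axis=0), mean_b=np.nanmean(b, axis=0),
        test_name="pooled t" if equal_var else "Welch t",
        adjustment=adjust,
    )


@dataclass
class PowerSpec:
    """Two-sample t-test power scenario (equal n per group)."""

    n_per_group: int
    delta: float
    sd1: float
    sd2: float
    alpha: float = 0.05
    sides: int = 2

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.sd1 < 0 or self.sd2 < 0:
            raise ValueError("SDs must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.sides not in (1, 2):
            raise ValueError("sides must be 1 or 2")


def two_sample_power(spec: PowerSpec) -> float:
    """Power of the two-sample t-test via the noncentral t distribution.

    Uses the pooled-SD convention sd_pooled = sqrt((sd1^2 + sd2^2)/2) and
    noncentrality delta * sqrt(n/2) / sd_pooled with df = 2n - 2.
    """
    n = spec.n_per_group
    df = 2 * n - 2
    sd_pooled = np.sqrt((spec.sd1**2 + spec.sd2**2) / 2.0)
    nc = spec.delta / (sd_pooled * np.sqrt(2.0 / n))
    if spec.sides == 2:
        tcrit = sps.t.ppf(1.0 - spec.alpha / 2.0, df)
        power = sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc)
    else:
        tcrit = sps.t.ppf(1.0 - spec.alpha, df)
        power = sps.nct.sf(tcrit, df, nc)
    return float(power)


def km_logrank(times, events, groups):
    """Kaplan-Meier curves per group and the log-rank test across groups.

    Returns (fitted KaplanMeierFitter per group, chi2, p, flag); the flag is
    True and chi2/p are NaN when no events occurred anywhere (log-rank
    undefined, survival identically 1).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    labels = np.unique(groups)
    if labels.size < 2:
        raise ValueError("log-rank needs >= 2 groups")
    fitters = {}
    for g in labels:
        kmf = KaplanMeierFitter(label=str(g))
        kmf.fit(times[groups == g], events[groups == g])
        fitters[str(g)] = kmf
    if events.sum() == 0:
        return fitters, np.nan, np.nan, True
    res = multivariate_logrank_test(times, groups, events)
    return fitters, float(res.test_statistic), float(res.p_value), False
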