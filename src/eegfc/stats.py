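"""Group-level statistics: one-way repeated-measures ANOVA with partial
eta squared, Bonferroni post-hoc paired t-tests, paired t-test, and the
Mann-Whitney U test.

The repeated-measures ANOVA is the plain one-way within-subject
decomposition (no sphericity correction):

    SS_total = SS_subject + SS_condition + SS_error
    F = MS_condition / MS_error,  df = (k-1, (k-1)(n-1))
    partial eta^2 = SS_condition / (SS_condition + SS_error)

Degenerate inputs (zero error variance, all-zero differences) return
flagged results rather than raising, so sparse synthetic cohorts do not
abort a pipeline run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class StatResult:
    """One test outcome: statistic, df, p, effect size, decision."""

    test: str
    statistic: float
    df: tuple[float, ...]
    p: float
    alpha: float = 0.05
    effect_size: float | None = None
    degenerate: bool = False
    detail: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p < self.alpha

    def as_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": None if np.isnan(self.statistic) else float(self.statistic),
            "df": list(self.df),
            "p": None if np.isnan(self.p) else float(self.p),
            "alpha": self.alpha,
            "effect_size": self.effect_size,
            "significant": self.significant,
            "degenerate": self.degenerate,
            **{k: v for k, v in self.detail.items()},
        }


def _as_table(t) -> pd.DataFrame:
    table = pd.DataFrame(t)
    if table.isna().any().any():
        raise ValueError("measurement table has missing cells")
    if table.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    return table


def rm_anova_oneway(t, alpha: float = 0.05) -> StatResult:
    """One-way repeated-measures ANOVA over a subjects x conditions table.

    Returns F, (k-1, (k-1)(n-1)) degrees of freedom, the p-value, and
    partial eta squared. Zero error variance is flagged (p undefined)
    unless the condition effect is also zero, in which case F = 0, p = 1.
    """
    table = _as_table(t)
    n, k = table.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    x = table.to_numpy(dtype=float)
    grand = x.mean()
    ss_cond = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = max(ss_total - ss_cond - ss_subj, 0.0)
    df1, df2 = k - 1, (k - 1) * (n - 1)
    detail = {"ss_condition": float(ss_cond), "ss_error": float(ss_err),
              "ss_subject": float(ss_subj)}
    tiny = np.finfo(float).eps * max(ss_total, 1.0)
    if ss_err <= tiny:
        if ss_cond <= tiny:
            return StatResult("rm_anova", 0.0, (df1, df2), 1.0, alpha,
                              effect_size=0.0, detail=detail)
        return StatResult("rm_anova", np.inf, (df1, df2), np.nan, alpha,
                          effect_size=1.0, degenerate=True, detail=detail)
    f = (ss_cond / df1) / (ss_err / df2)
    p = float(sps.f.sf(f, df1, df2))
    eta_p2 = ss_cond / (ss_cond + ss_err)
    return StatResult("rm_anova", float(f), (df1, df2), p, alpha,
                      effect_size=float(eta_p2), detail=detail)


def paired_ttest(a, b, alpha: float = 0.05) -> StatResult:
    """Two-sided paired-samples t-test on per-subject vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length vectors")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        return StatResult("paired_t", np.nan, (float(a.size - 1),), np.nan,
                          alpha, degenerate=True,
                          detail={"mean_difference": float(d.mean())})
    res = sps.ttest_rel(a, b)
    return StatResult("paired_t", float(res.statistic), (float(a.size - 1),),
                      float(res.pvalue), alpha,
                      detail={"mean_difference": float(d.mean())})


def posthoc_paired_ttests(t, alpha_family: float = 0.05,
                          ) -> list[StatResult]:
    """Bonferroni-corrected paired t-tests for every condition pair.

    With three conditions the per-test level is 0.05/3 ~ 0.0167.
    """
    table = _as_table(t)
    cols = list(table.columns)
    pairs = list(combinations(cols, 2))
    alpha = alpha_family / len(pairs)
    results = []
    for ca, cb in pairs:
        r = paired_ttest(table[ca].to_numpy(), table[cb].to_numpy(),
                         alpha=alpha)
        r.detail["pair"] = (str(ca), str(cb))
        r.detail["alpha_family"] = alpha_family
        results.append(r)
    return results


def mann_whitney_u(x, y, alpha: float = 0.05) -> StatResult:
    """Two-sided Mann-Whitney U test between two independent samples.

    Exact null distribution when the combined sample size is at most 20 and
    the data have no ties; otherwise the normal approximation with tie
    correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return StatResult("mann_whitney_u", float(res.statistic),
                      (float(x.size), float(y.size)), float(res.pvalue),
                      alpha, detail={"method": method})
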