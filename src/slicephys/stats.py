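"""Cohort-level statistics: normality-gated group tests, post hoc power,
and normalized phenotype proportions.

The testing logic mirrors the source workflow: Shapiro-Wilk decides
normality (on the paired differences for paired designs); normally
distributed data get a two-sided Student's t test (unpaired or paired),
otherwise a two-sided Mann-Whitney test is used.  Significance is at
p < 0.05 and a post hoc power (G*Power convention) is attached to every
comparison; for the Mann-Whitney case the power uses the asymptotic
relative efficiency correction (A.R.E. = 3/pi for a normal parent).

No multiple-testing correction is applied by default, matching the source
workflow; :func:`holm_adjust` is provided for reuse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["StatResult", "ProportionTable", "compare_groups", "posthoc_power",
           "normalized_proportions", "holm_adjust", "InsufficientDataError"]

_ARE_NORMAL = 3.0 / np.pi


class InsufficientDataError(ValueError):
    pass


@dataclass
class StatResult:
    comparison_label: str
    test_used: str              # unpaired_t | paired_t | mann_whitney
    normality_p_x: float
    normality_p_y: float | None
    statistic: float
    p_value: float
    effect_size: float          # Cohen's d (t tests) or rank-biserial (MW)
    parametric_d: float         # Cohen's d regardless of test (for power)
    posthoc_power: float
    n_x: int
    n_y: int


def _cohens_d_unpaired(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = x.size, y.size
    sp = np.sqrt(((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1))
                 / (nx + ny - 2))
    if sp == 0:
        return 0.0
    return float((np.mean(x) - np.mean(y)) / sp)


def compare_groups(x, y, paired: bool = False, alpha: float = 0.05,
                   label: str = "") -> StatResult:
    """Normality-gated two-sample comparison with effect size and power.

    Shapiro-Wilk is applied to each sample (to the differences when
    ``paired``); the comparison is called non-normal if any gate p-value is
    below ``alpha``, in which case a two-sided Mann-Whitney test replaces
    the t test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise InsufficientDataError("need at least 3 observations per sample")
    if paired and x.size != y.size:
        raise InsufficientDataError("paired comparison requires equal lengths")

    if paired:
        diffs = x - y
        if np.ptp(diffs) == 0:
            p_norm_x, p_norm_y = 1.0, None
        else:
            p_norm_x, p_norm_y = float(sps.shapiro(diffs).pvalue), None
        normal = p_norm_x >= alpha
    else:
        p_norm_x = 1.0 if np.ptp(x) == 0 else float(sps.shapiro(x).pvalue)
        p_norm_y = 1.0 if np.ptp(y) == 0 else float(sps.shapiro(y).pvalue)
        normal = p_norm_x >= alpha and p_norm_y >= alpha

    if paired:
        d_param = 0.0
        sd = np.std(x - y, ddof=1)
        if sd > 0:
            d_param = float(np.mean(x - y) / sd)
    else:
        d_param = _cohens_d_unpaired(x, y)

    if normal:
        if paired:
            res = sps.ttest_rel(x, y)
            test_used, effect = "paired_t", d_param
        else:
            res = sps.ttest_ind(x, y)
            test_used, effect = "unpaired_t", d_param
        stat, p = float(res.statistic), float(res.pvalue)
        if not np.isfinite(stat):   # identical samples
            stat, p = 0.0, 1.0
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
        test_used = "mann_whitney"
        effect = float(1.0 - 2.0 * stat / (x.size * y.size))  # rank-biserial

    power = posthoc_power(test_used, d_param, x.size, y.size, alpha=alpha)
    return StatResult(comparison_label=label, test_used=test_used,
                      normality_p_x=p_norm_x, normality_p_y=p_norm_y,
                      statistic=stat, p_value=p, effect_size=effect,
                      parametric_d=d_param, posthoc_power=power,
                      n_x=x.size, n_y=y.size)


def posthoc_power(test_used: str, effect_size: float, n_x: int, n_y: int = 0,
                  alpha: float = 0.05) -> float:
    """Two-sided post hoc power at the observed effect size (G*Power style).

    t tests use the noncentral-t closed form; the Mann-Whitney power uses
    the same form with sample sizes scaled by the asymptotic relative
    efficiency for a normal parent (3/pi).
    """
    if n_x <= 0 or (test_used != "paired_t" and n_y <= 0):
        raise ValueError("sample sizes must be positive")
    d = abs(float(effect_size))
    if test_used == "paired_t":
        n = n_x
        df = n - 1
        ncp = d * np.sqrt(n)
    elif test_used == "unpaired_t":
        df = n_x + n_y - 2
        ncp = d * np.sqrt(n_x * n_y / (n_x + n_y))
    elif test_used == "mann_whitney":
        ex, ey = n_x * _ARE_NORMAL, n_y * _ARE_NORMAL
        df = ex + ey - 2
        ncp = d * np.sqrt(ex * ey / (ex + ey))
    else:
        raise ValueError(f"unknown test {test_used!r}")
    if df <= 0:
        raise ValueError("not enough observations for power")
    t_crit = sps.t.ppf(1 - alpha / 2, df)
    power = (1.0 - sps.nct.cdf(t_crit, df, ncp)) + sps.nct.cdf(-t_crit, df, ncp)
    if not np.isfinite(power):   # nct.cdf underflows at large noncentrality
        power = sps.norm.sf(t_crit - ncp) + sps.norm.cdf(-t_crit - ncp)
    return float(np.clip(power, 0.0, 1.0))


@dataclass
class ProportionTable:
    """Per-category counts, within-group percentages, and shares after
    normalizing both group totals to 100."""

    labels: list[str]
    counts_g1: np.ndarray
    counts_g2: np.ndarray
    pct_g1: np.ndarray
    pct_g2: np.ndarray
    share_g1: np.ndarray
    share_g2: np.ndarray

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "category": self.labels,
            "count_g1": self.counts_g1, "count_g2": self.counts_g2,
            "pct_g1": self.pct_g1, "pct_g2": self.pct_g2,
            "share_g1": self.share_g1, "share_g2": self.share_g2,
        })


def normalized_proportions(counts_g1: dict[str, int],
                           counts_g2: dict[str, int]) -> ProportionTable:
    """Within-group percentages and cross-group normalized shares.

    Both group totals are normalized to 100; the share of group g in
    category c is pct_g(c) / (pct_1(c) + pct_2(c)), which removes the
    imbalance in total cohort sizes.  Categories absent from both groups
    get undefined (NaN) shares.
    """
    if set(counts_g1) != set(counts_g2):
        raise ValueError("category sets must match")
    labels = sorted(counts_g1)
    c1 = np.array([counts_g1[k] for k in labels], dtype=float)
    c2 = np.array([counts_g2[k] for k in labels], dtype=float)
    if c1.sum() <= 0 or c2.sum() <= 0:
        raise ValueError("each group must have a positive total")
    pct1 = 100.0 * c1 / c1.sum()
    pct2 = 100.0 * c2 / c2.sum()
    denom = pct1 + pct2
    with np.errstate(invalid="ignore", divide="ignore"):
        s1 = np.where(denom > 0, pct1 / denom, np.nan)
        s2 = np.where(denom > 0, pct2 / denom, np.nan)
    return ProportionTable(labels=labels, counts_g1=c1.astype(int),
                           counts_g2=c2.astype(int), pct_g1=pct1, pct_g2=pct2,
                           share_g1=s1, share_g2=s2)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (optional reuse switch)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj
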