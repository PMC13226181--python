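"""Test-retest and comparison statistics.

ICC(3,1) is the two-way mixed-effects, consistency, single-measure intraclass
correlation (McGraw & Wong C,1): with MS_R the between-subject and MS_E the
residual mean square from the subject x session ANOVA and k sessions,

    ICC(3,1) = (MS_R - MS_E) / (MS_R + (k - 1) MS_E),

with the 95% CI from F-distribution bounds on MS_R/MS_E. Being a consistency
coefficient it ignores fixed session offsets (a constant shift between
sessions leaves it at 1).

Bland-Altman agreement reports the mean paired difference (bias) and the
limits of agreement bias +/- 1.96 SD of the differences. Paired comparisons
report Cohen's d in the d = t / sqrt(n) convention for paired designs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

__all__ = [
    "reliability_report",
    "LOA_MULTIPLIER",
    "IccResult",
    "BlandAltmanResult",
    "ComparisonResult",
    "icc3_1",
    "bland_altman",
    "correlate",
    "paired_comparison",
    "cohens_d_from_t",
    "correlation_power_exact",
    "required_n_correlation",
    "required_n_correlation_fisher",
]

#: Two-sided 95% standard-normal quantile used for the limits of agreement.
LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    f_value: float
    df1: int
    df2: int


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    df: int
    p_value: float
    effect_size: float | None = None
    method: str = ""


def icc3_1(scores, confidence: float = 0.95) -> IccResult:
    """ICC(3,1) with a CI from the two-way ANOVA of an n x k score matrix.

    Rows are subjects, columns raters/sessions (k = 2 for test-retest).
    Requires n >= 3 complete rows; rows containing NaN are dropped first.
    Zero between-subject variance yields a non-positive ICC, reported as
    computed (not clipped).
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("scores must be an n x k matrix with k >= 2")
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 complete subjects")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_err = np.sum(resid**2)
    df1, df2 = n - 1, (n - 1) * (k - 1)
    ms_r = ss_rows / df1
    ms_e = ss_err / df2
    icc = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
    if ms_e == 0:  # perfect consistency: degenerate F, CI collapses
        return IccResult(float(icc), float(icc), float(icc), math.inf, df1, df2)
    f_obs = ms_r / ms_e
    alpha = 1.0 - confidence
    fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    return IccResult(
        icc=float(icc),
        ci_low=float((fl - 1) / (fl + k - 1)),
        ci_high=float((fu - 1) / (fu + k - 1)),
        f_value=float(f_obs),
        df1=df1,
        df2=df2,
    )


def bland_altman(a, b, multiplier: float = LOA_MULTIPLIER) -> BlandAltmanResult:
    """Bias and limits of agreement of the paired differences a - b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltmanResult(bias, sd, bias - multiplier * sd, bias + multiplier * sd)


def correlate(
    a, b, method: str = "auto", alternative: str = "two-sided"
) -> ComparisonResult:
    """Pearson or Spearman correlation with a normality-driven 'auto' mode.

    ``method='auto'`` runs Shapiro-Wilk on each margin at alpha = 0.05 and
    falls back to Spearman when either fails; otherwise Pearson.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 4:
        raise ValueError("correlation needs >= 4 aligned pairs")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if method == "auto":
        normal = (
            stats.shapiro(a).pvalue > 0.05 and stats.shapiro(b).pvalue > 0.05
        )
        method = "pearson" if normal else "spearman"
    if method == "pearson":
        res = stats.pearsonr(a, b, alternative=alternative)
    elif method == "spearman":
        res = stats.spearmanr(a, b, alternative=alternative)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ComparisonResult(
        statistic=float(res.statistic),
        df=a.size - 2,
        p_value=float(res.pvalue),
        method=method,
    )


def cohens_d_from_t(t: float, n: int) -> float:
    """Paired-design effect size d = t / sqrt(n) (n = number of pairs)."""
    return t / math.sqrt(n)


def paired_comparison(
    a, b, alternative: str = "two-sided"
) -> ComparisonResult:
    """Paired t-test of a vs b with Cohen's d = t / sqrt(n)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired comparison needs >= 2 aligned pairs")
    if np.std(a - b, ddof=1) == 0:
        raise ValueError("zero variance of paired differences; t undefined")
    res = stats.ttest_rel(a, b, alternative=alternative)
    t = float(res.statistic)
    return ComparisonResult(
        statistic=t,
        df=a.size - 1,
        p_value=float(res.pvalue),
        effect_size=cohens_d_from_t(t, a.size),
        method="paired-t",
    )


def _sample_r_logpdf_factor(n: int, rho: float) -> float:
    return (
        math.log(n - 2)
        + special.gammaln(n - 1)
        - 0.5 * math.log(2 * math.pi)
        - special.gammaln(n - 0.5)
        + (n - 1) / 2 * math.log1p(-rho * rho)
    )


def _sample_r_pdf(r, rho: float, n: int):
    """Exact density of the sample correlation under a bivariate normal."""
    r = np.asarray(r, dtype=float)
    lg = (
        _sample_r_logpdf_factor(n, rho)
        + (n - 4) / 2 * np.log1p(-r * r)
        - (n - 1.5) * np.log1p(-rho * r)
    )
    return np.exp(lg) * special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1) / 2)


def correlation_power_exact(
    rho: float, n: int, alpha: float = 0.05, tails: str = "one"
) -> float:
    """Power of the t-test of H0: rho = 0 under the exact sampling law of r.

    The rejection region on r comes from the usual t(n-2) transform of the
    sample correlation; power integrates the exact (hypergeometric) density
    of r under the alternative over that region.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    a = alpha if tails == "one" else alpha / 2
    t_crit = stats.t.ppf(1 - a, n - 2)
    r_crit = t_crit / math.sqrt(t_crit**2 + n - 2)
    upper, _ = integrate.quad(_sample_r_pdf, r_crit, 1, args=(rho, n), limit=200)
    if tails == "one":
        return float(upper)
    lower, _ = integrate.quad(_sample_r_pdf, -1, -r_crit, args=(rho, n), limit=200)
    return float(upper + lower)


def required_n_correlation(
    rho: float,
    alpha: float = 0.05,
    power: float = 0.8,
    tails: str = "one",
    n_max: int = 100_000,
) -> int:
    """Smallest n detecting a population correlation rho at the target power.

    Uses the exact bivariate-normal sampling distribution of r (not the
    Fisher-z approximation). Since power is monotone in n, the search brackets
    geometrically from the Fisher-z guess and then bisects.
    """
    if not 0 < rho < 1:
        raise ValueError("rho must lie in (0, 1)")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")

    def achieved(n: int) -> float:
        return correlation_power_exact(rho, n, alpha, tails)

    if achieved(4) >= power:
        return 4
    lo = 4
    hi = max(5, min(n_max, required_n_correlation_fisher(rho, alpha, power, tails)))
    while achieved(hi) < power:
        lo = hi
        hi *= 2
        if hi > n_max:
            raise ValueError(f"target power unreachable below n = {n_max}")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if mid < 4 or achieved(mid) < power:
            lo = mid
        else:
            hi = mid
    return hi


def reliability_report(
    results: pd.DataFrame, value_col: str = "auroc2"
) -> pd.DataFrame:
    """Test-retest summary of a per participant-session results table.

    ``results`` needs columns participant_id, session, dimension, condition
    and the measure column; exactly two sessions must be present. Per
    dimension x condition cell the report carries ICC(3,1) with its 95% CI,
    Bland-Altman bias and limits of agreement (session 1 minus session 2),
    and the between-session correlation (auto Pearson/Spearman). Participants
    missing either session or with a NaN measure are dropped pairwise.
    """
    sessions = sorted(results["session"].unique())
    if len(sessions) != 2:
        raise ValueError("reliability report needs exactly two sessions")
    rows = []
    for (dim, cond), cell in results.groupby(["dimension", "condition"]):
        wide = cell.pivot(
            index="participant_id", columns="session", values=value_col
        ).dropna()
        n = len(wide)
        row = {"measure": value_col, "dimension": dim, "condition": cond, "n": n}
        if n >= 4:
            a = wide[sessions[0]].to_numpy()
            b = wide[sessions[1]].to_numpy()
            icc = icc3_1(np.column_stack([a, b]))
            ba = bland_altman(a, b)
            corr = correlate(a, b, method="auto")
            row.update(
                icc=icc.icc,
                icc_ci_low=icc.ci_low,
                icc_ci_high=icc.ci_high,
                bias=ba.bias,
                loa_low=ba.loa_low,
                loa_high=ba.loa_high,
                corr=corr.statistic,
                corr_method=corr.method,
                corr_p=corr.p_value,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def required_n_correlation_fisher(
    rho: float, alpha: float = 0.05, power: float = 0.8, tails: str = "one"
) -> int:
    """Fisher-z approximation to the required sample size (cross-check)."""
    a = alpha if tails == "one" else alpha / 2
    za = stats.norm.ppf(1 - a)
    zb = stats.norm.ppf(power)
    n = ((za + zb) / math.atanh(rho)) ** 2 + 3
    return int(math.ceil(n))
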