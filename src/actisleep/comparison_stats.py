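"""Between-algorithm inference and method-agreement statistics.

Covers the study's comparison layer: one-way within-subject (repeated
measures) ANOVA with Mauchly's sphericity test and the Greenhouse-Geisser
correction, Bonferroni-corrected pairwise post hocs with Hedges g,
Bland-Altman agreement (mean difference, limits of agreement, proportional
bias), and the two-tier raw-count outlier sensitivity analysis.

The RM-ANOVA uses the textbook decomposition for an n x k complete-case
matrix (participants x conditions):

    SS_total = SS_subject + SS_condition + SS_error
    F = MS_condition / MS_error,  df = (k-1), (n-1)(k-1)

Greenhouse-Geisser epsilon is computed from the sample covariance of the
conditions projected through orthonormal contrasts C (k-1 x k):

    S~ = C S C',   eps = tr(S~)^2 / ((k-1) * tr(S~ S~))

and the corrected p value evaluates F on eps-scaled degrees of freedom.
Generalized eta squared is SS_condition / (SS_condition + SS_subject +
SS_error), appropriate for a one-way within design.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats


class DegenerateDataError(ValueError):
    pass


@dataclass
class AnovaResult:
    metric: str
    n_subjects: int
    n_conditions: int
    ss_condition: float
    ss_subject: float
    ss_error: float
    ms_condition: float
    ms_error: float
    F: float
    df_num: float
    df_den: float
    eta2_g: float
    epsilon_gg: float
    mauchly_w: float
    mauchly_chi2: float
    mauchly_df: int
    mauchly_p: float
    p_uncorrected: float
    df_num_adj: float
    df_den_adj: float
    p_adjusted: float


@dataclass
class PostHocResult:
    condition_a: str
    condition_b: str
    mean_difference: float
    t: float
    p_raw: float
    p_bonferroni: float
    hedges_g: float
    size_label: str


@dataclass
class BlandAltmanResult:
    metric: str
    method_pair: tuple[str, str]
    n: int
    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float
    prop_bias_slope: float
    prop_bias_intercept: float
    prop_bias_r2: float
    prop_bias_p: float
    undefined: str | None = None


@dataclass
class OutlierReport:
    flagged: dict[str, list[str]]
    metrics_with: dict[str, float]
    metrics_without: dict[str, float]
    relative_change: dict[str, float]
    within_criterion: bool
    criterion: float = 0.05


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (rows orthogonal to 1)."""
    h = linalg.helmert(k, full=False)
    return h


def gg_epsilon_from_cov(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a k x k condition covariance matrix."""
    s = np.asarray(cov, dtype=float)
    k = s.shape[0]
    if k < 2:
        raise DegenerateDataError("need >= 2 conditions")
    c = _orthonormal_contrasts(k)
    st = c @ s @ c.T
    tr = np.trace(st)
    if tr <= 0:
        return math.nan
    return float(tr**2 / ((k - 1) * np.trace(st @ st)))


def gg_epsilon(matrix: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from an n x k condition matrix."""
    y = np.asarray(matrix, dtype=float)
    return gg_epsilon_from_cov(np.cov(y, rowvar=False, ddof=1))


def mauchly_test(matrix: np.ndarray) -> tuple[float, float, int, float]:
    """Mauchly's sphericity test; returns (W, chi2, df, p)."""
    y = np.asarray(matrix, dtype=float)
    n, k = y.shape
    c = _orthonormal_contrasts(k)
    st = c @ np.cov(y, rowvar=False, ddof=1) @ c.T
    d = k - 1
    df = int(d * (d + 1) / 2 - 1)
    tr = np.trace(st)
    det = linalg.det(st)
    if tr <= 0 or det <= 0:
        return 0.0, math.inf, df, 0.0
    w = float(det / (tr / d) ** d)
    # chi-square approximation with the second-order correction term
    # (as in ezANOVA / pingouin)
    f_corr = 1.0 - (2 * d**2 + d + 2) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * f_corr * math.log(w)
    if df <= 0:
        return w, chi2, df, 1.0
    w2 = (
        (d + 2) * (d - 1) * (d - 2) * (2 * d**3 + 6 * d**2 + 3 * k + 2)
        / (288.0 * ((n - 1) * d * f_corr) ** 2)
    )
    p1 = float(stats.chi2.sf(chi2, df))
    p2 = float(stats.chi2.sf(chi2, df + 4))
    return w, chi2, df, p1 + w2 * (p2 - p1)


def rm_anova(matrix, condition_names: Sequence[str] | None = None, metric: str = "") -> AnovaResult:
    """One-way within-subject ANOVA with Greenhouse-Geisser correction.

    ``matrix`` is participants x conditions (complete cases), as an array
    or DataFrame (columns = conditions).
    """
    if isinstance(matrix, pd.DataFrame):
        condition_names = condition_names or list(matrix.columns)
        y = matrix.to_numpy(dtype=float)
    else:
        y = np.asarray(matrix, dtype=float)
    n, k = y.shape
    if k < 2:
        raise DegenerateDataError("need >= 2 conditions")
    if n < 3:
        raise DegenerateDataError("need >= 3 participants")
    if not np.isfinite(y).all():
        raise DegenerateDataError("complete cases required (found non-finite values)")
    grand = y.mean()
    if np.allclose(y, grand):
        raise DegenerateDataError("constant data: no variance to partition")

    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_total = float(((y - grand) ** 2).sum())
    ss_subject = float(k * ((row_means - grand) ** 2).sum())
    ss_cond = float(n * ((col_means - grand) ** 2).sum())
    ss_err = max(ss_total - ss_subject - ss_cond, 0.0)
    df_num = float(k - 1)
    df_den = float((n - 1) * (k - 1))
    ms_cond = ss_cond / df_num
    ms_err = ss_err / df_den
    if ss_cond <= 1e-12 * ss_total:  # no condition effect beyond float noise
        ss_cond = 0.0
        ms_cond = 0.0
        f_stat, p_unc = 0.0, 1.0
    elif ms_err == 0.0:
        f_stat, p_unc = math.inf, 0.0
    else:
        f_stat = ms_cond / ms_err
        p_unc = float(stats.f.sf(f_stat, df_num, df_den))

    eps = 1.0 if k == 2 else gg_epsilon(y)
    w, chi2, mdf, mp = mauchly_test(y)
    eta2g = ss_cond / (ss_cond + ss_subject + ss_err) if (ss_cond + ss_subject + ss_err) else 0.0

    if math.isnan(eps):
        df_num_adj = df_den_adj = math.nan
        p_adj = p_unc
    else:
        df_num_adj = eps * df_num
        df_den_adj = eps * df_den
        if f_stat == 0.0:
            p_adj = 1.0
        elif math.isinf(f_stat):
            p_adj = 0.0
        else:
            p_adj = float(stats.f.sf(f_stat, df_num_adj, df_den_adj))

    return AnovaResult(
        metric=metric,
        n_subjects=n,
        n_conditions=k,
        ss_condition=ss_cond,
        ss_subject=ss_subject,
        ss_error=ss_err,
        ms_condition=ms_cond,
        ms_error=ms_err,
        F=f_stat,
        df_num=df_num,
        df_den=df_den,
        eta2_g=eta2g,
        epsilon_gg=eps,
        mauchly_w=w,
        mauchly_chi2=chi2,
        mauchly_df=mdf,
        mauchly_p=mp,
        p_uncorrected=p_unc,
        df_num_adj=df_num_adj,
        df_den_adj=df_den_adj,
        p_adjusted=p_adj,
    )


def hedges_g(a: np.ndarray, b: np.ndarray) -> float:
    """Hedges g for paired conditions with the averaged-SD standardizer.

    g = J * (mean(a) - mean(b)) / sqrt((sd_a^2 + sd_b^2) / 2), with the
    small-sample correction J = 1 - 3/(4*(2n-2) - 1).  The SD of the
    difference scores is deliberately not used as the standardizer.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n = a.size
    sd_pool = math.sqrt((a.std(ddof=1) ** 2 + b.std(ddof=1) ** 2) / 2.0)
    diff = float(a.mean() - b.mean())
    if sd_pool == 0.0:
        return 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    j = 1.0 - 3.0 / (4.0 * (2 * n - 2) - 1.0)
    return j * diff / sd_pool


def effect_size_label(g: float) -> str:
    """0.2 / 0.5 / 0.8 cutpoints: very small, small, medium, large."""
    a = abs(g)
    if a < 0.2:
        return "very small"
    if a < 0.5:
        return "small"
    if a < 0.8:
        return "medium"
    return "large"


def posthoc_pairs(
    matrix, condition_names: Sequence[str] | None = None, m: int | None = None
) -> list[PostHocResult]:
    """All pairwise paired t tests with Bonferroni correction and Hedges g.

    ``m`` is the Bonferroni family size (defaults to the number of pairs).
    All pairs are always computed regardless of the omnibus outcome.
    """
    if isinstance(matrix, pd.DataFrame):
        condition_names = condition_names or list(matrix.columns)
        y = matrix.to_numpy(dtype=float)
    else:
        y = np.asarray(matrix, dtype=float)
    n, k = y.shape
    if n < 2:
        raise DegenerateDataError("need >= 2 participants for paired comparisons")
    names = list(condition_names) if condition_names else [f"c{i}" for i in range(k)]
    pairs = list(combinations(range(k), 2))
    m = m or len(pairs)
    out = []
    for i, j in pairs:
        a, b = y[:, i], y[:, j]
        d = a - b
        if np.allclose(d, 0.0):
            t_stat, p_raw = 0.0, 1.0
        else:
            with warnings.catch_warnings():
                # near-identical conditions trigger scipy's catastrophic-
                # cancellation warning; the degenerate cases are handled above
                warnings.simplefilter("ignore", RuntimeWarning)
                t_stat, p_raw = stats.ttest_rel(a, b)
            t_stat, p_raw = float(t_stat), float(p_raw)
        g = hedges_g(a, b)
        out.append(
            PostHocResult(
                condition_a=names[i],
                condition_b=names[j],
                mean_difference=float(a.mean() - b.mean()),
                t=t_stat,
                p_raw=p_raw,
                p_bonferroni=min(1.0, p_raw * m),
                hedges_g=g,
                size_label=effect_size_label(g),
            )
        )
    return out


def bland_altman(
    values_a: np.ndarray,
    values_b: np.ndarray,
    metric: str = "",
    method_pair: tuple[str, str] = ("actigraphy", "psg"),
) -> BlandAltmanResult:
    """Bland-Altman agreement for paired night metrics (a - b).

    Mean difference, SD of differences (ddof=1), 95% limits of agreement
    MD +/- 1.96*SD, and proportional bias as the OLS regression of the
    differences on the pair means (slope, R^2, two-sided p).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size != b.size or a.size < 3:
        raise DegenerateDataError("need >= 3 paired values")
    d = a - b
    means = (a + b) / 2.0
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    undefined = None
    if np.ptp(means) == 0.0:
        slope = intercept = r2 = pval = math.nan
        undefined = "zero variance in pair means: proportional bias undefined"
    else:
        res = stats.linregress(means, d)
        slope, intercept = float(res.slope), float(res.intercept)
        r2, pval = float(res.rvalue**2), float(res.pvalue)
    return BlandAltmanResult(
        metric=metric,
        method_pair=method_pair,
        n=int(a.size),
        mean_difference=md,
        sd_difference=sd,
        loa_low=md - 1.96 * sd,
        loa_high=md + 1.96 * sd,
        prop_bias_slope=slope,
        prop_bias_intercept=intercept,
        prop_bias_r2=r2,
        prop_bias_p=pval,
        undefined=undefined,
    )


def outlier_sensitivity(
    raw_counts: Mapping[str, np.ndarray],
    metrics_pipeline: Callable[[Sequence[str]], Mapping[str, float]],
    z_cut: float = 2.0,
    criterion: float = 0.05,
) -> OutlierReport:
    """Two-tier raw-count outlier identification and sensitivity re-analysis.

    Tier 1 (IQR rule): each participant's IQR of 30-s counts is compared to
    the sample distribution of those IQRs; values outside the Tukey fences
    [Q1 - 1.5*IQR, Q3 + 1.5*IQR] flag the participant.  Tier 2 (z rule):
    participants whose mean count has |z| >= 2 against the sample mean/SD
    of participant means are flagged.  The flag set is the union.  The
    supplied ``metrics_pipeline`` is re-run without the flagged
    participants and the relative change |with - without| / |with| is
    tabulated against the 5% criterion.
    """
    ids = list(raw_counts)
    if len(ids) < 10:
        raise DegenerateDataError("need >= 10 participants for outlier screening")
    iqrs = np.array([stats.iqr(raw_counts[i]) for i in ids])
    means = np.array([np.mean(raw_counts[i]) for i in ids])
    q1, q3 = np.percentile(iqrs, [25, 75])
    fence = 1.5 * (q3 - q1)
    iqr_flag = (iqrs < q1 - fence) | (iqrs > q3 + fence)
    sd = means.std(ddof=1)
    z = (means - means.mean()) / sd if sd > 0 else np.zeros_like(means)
    z_flag = np.abs(z) >= z_cut

    flagged: dict[str, list[str]] = {}
    for pid, f1, f2 in zip(ids, iqr_flag, z_flag):
        rules = (["iqr_fence"] if f1 else []) + (["z_score"] if f2 else [])
        if rules:
            flagged[pid] = rules
    kept = [i for i in ids if i not in flagged]

    metrics_with = dict(metrics_pipeline(ids))
    metrics_without = dict(metrics_pipeline(kept)) if flagged else dict(metrics_with)
    rel = {
        k: (abs(metrics_with[k] - metrics_without[k]) / abs(metrics_with[k])
            if metrics_with[k] != 0 else (0.0 if metrics_without[k] == 0 else math.inf))
        for k in metrics_with
    }
    return OutlierReport(
        flagged=flagged,
        metrics_with=metrics_with,
        metrics_without=metrics_without,
        relative_change=rel,
        within_criterion=all(v < criterion for v in rel.values()),
        criterion=criterion,
    )
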