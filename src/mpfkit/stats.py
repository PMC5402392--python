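"""Statistical procedures for the MRI-histology validation analysis.

Covers group comparison (one-way MANOVA with Wilks' lambda, per-structure
t-tests, Cohen's d), correlation/regression between MPF and LFB optical
density (Pearson r with coefficient CIs, Fisher r-to-z comparison of
correlations, ANCOVA comparison of regression lines), factorial ANOVA with
sum-to-zero coding for regional effects, and scan-rescan repeatability
(Bland-Altman limits of agreement, within-subject coefficient of variation,
Levene's test).  Two-tailed tests at alpha = 0.05 throughout; no
multiple-testing correction is applied.

Standard fits and exact test routines are delegated to scipy/statsmodels;
Wilks' lambda and its Rao F approximation are computed directly from the
within/between scatter matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "RepeatabilityResult",
    "GroupComparison",
    "cohens_d",
    "cohens_d_from_summary",
    "pearson_regression",
    "fisher_compare_correlations",
    "ancova_compare_lines",
    "factorial_anova",
    "manova_wilks",
    "bland_altman",
    "shapiro_wilk",
    "compare_groups",
]


@dataclass
class RegressionResult:
    r: float
    r2: float
    n: int
    p: float
    slope: float
    slope_ci: tuple
    slope_p: float
    intercept: float
    intercept_ci: tuple
    intercept_p: float

    def to_dict(self) -> dict:
        return {"r": self.r, "r2": self.r2, "n": self.n, "p": self.p,
                "slope": self.slope, "slope_ci": list(self.slope_ci),
                "slope_p": self.slope_p, "intercept": self.intercept,
                "intercept_ci": list(self.intercept_ci),
                "intercept_p": self.intercept_p}


@dataclass
class RepeatabilityResult:
    bias: float
    loa_lower: float
    loa_upper: float
    p_bias: float
    within_subject_cov: float
    levene_p: float
    per_subject_cov: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"bias": self.bias, "loa_lower": self.loa_lower,
                "loa_upper": self.loa_upper, "p_bias": self.p_bias,
                "within_subject_cov": self.within_subject_cov,
                "levene_p": self.levene_p}


@dataclass
class GroupComparison:
    wilks_lambda: float
    manova_f: float
    manova_p: float
    per_structure: dict  # name -> {t, p, d, d_ci}

    def to_dict(self) -> dict:
        return {"wilks_lambda": self.wilks_lambda, "manova_f": self.manova_f,
                "manova_p": self.manova_p,
                "per_structure": self.per_structure}


# ---------------------------------------------------------------------------
# effect size
# ---------------------------------------------------------------------------

def cohens_d_from_summary(mean1, sd1, n1, mean2, sd2, n2) -> float:
    """Cohen's d from group summaries: mean difference over the df-weighted
    pooled SD (with equal n this reduces to sqrt((s1^2+s2^2)/2))."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    pooled = np.sqrt(((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2)
                     / (n1 + n2 - 2))
    if pooled <= 0:
        raise ValueError("pooled standard deviation is zero")
    return float((mean1 - mean2) / pooled)


def cohens_d(x1, x2) -> float:
    """Cohen's d between two samples (ddof=1 pooled SD)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return cohens_d_from_summary(x1.mean(), x1.std(ddof=1), x1.size,
                                 x2.mean(), x2.std(ddof=1), x2.size)


def _cohens_d_ci(d, n1, n2, alpha=0.05):
    # normal approximation to the sampling variance of d
    se = np.sqrt((n1 + n2) / (n1 * n2) + d ** 2 / (2.0 * (n1 + n2 - 2)))
    z = sps.norm.ppf(1 - alpha / 2)
    return (d - z * se, d + z * se)


# ---------------------------------------------------------------------------
# correlation / regression
# ---------------------------------------------------------------------------

def pearson_regression(x, y, alpha: float = 0.05) -> RegressionResult:
    """Pearson correlation and OLS line of y on x with coefficient CIs.

    The correlation p-value comes from t = r sqrt((n-2)/(1-r^2)); coefficient
    confidence intervals use t quantiles with n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least three points")
    if np.var(x) == 0:
        raise ValueError("x is constant")
    res = sps.linregress(x, y)
    tq = sps.t.ppf(1 - alpha / 2, n - 2)
    slope_ci = (res.slope - tq * res.stderr, res.slope + tq * res.stderr)
    icept_ci = (res.intercept - tq * res.intercept_stderr,
                res.intercept + tq * res.intercept_stderr)
    if res.intercept_stderr == 0:  # exact fit
        icept_p = 1.0 if res.intercept == 0 else 0.0
    else:
        t_icept = res.intercept / res.intercept_stderr
        icept_p = 2 * sps.t.sf(abs(t_icept), n - 2)
    return RegressionResult(r=float(res.rvalue), r2=float(res.rvalue ** 2),
                            n=int(n), p=float(res.pvalue),
                            slope=float(res.slope), slope_ci=slope_ci,
                            slope_p=float(res.pvalue),
                            intercept=float(res.intercept),
                            intercept_ci=icept_ci,
                            intercept_p=float(icept_p))


def fisher_compare_correlations(r1, n1, r2, n2):
    """Two-sided comparison of two independent Pearson correlations through
    Fisher's r-to-z transformation.  Returns (z, p)."""
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1")
        if n <= 3:
            raise ValueError("need n > 3 per correlation")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3)
                                                    + 1.0 / (n2 - 3))
    p = 2 * sps.norm.sf(abs(z))
    return float(z), float(p)


def ancova_compare_lines(x, y, group) -> dict:
    """ANCOVA comparison of regression lines between two groups.

    Fits y ~ group + x + group:x; the interaction term tests slope equality.
    If slopes are homogeneous, the group effect in the reduced additive model
    y ~ group + x tests intercept equality.
    """
    import statsmodels.formula.api as smf
    df = pd.DataFrame({"x": np.asarray(x, float), "y": np.asarray(y, float),
                       "g": np.asarray(group)})
    counts = df.groupby("g").size()
    if len(counts) != 2 or counts.min() < 3:
        raise ValueError("need two groups with at least three points each")
    full = smf.ols("y ~ C(g) * x", data=df).fit()
    inter_term = [t for t in full.pvalues.index if ":" in t]
    p_slope = float(full.pvalues[inter_term[0]])
    reduced = smf.ols("y ~ C(g) + x", data=df).fit()
    group_term = [t for t in reduced.pvalues.index if t.startswith("C(g)")]
    p_intercept = float(reduced.pvalues[group_term[0]])
    return {"p_slope_diff": p_slope, "p_intercept_diff": p_intercept}


# ---------------------------------------------------------------------------
# factorial ANOVA
# ---------------------------------------------------------------------------

def factorial_anova(values, factor_table: pd.DataFrame,
                    terms: list | None = None) -> pd.DataFrame:
    """Fixed-effects factorial ANOVA with sum-to-zero (effect) coding and
    Type-III sums of squares.

    ``terms`` selects the model terms; the default is all main effects plus
    all pairwise interactions (no higher-order terms).  Returns a DataFrame
    indexed by term with columns F and p.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm
    factor_table = pd.DataFrame(factor_table).copy()
    factors = list(factor_table.columns)
    for f_ in factors:
        if factor_table[f_].nunique() < 2:
            raise ValueError(f"factor {f_!r} needs at least two levels")
    if terms is None:
        terms = factors + [(a, b) for i, a in enumerate(factors)
                           for b in factors[i + 1:]]
    df = factor_table.copy()
    df["_y"] = np.asarray(values, dtype=float)

    def enc(name):
        return f"C({name}, Sum)"

    rhs = []
    for t in terms:
        rhs.append(enc(t) if isinstance(t, str) else
                   ":".join(enc(u) for u in t))
    model = smf.ols("_y ~ " + " + ".join(rhs), data=df).fit()
    if model.df_resid <= 0:
        raise ValueError("model saturated: no residual degrees of freedom")
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("aliased terms in the requested model: "
                         + " + ".join(rhs))
    table = anova_lm(model, typ=3)
    out = {}
    for t, r in zip(terms, rhs):
        key = t if isinstance(t, str) else ":".join(t)
        out[key] = {"F": float(table.loc[r, "F"]),
                    "p": float(table.loc[r, "PR(>F)"]),
                    "df": float(table.loc[r, "df"])}
    return pd.DataFrame(out).T


# ---------------------------------------------------------------------------
# MANOVA (Wilks)
# ---------------------------------------------------------------------------

def manova_wilks(group, response_matrix):
    """One-way MANOVA via Wilks' lambda and Rao's F approximation.

    Lambda = det(W) / det(W + B) with W the pooled within-group and B the
    between-group scatter matrix.  Returns (lambda, F, p).
    """
    y = np.asarray(response_matrix, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    group = np.asarray(group)
    levels = np.unique(group)
    n, p = y.shape
    g = len(levels)
    if g < 2:
        raise ValueError("need at least two groups")
    if n <= p + g - 1:
        raise ValueError("too few observations for the number of responses")
    grand = y.mean(axis=0)
    w = np.zeros((p, p))
    b = np.zeros((p, p))
    for lev in levels:
        yi = y[group == lev]
        ci = yi.mean(axis=0)
        d = yi - ci
        w += d.T @ d
        m = (ci - grand)[:, None]
        b += yi.shape[0] * (m @ m.T)
    det_w = np.linalg.det(w)
    det_t = np.linalg.det(w + b)
    if det_t <= 0 or det_w < 0:
        raise ValueError("singular scatter matrices")
    lam = det_w / det_t
    q = g - 1
    v = n - g
    denom = p * p + q * q - 5
    s = np.sqrt((p * p * q * q - 4.0) / denom) if denom > 0 else 1.0
    m_ = v - (p - q + 1) / 2.0
    df1 = p * q
    df2 = m_ * s - p * q / 2.0 + 1.0
    lam_s = lam ** (1.0 / s)
    f_stat = (1.0 - lam_s) / lam_s * df2 / df1
    p_val = sps.f.sf(f_stat, df1, df2)
    return float(lam), float(f_stat), float(p_val)


# ---------------------------------------------------------------------------
# repeatability
# ---------------------------------------------------------------------------

def bland_altman(m1, m2, cov_aggregate: str = "mean") -> RepeatabilityResult:
    """Bland-Altman agreement between paired measurements.

    Bias is mean(m1 - m2) with limits of agreement bias +/- 1.96 SD of the
    differences and a one-sample t-test on the differences.  The
    within-subject CoV is 100 * SD(pair)/mean(pair) per subject, aggregated
    as the arithmetic mean (or RMS with ``cov_aggregate='rms'``); subjects
    with zero pair mean are excluded.  Levene's test compares the variances
    of the two measurement sets.
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.shape != m2.shape or m1.size < 3:
        raise ValueError("need at least three pairs")
    diff = m1 - m2
    bias = diff.mean()
    sd = diff.std(ddof=1)
    _, p_bias = sps.ttest_1samp(diff, 0.0)
    pair_mean = (m1 + m2) / 2.0
    pair_sd = np.abs(diff) / np.sqrt(2.0)
    keep = pair_mean != 0
    if not keep.all():
        import logging
        logging.getLogger(__name__).warning(
            "%d subjects excluded from CoV (zero pair mean)", (~keep).sum())
    cov_i = 100.0 * pair_sd[keep] / pair_mean[keep]
    cov = float(np.sqrt(np.mean(cov_i ** 2)) if cov_aggregate == "rms"
                else cov_i.mean())
    _, levene_p = sps.levene(m1, m2, center="mean")
    return RepeatabilityResult(bias=float(bias),
                               loa_lower=float(bias - 1.96 * sd),
                               loa_upper=float(bias + 1.96 * sd),
                               p_bias=float(p_bias),
                               within_subject_cov=cov,
                               levene_p=float(levene_p),
                               per_subject_cov=list(cov_i))


def shapiro_wilk(x):
    """Shapiro-Wilk normality test (W, p); errors on constant input."""
    x = np.asarray(x, dtype=float)
    if not (3 <= x.size <= 5000):
        raise ValueError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant input")
    w, p = sps.shapiro(x)
    return float(w), float(p)


# ---------------------------------------------------------------------------
# group comparison on the tidy table
# ---------------------------------------------------------------------------

def compare_groups(table: pd.DataFrame, measure: str = "mpf_percent",
                   group_col: str = "group") -> GroupComparison:
    """MANOVA across structures followed by per-structure t-tests and effect
    sizes, on an aggregated tidy table (one row per animal x structure)."""
    sub = table[table["measure"] == measure]
    wide = sub.pivot_table(index=["animal_id", group_col],
                           columns="structure", values="value")
    wide = wide.dropna()
    groups = wide.index.get_level_values(group_col).to_numpy()
    lam, f_stat, p_val = manova_wilks(groups, wide.to_numpy())
    levels = np.unique(groups)
    per = {}
    for name in wide.columns:
        x1 = wide.loc[wide.index.get_level_values(group_col) == levels[0],
                      name].to_numpy()
        x2 = wide.loc[wide.index.get_level_values(group_col) == levels[1],
                      name].to_numpy()
        t, p = sps.ttest_ind(x1, x2, equal_var=True)
        d = cohens_d(x1, x2)
        per[name] = {"t": float(t), "p": float(p), "d": d,
                     "d_ci": list(_cohens_d_ci(d, x1.size, x2.size))}
    return GroupComparison(wilks_lambda=lam, manova_f=f_stat, manova_p=p_val,
                           per_structure=per)
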