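"""Statistical engine: correlations with BCa bootstrap CIs, repeated-measures
ANOVA, and backward multivariable regression.

Inference follows the small-sample bootstrap-first convention: every estimate
(Pearson r, partial r, standardised beta) carries a bias-corrected and
accelerated (BCa) 95% bootstrap confidence interval from 1000 case resamples,
and significance is decided by whether that interval excludes zero; the
original-sample p value is reported for transparency.  The resampling unit is
always the subject row.  Variables are demeaned and scaled to unit variance
before modelling; binary predictors are coded 0/1 and standardised like
continuous ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.anova import AnovaRM

N_BOOT = 1000
CI_LEVEL = 0.95
P_RETAIN = 0.1


def standardize(x) -> np.ndarray:
    """Demean and scale to unit variance (n-1 denominator)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant variable")
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# BCa bootstrap
# ---------------------------------------------------------------------------


def bca_ci(statistic, data: np.ndarray, n_boot: int = N_BOOT,
           level: float = CI_LEVEL, rng=None, resample_indices=None,
           max_redraws: int = 100):
    """Bias-corrected and accelerated bootstrap confidence interval.

    Parameters
    ----------
    statistic
        Callable mapping a (rows, cols) array to a scalar.
    data
        2-D array of case rows (resampling unit = row).
    resample_indices
        Optional precomputed (n_boot, n) index matrix; when given, those exact
        resamples are used (reproducibility / oracle comparisons).

    Returns ``(lo, hi)``.  The bias term is z0 = Phi^-1(#{theta* < theta}/B);
    the acceleration a comes from the jackknife skewness of the statistic;
    the interval is the pair of empirical bootstrap quantiles at the adjusted
    levels.  A resample on which the statistic is undefined (NaN) is redrawn.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    n = data.shape[0]
    rng = np.random.default_rng(rng)
    theta = float(statistic(data))

    if resample_indices is not None:
        idx = np.asarray(resample_indices)
        n_boot = idx.shape[0]
        boots = np.array([statistic(data[row]) for row in idx], dtype=float)
        if np.isnan(boots).any():
            raise ValueError("statistic undefined on a provided resample")
    else:
        boots = np.empty(n_boot)
        redraws = 0
        for b in range(n_boot):
            for _ in range(max_redraws + 1):
                val = statistic(data[rng.integers(0, n, n)])
                if np.isfinite(val):
                    break
                redraws += 1
            else:
                raise RuntimeError("statistic undefined on too many resamples")
            boots[b] = val
        if redraws:
            warnings.warn(f"redrew {redraws} degenerate bootstrap resample(s)")

    if np.ptp(boots) == 0:
        warnings.warn("degenerate bootstrap distribution; interval collapsed")
        return float(boots[0]), float(boots[0])

    jack = np.array([statistic(np.delete(data, i, axis=0)) for i in range(n)])
    a1, a2 = adjusted_levels(boots, theta, jack, level=level)
    lo, hi = np.quantile(boots, [a1, a2])
    return float(lo), float(hi)


def adjusted_levels(boots: np.ndarray, theta: float, jack: np.ndarray,
                    level: float = CI_LEVEL):
    """BCa-adjusted quantile levels (a1, a2) for a bootstrap distribution.

    z0 = Phi^-1 of the fraction of replicates below the observed statistic;
    a = jackknife skewness of the statistic.  With z0 = 0 and a = 0 the
    levels reduce exactly to the plain percentile pair.
    """
    n_boot = boots.size
    prop = np.mean(boots < theta)
    prop = min(max(prop, 1.0 / (2 * n_boot)), 1 - 1.0 / (2 * n_boot))
    z0 = stats.norm.ppf(prop)
    d = jack.mean() - jack
    denom = 6.0 * (d ** 2).sum() ** 1.5
    a = (d ** 3).sum() / denom if denom > 0 else 0.0
    alpha = (1 - level) / 2
    z_lo, z_hi = stats.norm.ppf([alpha, 1 - alpha])
    a1 = stats.norm.cdf(z0 + (z0 + z_lo) / (1 - a * (z0 + z_lo)))
    a2 = stats.norm.cdf(z0 + (z0 + z_hi) / (1 - a * (z0 + z_hi)))
    return float(a1), float(a2)


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------


@dataclass
class AssocResult:
    """One association cell: estimate, original-sample p, BCa 95% CI."""

    estimate: float
    p_original: float
    ci_lo: float = np.nan
    ci_hi: float = np.nan
    n: int = 0
    n_boot: int = 0
    kind: str = "pearson"

    @property
    def significant(self) -> bool:
        """CI-based inference: interval excludes zero."""
        return bool(np.isfinite(self.ci_lo) and (self.ci_lo > 0 or self.ci_hi < 0))


def _pearson_r(xy: np.ndarray) -> float:
    x, y = xy[:, 0], xy[:, 1]
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return np.corrcoef(x, y)[0, 1]


def pearson(x, y, ci: bool = True, n_boot: int = N_BOOT, rng=None) -> AssocResult:
    """Pearson product-moment correlation with t-based p (n-2 df) and BCa CI."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need aligned samples with n >= 4")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValueError("constant input")
    r, p = stats.pearsonr(x, y)
    res = AssocResult(float(r), float(p), n=x.size, kind="pearson")
    if ci:
        res.ci_lo, res.ci_hi = bca_ci(_pearson_r, np.column_stack([x, y]),
                                      n_boot=n_boot, rng=rng)
        res.n_boot = n_boot
    return res


def _residualize(v: np.ndarray, cov: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(v)), cov])
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def _partial_r(mat: np.ndarray) -> float:
    """columns: x, y, covariates..."""
    rx = _residualize(mat[:, 0], mat[:, 2:])
    ry = _residualize(mat[:, 1], mat[:, 2:])
    if rx.std() == 0 or ry.std() == 0:
        return np.nan
    return np.corrcoef(rx, ry)[0, 1]


def partial_corr(x, y, covariates, ci: bool = True, n_boot: int = N_BOOT,
                 rng=None) -> AssocResult:
    """Pearson partial correlation by the residual method.

    ``covariates`` is one series or a (n, k) matrix.  p uses a t distribution
    with n - 2 - k degrees of freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    cov = np.asarray(covariates, float)
    if cov.ndim == 1:
        cov = cov[:, None]
    n, k = cov.shape
    if not (x.size == y.size == n) or n < k + 4:
        raise ValueError("need aligned samples with n >= k + 4")
    for j in range(k):
        for other in (x, y):
            c = np.corrcoef(cov[:, j], other)[0, 1]
            if np.abs(c) >= 1 - 1e-12:
                raise ValueError("covariate collinear with x or y (|r| = 1)")
    mat = np.column_stack([x, y, cov])
    r = _partial_r(mat)
    if not np.isfinite(r):
        raise ValueError("partial correlation undefined (zero-variance residuals)")
    df = n - 2 - k
    t = r * np.sqrt(df / (1 - r ** 2)) if abs(r) < 1 else np.inf
    p = 2 * stats.t.sf(abs(t), df)
    res = AssocResult(float(r), float(p), n=n, kind="partial")
    if ci:
        res.ci_lo, res.ci_hi = bca_ci(_partial_r, mat, n_boot=n_boot, rng=rng)
        res.n_boot = n_boot
    return res


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    f: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float
    pairwise: pd.DataFrame  # contrast, mean_diff, sd_diff, p_bonferroni


def rm_anova(panel: pd.DataFrame, value: str = "accuracy",
             timepoints=("pre", "post", "followup")) -> AnovaResult:
    """One-way within-subject ANOVA over timepoints with Bonferroni pairwise
    paired t-tests.  Sphericity is not adjusted (unadjusted degrees of freedom).

    ``panel``: long table with columns subject, timepoint, ``value`` —
    complete cases across all timepoints required.
    """
    wide = panel.pivot(index="subject", columns="timepoint", values=value)
    wide = wide[list(timepoints)].dropna()
    if wide.shape[0] < 2:
        raise ValueError("need at least 2 complete subjects")
    n_subj, m_tp = wide.shape
    ss_time = n_subj * ((wide.mean(axis=0) - wide.to_numpy().mean()) ** 2).sum()
    if ss_time == 0:  # no Time effect at all; F = 0/MS_error by convention
        pairs = [{"contrast": f"{b} - {a}", "mean_diff": 0.0, "sd_diff": 0.0,
                  "p_bonferroni": 1.0}
                 for i, a in enumerate(timepoints) for b in timepoints[i + 1:]]
        return AnovaResult(0.0, m_tp - 1, (m_tp - 1) * (n_subj - 1), 1.0, 0.0,
                           pd.DataFrame(pairs))
    long = wide.reset_index().melt(id_vars="subject", var_name="timepoint",
                                   value_name=value)
    fit = AnovaRM(long, depvar=value, subject="subject",
                  within=["timepoint"]).fit()
    row = fit.anova_table.iloc[0]
    f, df1, df2 = float(row["F Value"]), int(row["Num DF"]), int(row["Den DF"])
    p = float(row["Pr > F"])
    # exact for one-way RM: eta_p^2 = SS_time / (SS_time + SS_error) = F*df1/(F*df1+df2)
    eta = f * df1 / (f * df1 + df2)
    m = len(timepoints)
    n_pairs = m * (m - 1) // 2
    rows = []
    for i in range(m):
        for j in range(i + 1, m):
            a, b = timepoints[i], timepoints[j]
            diff = wide[b] - wide[a]
            t, pp = stats.ttest_rel(wide[b], wide[a])
            rows.append({"contrast": f"{b} - {a}",
                         "mean_diff": float(diff.mean()),
                         "sd_diff": float(diff.std(ddof=1)),
                         "p_bonferroni": float(min(1.0, pp * n_pairs))})
    return AnovaResult(f, df1, df2, p, float(eta), pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Backward multivariable regression
# ---------------------------------------------------------------------------


@dataclass
class ModelResult:
    retained: list
    betas: pd.Series
    p_values: pd.Series
    ci: pd.DataFrame            # predictor x (lo, hi), BCa over case resamples
    adj_r_squared: float
    r_squared: float
    model_p: float
    elimination_trace: list = field(default_factory=list)


def backward_select(y, X: pd.DataFrame, p_retain: float = P_RETAIN,
                    forced=(), ci: bool = True, n_boot: int = N_BOOT,
                    rng=None) -> ModelResult:
    """Backward elimination on standardised OLS, retaining predictors with
    p < ``p_retain``.

    At each step the non-forced predictor with the largest coefficient
    p >= p_retain is removed and the model refitted.  Beta CIs are BCa over
    case resamples, refitting the *final* model.  Returns an intercept-only
    result (empty retained set) when nothing survives.
    """
    yv = standardize(y)
    Xs = pd.DataFrame({c: standardize(X[c]) for c in X.columns})
    n = len(yv)
    if n <= X.shape[1] + 2:
        raise ValueError("too few cases for the candidate set")
    corr = Xs.corr().to_numpy()
    hi = np.argwhere(np.triu(np.abs(corr) >= 1 - 1e-10, k=1))
    if hi.size:
        i, j = hi[0]
        raise ValueError(
            f"perfect collinearity between {X.columns[i]!r} and {X.columns[j]!r}")

    cols = list(X.columns)
    trace = []
    fit = None
    while cols:
        design = sm.add_constant(Xs[cols].to_numpy())
        fit = sm.OLS(yv, design).fit()
        pvals = pd.Series(fit.pvalues[1:], index=cols)
        droppable = pvals.drop(index=[c for c in forced if c in cols],
                               errors="ignore")
        if droppable.empty or droppable.max() < p_retain:
            break
        worst = droppable.idxmax()
        trace.append({"removed": worst, "p": float(droppable.max()),
                      "remaining": [c for c in cols if c != worst]})
        cols.remove(worst)
        fit = None

    if not cols:
        return ModelResult([], pd.Series(dtype=float), pd.Series(dtype=float),
                           pd.DataFrame(columns=["lo", "hi"]),
                           adj_r_squared=0.0, r_squared=0.0, model_p=np.nan,
                           elimination_trace=trace)

    betas = pd.Series(fit.params[1:], index=cols)
    pvals = pd.Series(fit.pvalues[1:], index=cols)
    ci_df = pd.DataFrame(index=cols, columns=["lo", "hi"], dtype=float)
    if ci:
        mat = np.column_stack([yv, Xs[cols].to_numpy()])

        def beta_stat(j):
            def stat(m):
                d = sm.add_constant(m[:, 1:])
                coef, *_ = np.linalg.lstsq(d, m[:, 0], rcond=None)
                return coef[1 + j]
            return stat

        for j, c in enumerate(cols):
            ci_df.loc[c] = bca_ci(beta_stat(j), mat, n_boot=n_boot, rng=rng)
    return ModelResult(cols, betas, pvals, ci_df,
                       adj_r_squared=float(fit.rsquared_adj),
                       r_squared=float(fit.rsquared),
                       model_p=float(fit.f_pvalue),
                       elimination_trace=trace)


# ---------------------------------------------------------------------------
# The association grid (Table-2 shape)
# ---------------------------------------------------------------------------

ENDPOINTS = ("acquisition", "retention", "overall")


def association_table(gains: pd.DataFrame, predictors: pd.DataFrame,
                      baseline_col: str = "baseline", n_boot: int = N_BOOT,
                      seed: int = 0) -> pd.DataFrame:
    """Partial correlation of every predictor with every learning endpoint,
    controlling baseline writing accuracy, with BCa 95% CIs.

    ``gains``: columns subject, baseline, acquisition, retention, overall.
    ``predictors``: column subject plus one column per predictor.
    Baseline-vs-gain Pearson correlations are included as predictor
    ``baseline`` rows with kind ``pearson``.
    """
    merged = gains.merge(predictors, on="subject", validate="1:1")
    baseline = merged[baseline_col].to_numpy()
    pred_cols = [c for c in predictors.columns if c != "subject"]
    seeds = np.random.SeedSequence(seed).spawn(
        (len(pred_cols) + 1) * len(ENDPOINTS))
    rows = []
    si = 0
    for endpoint in ENDPOINTS:
        yv = merged[endpoint].to_numpy()
        res = pearson(baseline, yv, n_boot=n_boot,
                      rng=np.random.default_rng(seeds[si])); si += 1
        rows.append({"endpoint": endpoint, "predictor": "baseline",
                     "kind": "pearson", **_as_row(res)})
        for c in pred_cols:
            xv = merged[c].to_numpy(dtype=float)
            if len(xv) < 8:
                rows.append({"endpoint": endpoint, "predictor": c,
                             "kind": "partial", "r": np.nan, "p": np.nan,
                             "ci_lo": np.nan, "ci_hi": np.nan,
                             "significant": False, "n": len(xv)})
                si += 1
                continue
            res = partial_corr(xv, yv, baseline, n_boot=n_boot,
                               rng=np.random.default_rng(seeds[si])); si += 1
            rows.append({"endpoint": endpoint, "predictor": c,
                         "kind": "partial", **_as_row(res)})
    return pd.DataFrame(rows)


def _as_row(res: AssocResult) -> dict:
    return {"r": res.estimate, "p": res.p_original, "ci_lo": res.ci_lo,
            "ci_hi": res.ci_hi, "significant": res.significant, "n": res.n}
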