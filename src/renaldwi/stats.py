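"""Statistical analyses over per-kidney records.

Implements the cohort-level procedures:

* Pearson correlation (eGFR vs mGFR and per-context averages);
* bilateral repeated-measures correlation via a bivariate linear mixed model
  with subject-level random intercepts for both variables (the classical
  Hamlett-style decomposition into between- and within-subject covariance);
  the reported r is the *total* correlation
  ``r = (cov_b + cov_w) / sqrt((var_b+var_w)_x (var_b+var_w)_y)``;
* Benjamini-Hochberg step-up adjustment for table-wide families;
* mixed-effects LASSO: L1-penalized fixed effects with a subject random
  intercept, variance components re-estimated along the penalty path, and
  the penalty chosen by subject-grouped K-fold cross-validated deviance;
* bivariable regressions testing a metric's added value over eGFR;
* Welch two-sample t tests for proteinuria group differences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize
from sklearn.linear_model import Lasso

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Pearson

def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input has no defined correlation")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg

def bh_adjust(p_values) -> np.ndarray:
    """Step-up FDR adjustment: ``adj_(i) = min_{j>=i} (m/j) p_(j)``, capped
    at 1, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# Bilateral mixed-model correlation

@dataclass
class CorrelationResult:
    r: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_subjects: int
    n_kidneys: int
    adjusted_p: float = np.nan
    method: str = "mixed_ml"
    context: str = ""
    between: np.ndarray | None = None  # 2x2 between-subject covariance
    within: np.ndarray | None = None


def _cs_cov(sb: np.ndarray, sw: np.ndarray, m: int) -> np.ndarray:
    """2m x 2m covariance of [x_1..x_m, y_1..y_m] under the bivariate
    random-intercept model: kron(Sb, J_m) + kron(Sw, I_m)."""
    J = np.ones((m, m))
    I = np.eye(m)
    return np.block(
        [
            [sb[0, 0] * J + sw[0, 0] * I, sb[0, 1] * J + sw[0, 1] * I],
            [sb[1, 0] * J + sw[1, 0] * I, sb[1, 1] * J + sw[1, 1] * I],
        ]
    )


def _theta_to_cov(theta):
    mux, muy = theta[0], theta[1]
    lbx, lby, rb = theta[2], theta[3], np.tanh(theta[4])
    lwx, lwy, rw = theta[5], theta[6], np.tanh(theta[7])
    sbx, sby = np.exp(lbx), np.exp(lby)
    swx, swy = np.exp(lwx), np.exp(lwy)
    sb = np.array([[sbx**2, rb * sbx * sby], [rb * sbx * sby, sby**2]])
    sw = np.array([[swx**2, rw * swx * swy], [rw * swx * swy, swy**2]])
    return mux, muy, sb, sw


def _total_r(theta) -> float:
    _, _, sb, sw = _theta_to_cov(theta)
    t = sb + sw
    return float(t[0, 1] / np.sqrt(t[0, 0] * t[1, 1]))


class _MixedCorrNLL:
    """Negative log-likelihood, vectorized over subjects grouped by size."""

    def __init__(self, x, y, subjects):
        df = pd.DataFrame({"s": subjects, "x": x, "y": y})
        self.blocks = []  # (m, X (n_g, m), Y (n_g, m))
        for m, grp in df.groupby(df.groupby("s")["s"].transform("size")):
            g = grp.sort_values("s")
            n_g = g["s"].nunique()
            self.blocks.append(
                (
                    int(m),
                    g["x"].to_numpy().reshape(n_g, int(m)),
                    g["y"].to_numpy().reshape(n_g, int(m)),
                )
            )

    def __call__(self, theta) -> float:
        mux, muy, sb, sw = _theta_to_cov(theta)
        nll = 0.0
        for m, X, Y in self.blocks:
            C = _cs_cov(sb, sw, m)
            try:
                L = np.linalg.cholesky(C)
            except np.linalg.LinAlgError:
                return 1e12
            logdet = 2.0 * np.sum(np.log(np.diag(L)))
            R = np.hstack([X - mux, Y - muy])  # (n_g, 2m)
            Z = np.linalg.solve(L, R.T)  # (2m, n_g)
            nll += 0.5 * (X.shape[0] * logdet + np.sum(Z**2))
        return float(nll)


def _moment_start(x, y, subjects):
    df = pd.DataFrame({"s": subjects, "x": x, "y": y})
    total = np.cov(np.vstack([x, y]))
    cent = df.groupby("s")[["x", "y"]].transform("mean")
    resid = df[["x", "y"]].to_numpy() - cent.to_numpy()
    sizes = df.groupby("s")["s"].transform("size").to_numpy()
    multi = sizes > 1
    if multi.sum() >= 4:
        # scale within-group residual covariance by m/(m-1) per observation
        corr = (sizes[multi] / (sizes[multi] - 1.0))[:, None]
        rw = resid[multi] * np.sqrt(corr)
        sw = rw.T @ rw / multi.sum()
    else:
        sw = total / 2.0
    sw = sw + 1e-8 * np.eye(2) * max(np.trace(total), 1.0)
    sb = total - sw
    # keep the between part positive definite
    ev, U = np.linalg.eigh(sb)
    floor = 1e-4 * max(np.trace(total), 1e-6)
    sb = U @ np.diag(np.clip(ev, floor, None)) @ U.T

    def pack(s):
        sx, sy = np.sqrt(s[0, 0]), np.sqrt(s[1, 1])
        rho = np.clip(s[0, 1] / (sx * sy), -0.99, 0.99)
        return np.log(sx), np.log(sy), np.arctanh(rho)

    return np.array([x.mean(), y.mean(), *pack(sb), *pack(sw)])


def mixed_corr(
    x,
    y,
    subjects,
    ci_method: str = "delta-z",
    context: str = "",
) -> CorrelationResult:
    """Repeated-measures (bilateral) correlation via bivariate mixed-model ML.

    ``subjects`` labels repeated measurements (kidneys) of the same subject.
    With one observation per subject the model degenerates to independent
    sampling and the plain Pearson estimate is returned (flagged in
    ``method``).  ``ci_method``: ``"delta-z"`` (default) propagates the
    observed-information SE of r through the Fisher transform;
    ``"fisher-n"`` uses 1/sqrt(n_subjects - 3).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    subjects = np.asarray(subjects)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y, subjects = x[keep], y[keep], subjects[keep]
    n_sub = len(np.unique(subjects))
    n_obs = x.size
    if n_obs < 4 or n_sub < 3:
        raise ValueError("too few subjects for a correlation")

    sizes = pd.Series(subjects).value_counts()
    if (sizes == 1).all():
        r, p = pearson(x, y)
        return _pearson_result(r, p, n_sub, n_obs, context)

    r_all = np.corrcoef(x, y)[0, 1]
    if abs(r_all) > 1 - 1e-12:
        # exactly collinear variables: ML covariance is singular
        r = float(np.sign(r_all))
        return CorrelationResult(
            r=r, se=0.0, ci_low=r, ci_high=r, p=0.0,
            n_subjects=n_sub, n_kidneys=n_obs,
            method="degenerate_collinear", context=context,
        )

    try:
        nll = _MixedCorrNLL(x, y, subjects)
        theta0 = _moment_start(x, y, subjects)
        res = minimize(nll, theta0, method="L-BFGS-B")
        if not np.isfinite(res.fun) or res.fun >= 1e11:
            raise np.linalg.LinAlgError("singular covariance")
        theta = res.x
        r = _total_r(theta)
        se_r = _delta_se(nll, theta)
    except (np.linalg.LinAlgError, ValueError) as exc:
        # singular within-subject structure: fall back to subject means
        logger.warning("mixed_corr fallback to subject-mean Pearson: %s", exc)
        df = pd.DataFrame({"s": subjects, "x": x, "y": y}).groupby("s").mean()
        r, p = pearson(df["x"], df["y"])
        out = _pearson_result(r, p, n_sub, n_obs, context)
        out.method = "subject_mean_pearson"
        return out

    _, _, sb, sw = _theta_to_cov(theta)
    r_c = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    z = np.arctanh(r_c)
    if ci_method == "fisher-n":
        se_z = 1.0 / np.sqrt(max(n_sub - 3, 1))
    else:
        se_z = se_r / (1.0 - r_c**2)
    ci = np.tanh([z - 1.959963984540054 * se_z, z + 1.959963984540054 * se_z])
    p = 2.0 * sps.norm.sf(abs(z) / se_z) if se_z > 0 else 0.0
    return CorrelationResult(
        r=float(r),
        se=float(se_r),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p=float(p),
        n_subjects=n_sub,
        n_kidneys=n_obs,
        method="mixed_ml",
        context=context,
        between=sb,
        within=sw,
    )


def _pearson_result(r, p, n_sub, n_obs, context) -> CorrelationResult:
    se = np.sqrt((1 - r**2) / max(n_obs - 2, 1))
    r_c = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    se_z = 1.0 / np.sqrt(max(n_obs - 3, 1))
    ci = np.tanh([np.arctanh(r_c) - 1.96 * se_z, np.arctanh(r_c) + 1.96 * se_z])
    return CorrelationResult(
        r=float(r),
        se=float(se),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p=float(p),
        n_subjects=n_sub,
        n_kidneys=n_obs,
        method="pearson",
        context=context,
    )


def _delta_se(nll, theta) -> float:
    """Observed-information SE of the total correlation via the delta method."""
    from statsmodels.tools.numdiff import approx_fprime, approx_hess

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        H = approx_hess(theta, nll)
        grad = approx_fprime(theta, lambda t: np.atleast_1d(_total_r(t))).ravel()
    try:
        cov = np.linalg.pinv(H)
        var = float(grad @ cov @ grad)
    except np.linalg.LinAlgError:
        return np.nan
    return float(np.sqrt(max(var, 0.0)))


# ---------------------------------------------------------------------------
# Mixed-effects LASSO

@dataclass
class LassoModel:
    coef: np.ndarray  # original scale
    coef_std: np.ndarray  # standardized-predictor scale
    intercept: float
    alpha: float
    tau2: float
    sigma2: float
    r2_marginal: float
    r2_conditional: float
    feature_names: list
    alphas: np.ndarray = field(default_factory=lambda: np.array([]))
    cv_deviance: np.ndarray = field(default_factory=lambda: np.array([]))
    fold_of_subject: dict = field(default_factory=dict)
    seed: int = 0
    dropped: list = field(default_factory=list)

    def predict_fixed(self, X) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.coef


def _group_codes(groups):
    """Integer codes, per-group sizes and per-observation sizes."""
    codes, _ = pd.factorize(groups)
    counts = np.bincount(codes).astype(float)
    return codes, counts


def _group_means(v, codes, counts):
    if v.ndim == 1:
        return np.bincount(codes, weights=v) / counts
    S = np.zeros((counts.size, v.shape[1]))
    np.add.at(S, codes, v)
    return S / counts[:, None]


def _cs_whiten(v, codes, counts, sigma2, tau2):
    """Multiply by sigma * V^{-1/2} for V = sigma2*I + tau2*J per group
    (identity-variance scale preserved)."""
    v = np.asarray(v, dtype=float)
    means = _group_means(v, codes, counts)
    c = 1.0 - np.sqrt(sigma2) / np.sqrt(sigma2 + counts * tau2)
    if v.ndim == 1:
        return v - c[codes] * means[codes]
    return v - c[codes, None] * means[codes]


def _cs_nll(resid, codes, counts, sigma2, tau2) -> float:
    """Gaussian -2 loglik of residuals under the compound-symmetry marginal
    covariance (vectorized over groups)."""
    lam = sigma2 + counts * tau2
    rbar = np.bincount(codes, weights=resid) / counts
    rss = np.bincount(codes, weights=resid**2)
    qf = rss / sigma2 - (tau2 * counts**2 * rbar**2) / (sigma2 * lam)
    dev = (counts - 1) * np.log(sigma2) + np.log(lam) + qf + counts * np.log(2 * np.pi)
    return float(dev.sum())


def _update_variances(resid, codes, counts, start=(0.1, 1.0)):
    def obj(lp):
        return _cs_nll(resid, codes, counts, np.exp(lp[1]), np.exp(lp[0]))

    res = minimize(
        obj,
        np.log(np.maximum(start, 1e-8)),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 300},
    )
    tau2, sigma2 = np.exp(res.x)
    return float(tau2), float(sigma2)


def _fit_at_alpha(Xs, y, codes, counts, alpha, n_iter=3, coef_init=None):
    """Inner solver: iterate GLS whitening <-> L1 fixed-effect fit <->
    variance-component ML update."""
    n = y.size
    tau2, sigma2 = 0.0, float(np.var(y)) or 1.0
    coef = np.zeros(Xs.shape[1]) if coef_init is None else coef_init.copy()
    for _ in range(n_iter):
        Xw = _cs_whiten(Xs, codes, counts, sigma2, tau2)
        yw = _cs_whiten(y, codes, counts, sigma2, tau2)
        ow = _cs_whiten(np.ones(n), codes, counts, sigma2, tau2)
        # partial out the (unpenalized) intercept
        denom = float(ow @ ow)
        if denom > 1e-12:
            yt = yw - ow * (ow @ yw) / denom
            Xt = Xw - np.outer(ow, (ow @ Xw) / denom)
        else:
            yt, Xt = yw - yw.mean(), Xw - Xw.mean(axis=0)
        las = Lasso(alpha=alpha, fit_intercept=False, max_iter=5000, tol=1e-8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            las.fit(Xt, yt)
        coef = las.coef_.copy()
        b0 = float(np.mean(y - Xs @ coef))
        resid = y - b0 - Xs @ coef
        tau2, sigma2 = _update_variances(
            resid, codes, counts, start=(max(tau2, 1e-4), max(sigma2, 1e-4))
        )
    b0 = float(np.mean(y - Xs @ coef))
    return coef, b0, tau2, sigma2


def lasso_mixed(
    X,
    y,
    subjects,
    n_folds: int = 5,
    seed: int = 0,
    alphas=None,
    n_alphas: int = 25,
    alpha_min_ratio: float = 1e-3,
    feature_names=None,
) -> LassoModel:
    """Mixed-effects LASSO with subject-grouped K-fold penalty selection.

    Predictors are standardized internally; reported coefficients are given
    on both scales.  ``alphas`` (sklearn scaling: (1/2n)RSS + alpha*|b|_1)
    overrides the automatic path.  The held-out criterion is the Gaussian
    deviance of fixed-effect predictions under the training-fold marginal
    covariance.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns) if feature_names is None else feature_names
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    subjects = np.asarray(subjects)
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    X, y, subjects = X[keep], y[keep], subjects[keep]

    sd = X.std(axis=0)
    dropped = [feature_names[j] for j in np.nonzero(sd == 0)[0]]
    if dropped:
        logger.warning("dropping constant predictor(s): %s", dropped)
    cols = sd > 0
    names = [n for n, c in zip(feature_names, cols) if c]
    X = X[:, cols]
    mu, sd = X.mean(axis=0), X.std(axis=0)
    Xs = (X - mu) / sd

    uniq = np.unique(subjects)
    if len(uniq) < 2 * n_folds:
        raise ValueError("need at least 2 subjects per fold")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(uniq))
    fold_of = {s: int(f) for s, f in zip(uniq[perm], np.arange(len(uniq)) % n_folds)}
    fold_idx = np.array([fold_of[s] for s in subjects])

    if alphas is None:
        yc = y - y.mean()
        alpha_max = np.max(np.abs(Xs.T @ yc)) / y.size
        alphas = np.geomspace(alpha_max, alpha_max * alpha_min_ratio, n_alphas)
    alphas = np.asarray(alphas, dtype=float)

    cv_dev = np.zeros(alphas.size)
    if alphas.size > 1:
        for f in range(n_folds):
            tr, te = fold_idx != f, fold_idx == f
            ctr, ntr = _group_codes(subjects[tr])
            cte, nte = _group_codes(subjects[te])
            coef = None
            for ai, alpha in enumerate(alphas):
                coef, b0, tau2, sigma2 = _fit_at_alpha(
                    Xs[tr], y[tr], ctr, ntr, alpha, coef_init=coef
                )
                resid = y[te] - b0 - Xs[te] @ coef
                cv_dev[ai] += _cs_nll(resid, cte, nte, sigma2, tau2)
        best = int(np.argmin(cv_dev))
    else:
        best = 0
    alpha = float(alphas[best])

    codes, counts = _group_codes(subjects)
    coef_std, b0, tau2, sigma2 = _fit_at_alpha(Xs, y, codes, counts, alpha)
    coef_raw = coef_std / sd
    intercept = float(y.mean() - mu @ coef_raw)
    pred = intercept + X @ coef_raw
    if np.std(pred) > 0 and np.std(y) > 0:
        r2m = float(np.corrcoef(pred, y)[0, 1] ** 2)
    else:
        r2m = 0.0
    # conditional predictions add the BLUP of the subject intercept
    pred_c = pred.copy()
    resid = y - pred
    for s in uniq:
        idx = subjects == s
        m = idx.sum()
        shrink = m * tau2 / (sigma2 + m * tau2) if (sigma2 + m * tau2) > 0 else 0.0
        pred_c[idx] += shrink * resid[idx].mean()
    r2c = float(np.corrcoef(pred_c, y)[0, 1] ** 2) if np.std(pred_c) > 0 else r2m
    return LassoModel(
        coef=coef_raw,
        coef_std=coef_std,
        intercept=intercept,
        alpha=alpha,
        tau2=tau2,
        sigma2=sigma2,
        r2_marginal=r2m,
        r2_conditional=r2c,
        feature_names=names,
        alphas=alphas,
        cv_deviance=cv_dev,
        fold_of_subject=fold_of,
        seed=seed,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# eGFR-augmented regression

def egfr_augmented_regression(mgfr, egfr, metric, volume=None):
    """OLS of mGFR on eGFR plus one MR metric (optionally plus volume).

    Returns a dict with coefficients, the metric's added-value two-sided p
    (t test of its coefficient in the augmented model) and R^2 of both the
    base (eGFR-only) and augmented fits.
    """
    import statsmodels.api as sm

    mgfr = np.asarray(mgfr, dtype=float)
    cols = {"eGFR": np.asarray(egfr, dtype=float), "metric": np.asarray(metric, dtype=float)}
    if volume is not None:
        cols["volume"] = np.asarray(volume, dtype=float)
    keep = np.isfinite(mgfr)
    for v in cols.values():
        keep &= np.isfinite(v)
    mgfr = mgfr[keep]
    Xdf = pd.DataFrame({k: v[keep] for k, v in cols.items()})
    if mgfr.size < Xdf.shape[1] + 2:
        raise ValueError("too few complete cases")
    X = sm.add_constant(Xdf)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = Xdf.corr().abs()
        np.fill_diagonal(corr.values, 0)
        pair = corr.stack().idxmax()
        raise ValueError(f"collinear predictors: {pair[0]} and {pair[1]}")
    fit = sm.OLS(mgfr, X).fit()
    base = sm.OLS(mgfr, sm.add_constant(Xdf[["eGFR"]])).fit()
    p_metric = float(fit.pvalues["metric"])
    tss = float(np.sum((mgfr - mgfr.mean()) ** 2))
    coef_scale = abs(fit.params["metric"]) * float(np.std(Xdf["metric"]))
    if fit.ssr <= 1e-12 * max(tss, 1.0) and coef_scale**2 <= 1e-12 * max(tss, 1.0):
        # the base model already fits perfectly and the metric coefficient is
        # numerically zero: the metric adds nothing
        p_metric = 1.0
    return {
        "params": fit.params.to_dict(),
        "metric_coef": float(fit.params["metric"]),
        "metric_p": p_metric,
        "r2_augmented": float(fit.rsquared),
        "r2_base": float(base.rsquared),
        "n": int(mgfr.size),
    }


# ---------------------------------------------------------------------------
# Proteinuria group comparison

@dataclass
class GroupTestResult:
    mean_neg: float
    sd_neg: float
    n_neg: int
    mean_pos: float
    sd_pos: float
    n_pos: int
    t: float
    df: float
    p: float


def proteinuria_test(values, labels) -> GroupTestResult:
    """Welch (unequal-variance) two-sided two-sample t test, negative group
    minus positive group."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    keep = np.isfinite(values)
    values, labels = values[keep], labels[keep]
    neg, pos = values[labels == 0], values[labels == 1]
    if neg.size < 2 or pos.size < 2:
        raise ValueError("both groups need n >= 2")
    res = sps.ttest_ind(neg, pos, equal_var=False)
    return GroupTestResult(
        mean_neg=float(neg.mean()),
        sd_neg=float(neg.std(ddof=1)),
        n_neg=int(neg.size),
        mean_pos=float(pos.mean()),
        sd_pos=float(pos.std(ddof=1)),
        n_pos=int(pos.size),
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
    )


# ---------------------------------------------------------------------------
# Table-level pipelines

def correlation_table(
    kidneys: pd.DataFrame,
    metrics,
    outcome: str,
    family: str = "waveform",
    ci_method: str = "delta-z",
) -> pd.DataFrame:
    """Per-context bilateral correlations with BH adjustment.

    One row per (metric, tissue, waveform, phase); BH families are formed
    within each level of ``family`` (default: one 36-test family per gradient
    waveform, i.e. per table).
    """
    rows = []
    for wave in kidneys["waveform"].unique():
        for tissue in kidneys["tissue"].unique():
            for ph in kidneys["phase"].unique():
                ctx = kidneys[
                    (kidneys.waveform == wave)
                    & (kidneys.tissue == tissue)
                    & (kidneys.phase == ph)
                ]
                for metric in metrics:
                    res = mixed_corr(
                        ctx[metric],
                        ctx[outcome],
                        ctx["subject_id"],
                        ci_method=ci_method,
                        context=f"{tissue}/{wave}/{ph}/{metric}",
                    )
                    rows.append(
                        {
                            "Metric": metric,
                            "Tissue": tissue,
                            "Sequence": wave,
                            "Phase": ph,
                            "r": res.r,
                            "SE": res.se,
                            "CI_low": res.ci_low,
                            "CI_high": res.ci_high,
                            "P": res.p,
                        }
                    )
    table = pd.DataFrame(rows)
    table["adjusted_P"] = np.nan
    for wave, grp in table.groupby("Sequence"):
        table.loc[grp.index, "adjusted_P"] = bh_adjust(grp["P"].to_numpy())
    return table
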