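"""Global regression models with spatial diagnostics.

Three nested specifications over n areal units:

* OLS:  y = X beta + eps
* SLM (spatial lag):    y = rho W y + X beta + eps
* SEM (spatial error):  y = X beta + u,  u = lambda W u + eps

The spatial models are estimated by maximum likelihood with the
log-determinant term computed from the eigenvalues of the
row-standardized W (exact at the n <= few-thousand scale this package
targets).  Lagrange-multiplier score tests on the OLS residuals
discriminate lag-type from error-type dependence and drive the classic
model-selection decision rule.

All variables are z-standardized by default before fitting (flag to
disable), so coefficients are comparable in magnitude and the intercept
of a standardized fit is ~0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .moran import MoranResult, global_moran
from .weights import SpatialWeights

__all__ = [
    "RegressionSpec",
    "GlobalFit",
    "CollinearityReport",
    "LmDiagnostics",
    "fit_ols",
    "vif_prune",
    "lm_diagnostics",
    "fit_slm",
    "fit_sem",
    "residual_moran",
]


@dataclass(frozen=True)
class RegressionSpec:
    outcome: str
    covariates: tuple
    standardize: bool = True

    def __post_init__(self):
        cov = tuple(self.covariates)
        if len(cov) < 1:
            raise ValueError("need at least one covariate")
        if len(set(cov)) != len(cov) or self.outcome in cov:
            raise ValueError("variable names must be unique")
        object.__setattr__(self, "covariates", cov)


@dataclass(frozen=True)
class GlobalFit:
    kind: str  # OLS | SLM | SEM
    names: tuple  # ('intercept', covariates...)
    coefficients: np.ndarray
    std_errors: np.ndarray
    p_values: np.ndarray
    spatial_param: float | None  # rho (SLM) or lambda (SEM)
    spatial_se: float | None
    spatial_p: float | None
    sigma2: float
    r2: float
    aic: float
    log_likelihood: float
    residuals: np.ndarray
    fitted: np.ndarray
    n: int

    @property
    def k(self) -> int:
        """Free parameters: betas + sigma2 (+ spatial parameter)."""
        return len(self.names) + 1 + (self.spatial_param is not None)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coefficients, "se": self.std_errors, "p": self.p_values},
            index=list(self.names),
        )


@dataclass(frozen=True)
class CollinearityReport:
    vif: dict
    dropped: tuple
    threshold: float
    history: tuple = field(default_factory=tuple)

    @property
    def retained(self):
        return tuple(self.vif)


@dataclass(frozen=True)
class LmDiagnostics:
    lm_lag: float
    p_lm_lag: float
    robust_lm_lag: float
    p_robust_lm_lag: float
    lm_error: float
    p_lm_error: float
    robust_lm_error: float
    p_robust_lm_error: float
    recommendation: str  # SLM | SEM | OLS


def _design(table: pd.DataFrame, spec: RegressionSpec):
    """Build (y, X-with-intercept) honoring the standardize flag."""
    cols = [spec.outcome, *spec.covariates]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"columns not in table: {missing}")
    df = table[cols].astype(float)
    if spec.standardize:
        df = (df - df.mean()) / df.std(ddof=0)
    y = df[spec.outcome].to_numpy()
    X = np.column_stack([np.ones(len(df)), df[list(spec.covariates)].to_numpy()])
    names = ("intercept", *spec.covariates)
    return y, X, names


def _gauss_loglik(rss, n):
    s2 = rss / n
    return -0.5 * n * (np.log(2 * np.pi * s2) + 1)


def fit_ols(table: pd.DataFrame, spec: RegressionSpec) -> GlobalFit:
    """Ordinary least squares with Gaussian likelihood-based AIC."""
    y, X, names = _design(table, spec)
    n, p1 = X.shape
    if n <= p1:
        raise ValueError(f"n = {n} too small for {p1} parameters")
    rank = np.linalg.matrix_rank(X)
    if rank < p1:
        # name the offending column for the user
        for j in range(1, p1):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                raise ValueError(
                    f"rank-deficient design: column {names[j]!r} is linearly "
                    "dependent on the others"
                )
        raise ValueError("rank-deficient design")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    rss = resid @ resid
    tss = ((y - y.mean()) ** 2).sum()
    r2 = 1 - rss / tss if tss > 0 else np.nan
    dof = n - p1
    s2_unbiased = rss / dof
    cov = s2_unbiased * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    ll = _gauss_loglik(rss, n)
    k = p1 + 1
    return GlobalFit(
        "OLS", names, beta, se, pvals, None, None, None,
        rss / n, r2, 2 * k - 2 * ll, ll, resid, fitted, n,
    )


def vif_prune(
    table: pd.DataFrame, spec: RegressionSpec, threshold: float = 5.0
) -> CollinearityReport:
    """Iteratively drop the covariate with the largest VIF until all < threshold.

    VIF_j = 1 / (1 - R2_j), with R2_j from regressing X_j on the other
    covariates (with intercept).
    """
    cov = list(spec.covariates)
    if len(cov) < 2:
        raise ValueError("VIF pruning needs at least 2 covariates")
    X_all = table[cov].astype(float).to_numpy()
    dropped, history = [], []

    def vifs(active):
        out = {}
        for j, name in enumerate(active):
            idx = [cov.index(c) for c in active]
            Xa = X_all[:, idx]
            yj = Xa[:, j]
            Z = np.column_stack([np.ones(len(yj)), np.delete(Xa, j, axis=1)])
            bh, _, _, _ = np.linalg.lstsq(Z, yj, rcond=None)
            rss = ((yj - Z @ bh) ** 2).sum()
            tss = ((yj - yj.mean()) ** 2).sum()
            r2 = 1 - rss / tss if tss > 0 else 1.0
            out[name] = np.inf if r2 >= 1 else 1.0 / (1.0 - r2)
        return out

    active = list(cov)
    while len(active) >= 2:
        v = vifs(active)
        history.append(dict(v))
        worst = max(v, key=v.get)
        if v[worst] < threshold:
            break
        active.remove(worst)
        dropped.append(worst)
    final = vifs(active) if len(active) >= 2 else {active[0]: 1.0}
    return CollinearityReport(final, tuple(dropped), threshold, tuple(history))


def lm_diagnostics(ols: GlobalFit, w: SpatialWeights, table=None, spec=None,
                   alpha: float = 0.05) -> LmDiagnostics:
    """Lagrange-multiplier tests for spatial lag vs error dependence.

    The four score statistics (plain and robust, lag and error) are
    computed from the OLS residuals; the recommendation follows the
    classic decision flowchart: pick the alternative whose plain LM is
    significant, and when both are, the one whose *robust* form survives.

    ``table``/``spec`` must be the ones the OLS fit was built from (needed
    to reconstruct the design matrix).
    """
    if ols.kind != "OLS":
        raise ValueError("lm_diagnostics requires an OLS fit")
    if table is None or spec is None:
        raise ValueError("pass the table and spec used for the OLS fit")
    y, X, _ = _design(table, spec)
    Wm = w.matrix
    if Wm.shape[0] != ols.n:
        raise ValueError("weights and fit cover different unit sets")
    e = ols.residuals
    s2 = (e @ e) / ols.n
    Wy = Wm @ y
    We = Wm @ e
    d_y = (e @ Wy) / s2
    d_e = (e @ We) / s2
    T = np.trace((Wm.T + Wm) @ Wm)
    XtXinv = np.linalg.inv(X.T @ X)
    WXb = Wm @ (X @ ols.coefficients)
    M_WXb = WXb - X @ (XtXinv @ (X.T @ WXb))
    D = (WXb @ M_WXb) / s2 + T

    lm_lag = d_y**2 / D
    lm_err = d_e**2 / T
    rlm_lag = (d_y - d_e) ** 2 / (D - T)
    rlm_err = (d_e - (T / D) * d_y) ** 2 / (T * (1 - T / D))
    chi2 = stats.chi2(df=1)
    p = {k: chi2.sf(v) for k, v in
         dict(lag=lm_lag, err=lm_err, rlag=rlm_lag, rerr=rlm_err).items()}

    sig_lag, sig_err = p["lag"] < alpha, p["err"] < alpha
    if sig_lag and sig_err:
        rec = "SLM" if p["rlag"] <= p["rerr"] else "SEM"
        if p["rlag"] < alpha and p["rerr"] >= alpha:
            rec = "SLM"
        elif p["rerr"] < alpha and p["rlag"] >= alpha:
            rec = "SEM"
    elif sig_lag:
        rec = "SLM"
    elif sig_err:
        rec = "SEM"
    else:
        rec = "OLS"
    return LmDiagnostics(
        lm_lag, p["lag"], rlm_lag, p["rlag"],
        lm_err, p["err"], rlm_err, p["rerr"], rec,
    )


# ---------------------------------------------------------------------------
# maximum-likelihood spatial models


def _w_eigenvalues(w: SpatialWeights) -> np.ndarray:
    """Real eigenvalues of row-standardized W via the symmetric similar matrix."""
    Wm = w.matrix
    if np.allclose(Wm, Wm.T, atol=1e-12):
        return np.linalg.eigvalsh(Wm)
    # row-standardized W = D^-1 A with A symmetric is similar to the
    # symmetric D^-1/2 A D^-1/2, so its spectrum is real
    deg = (Wm > 0).sum(axis=1)
    d = np.where(deg > 0, deg, 1).astype(float)
    A = Wm * d[:, None]
    if np.allclose(A, A.T, atol=1e-10):
        S = A / np.sqrt(d[:, None] * d[None, :])
        return np.linalg.eigvalsh(S)
    ev = np.linalg.eigvals(Wm)
    if np.abs(ev.imag).max() > 1e-8:
        raise ValueError("complex eigenvalues of W; cannot bound the spatial parameter")
    return np.sort(ev.real)


def _spatial_bounds(eig):
    lo = 1.0 / eig.min() if eig.min() < 0 else -0.999
    hi = 1.0 / eig.max() if eig.max() > 0 else 0.999
    pad = 1e-5 * (hi - lo)
    return lo + pad, hi - pad


def _numeric_hessian(f, theta, h=1e-5):
    theta = np.asarray(theta, dtype=float)
    k = len(theta)
    H = np.empty((k, k))
    hs = h * np.maximum(1.0, np.abs(theta))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = hs[i]
            ej = np.zeros(k); ej[j] = hs[j]
            fpp = f(theta + ei + ej)
            fpm = f(theta + ei - ej)
            fmp = f(theta - ei + ej)
            fmm = f(theta - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * hs[i] * hs[j])
    return H


def _spatial_inference(beta, rho, full_nll, theta_hat):
    """Asymptotic z-tests from the observed information (numerical Hessian)."""
    H = _numeric_hessian(full_nll, theta_hat)
    try:
        cov = np.linalg.inv(H)
        se_all = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:  # pragma: no cover
        se_all = np.full(len(theta_hat), np.nan)
    # theta layout: [spatial, beta..., log s2]
    se_sp = se_all[0]
    se_b = se_all[1 : 1 + len(beta)]
    z_b = beta / se_b
    p_b = 2 * stats.norm.sf(np.abs(z_b))
    z_sp = rho / se_sp if se_sp > 0 else np.nan
    p_sp = 2 * stats.norm.sf(abs(z_sp))
    return se_b, p_b, se_sp, p_sp


def fit_slm(table: pd.DataFrame, spec: RegressionSpec, w: SpatialWeights) -> GlobalFit:
    """ML spatial-lag model via the concentrated likelihood in rho.

    For each rho the betas and sigma^2 are profiled out analytically; the
    log-determinant ln|I - rho W| is the sum of ln(1 - rho * eig_i) over
    the eigenvalues of W.  rho is searched by bounded scalar optimization
    inside the eigenvalue-determined stationarity interval.
    """
    if not w.standardized:
        raise ValueError("SLM requires a row-standardized W")
    y, X, names = _design(table, spec)
    n = len(y)
    Wm = w.matrix
    eig = _w_eigenvalues(w)
    lo, hi = _spatial_bounds(eig)
    Wy = Wm @ y
    XtXinv = np.linalg.inv(X.T @ X)
    b_o = XtXinv @ (X.T @ y)
    b_l = XtXinv @ (X.T @ Wy)
    e_o = y - X @ b_o
    e_l = Wy - X @ b_l

    def neg_conc(rho):
        e = e_o - rho * e_l
        s2 = (e @ e) / n
        logdet = np.log(1 - rho * eig).sum()
        return 0.5 * n * np.log(s2) - logdet

    res = optimize.minimize_scalar(neg_conc, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    if not res.success:  # pragma: no cover
        raise RuntimeError(f"SLM rho search failed: {res}")
    rho = float(res.x)
    beta = b_o - rho * b_l
    e = e_o - rho * e_l
    s2 = (e @ e) / n
    logdet = np.log(1 - rho * eig).sum()
    ll = -0.5 * n * (np.log(2 * np.pi * s2) + 1) + logdet

    def full_nll(theta):
        r, b, ls2 = theta[0], theta[1:-1], theta[-1]
        if not (lo < r < hi):
            return np.inf
        sig2 = np.exp(ls2)
        eps = y - r * Wy - X @ b
        ld = np.log(1 - r * eig).sum()
        return 0.5 * n * np.log(2 * np.pi * sig2) + (eps @ eps) / (2 * sig2) - ld

    theta_hat = np.concatenate([[rho], beta, [np.log(s2)]])
    se_b, p_b, se_sp, p_sp = _spatial_inference(beta, rho, full_nll, theta_hat)
    # fitted values include the spatial lag term, so residuals are the
    # model innovations eps_hat = y - rho W y - X beta (these are what the
    # whitening check on a correctly specified SLM expects to be noise)
    fitted = rho * Wy + X @ beta
    resid = y - fitted
    r2 = np.corrcoef(y, fitted)[0, 1] ** 2
    k = len(names) + 2  # betas + sigma2 + rho
    return GlobalFit(
        "SLM", names, beta, se_b, p_b, rho, se_sp, p_sp,
        s2, r2, 2 * k - 2 * ll, ll, resid, fitted, n,
    )


def fit_sem(table: pd.DataFrame, spec: RegressionSpec, w: SpatialWeights) -> GlobalFit:
    """ML spatial-error model via the concentrated likelihood in lambda.

    The model filters both sides by (I - lambda W); for each lambda the
    betas come from OLS on the filtered data and sigma^2 from the filtered
    residuals.
    """
    if not w.standardized:
        raise ValueError("SEM requires a row-standardized W")
    y, X, names = _design(table, spec)
    n = len(y)
    Wm = w.matrix
    eig = _w_eigenvalues(w)
    lo, hi = _spatial_bounds(eig)

    def filtered_fit(lam):
        B = np.eye(n) - lam * Wm
        ys, Xs = B @ y, B @ X
        b, _, _, _ = np.linalg.lstsq(Xs, ys, rcond=None)
        e = ys - Xs @ b
        return b, (e @ e) / n

    def neg_conc(lam):
        _, s2 = filtered_fit(lam)
        return 0.5 * n * np.log(s2) - np.log(1 - lam * eig).sum()

    res = optimize.minimize_scalar(neg_conc, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    if not res.success:  # pragma: no cover
        raise RuntimeError(f"SEM lambda search failed: {res}")
    lam = float(res.x)
    beta, s2 = filtered_fit(lam)
    ll = -0.5 * n * (np.log(2 * np.pi * s2) + 1) + np.log(1 - lam * eig).sum()

    def full_nll(theta):
        l_, b, ls2 = theta[0], theta[1:-1], theta[-1]
        if not (lo < l_ < hi):
            return np.inf
        sig2 = np.exp(ls2)
        B = np.eye(n) - l_ * Wm
        eps = B @ (y - X @ b)
        ld = np.log(1 - l_ * eig).sum()
        return 0.5 * n * np.log(2 * np.pi * sig2) + (eps @ eps) / (2 * sig2) - ld

    theta_hat = np.concatenate([[lam], beta, [np.log(s2)]])
    se_b, p_b, se_sp, p_sp = _spatial_inference(beta, lam, full_nll, theta_hat)
    fitted = X @ beta
    resid = y - fitted  # u, the spatially correlated error
    r2 = np.corrcoef(y, fitted)[0, 1] ** 2
    k = len(names) + 2
    return GlobalFit(
        "SEM", names, beta, se_b, p_b, lam, se_sp, p_sp,
        s2, r2, 2 * k - 2 * ll, ll, resid, fitted, n,
    )


def residual_moran(fit: GlobalFit, w: SpatialWeights, **kwargs) -> MoranResult:
    """Global Moran's I applied to a fit's residuals."""
    return global_moran(fit.residuals, w, **kwargs)
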