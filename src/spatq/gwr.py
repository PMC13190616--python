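"""Geographically weighted regression (GWR) and its multiscale extension.

GWR fits a separate weighted least-squares regression at every unit,
with observation weights decaying in distance from the focal unit
through a fixed Gaussian kernel

    w_ij = exp(-0.5 * (d_ij / bw)^2).

One bandwidth ``bw`` governs all covariates; it is chosen by minimizing
the corrected Akaike criterion

    AICc = 2n ln(sigma_hat) + n ln(2*pi) + n (n + tr(S)) / (n - 2 - tr(S))

where S is the hat matrix mapping y to fitted values and tr(S) is the
effective number of parameters.

MGWR relaxes the single-scale assumption: each term (including the
intercept) gets its own bandwidth, estimated by iterative back-fitting —
each term's contribution is re-smoothed against the partial residual of
the others with a freshly AICc-selected univariate bandwidth until the
residual sum of squares stabilizes.  A covariate operating globally gets
a large bandwidth; one with fine-scale structure gets a small one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

__all__ = [
    "LocalFit",
    "gaussian_kernel_weights",
    "select_bandwidth",
    "fit_gwr",
    "fit_mgwr",
    "local_significance",
]


@dataclass(frozen=True)
class LocalFit:
    kind: str  # GWR | MGWR
    term_names: tuple
    bandwidths: np.ndarray  # scalar broadcast for GWR, per-term for MGWR
    local_coefficients: np.ndarray  # (n, terms)
    local_t: np.ndarray  # (n, terms)
    enp: float  # tr(S)
    enp_terms: np.ndarray  # per-term effective parameters
    aicc: float
    local_r2: np.ndarray
    residuals: np.ndarray
    fitted: np.ndarray
    converged: bool = True
    iterations: int = 0
    soc_trace: tuple = field(default_factory=tuple)

    @property
    def n(self) -> int:
        return self.local_coefficients.shape[0]


def _check_coords(coords):
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be (n, 2) planar positions")
    if not np.isfinite(coords).all():
        raise ValueError("non-finite coordinates")
    d = cdist(coords, coords)
    np.fill_diagonal(d, np.inf)
    if d.min() == 0:
        raise ValueError("coincident coordinates: jitter the duplicated units")
    lon_like = (np.abs(coords[:, 0]) <= 180).all() and (np.abs(coords[:, 1]) <= 90).all()
    return coords, lon_like


def gaussian_kernel_weights(coords, focal: int, bandwidth: float) -> np.ndarray:
    """Fixed Gaussian kernel weights of every unit w.r.t. one focal unit."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    coords = np.asarray(coords, dtype=float)
    d = np.hypot(*(coords - coords[focal]).T)
    return np.exp(-0.5 * (d / bandwidth) ** 2)


def _kernel_matrix(dist, bandwidth):
    return np.exp(-0.5 * (dist / bandwidth) ** 2)


def _gwr_solve(y, X, dist, bandwidth, need_hat=True):
    """Local WLS at every focal unit; returns betas, hat matrix, fitted."""
    n, p = X.shape
    K = _kernel_matrix(dist, bandwidth)
    betas = np.empty((n, p))
    S = np.empty((n, n)) if need_hat else None
    C_all = np.empty((n, p, n))  # rows of (X'WX)^-1 X'W per focal unit
    for i in range(n):
        wi = K[i]
        Xw = X * wi[:, None]
        XtWX = X.T @ Xw
        try:
            Ci = np.linalg.solve(XtWX, Xw.T)  # (p, n)
        except np.linalg.LinAlgError:
            raise ValueError(
                f"local design rank-deficient at unit index {i} "
                f"(bandwidth {bandwidth:g})"
            ) from None
        betas[i] = Ci @ y
        C_all[i] = Ci
        if need_hat:
            S[i] = X[i] @ Ci
    fitted = (betas * X).sum(axis=1)
    return betas, S, fitted, C_all, K


def _aicc_from(y, fitted, trS):
    n = len(y)
    denom = n - 2.0 - trS
    if denom <= 0:
        return np.inf
    rss = ((y - fitted) ** 2).sum()
    sigma2 = rss / n
    return n * np.log(sigma2) + n * np.log(2 * np.pi) + n * (n + trS) / denom


def _pairwise(coords):
    d = cdist(coords, coords)
    iu = np.triu_indices_from(d, k=1)
    return d, d[iu]


def _golden_section(f, lo, hi, tol=1e-3, max_iter=100):
    """Minimize a unimodal scalar function on [lo, hi]; returns (x, f(x), trace)."""
    invphi = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    trace = [(c, fc), (d, fd)]
    it = 0
    while abs(b - a) > tol * (abs(c) + abs(d)) / 2 and it < max_iter:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
            trace.append((c, fc))
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
            trace.append((d, fd))
        it += 1
    x = c if fc < fd else d
    fx = min(fc, fd)
    return x, fx, trace


def select_bandwidth(y, X, coords, criterion: str = "aicc",
                     bounds=None, tol: float = 1e-3):
    """AICc-minimizing fixed Gaussian bandwidth via golden-section search.

    The search bracket defaults to [min pairwise distance, 2 x max
    pairwise distance].
    """
    if criterion.lower() != "aicc":
        raise ValueError("only the AICc criterion is supported")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    coords, _ = _check_coords(coords)
    n, p = X.shape
    if n <= p + 2:
        raise ValueError("too few units for AICc bandwidth selection")
    dist, pw = _pairwise(coords)
    lo, hi = bounds if bounds is not None else (pw.min(), 2 * pw.max())

    def f(bw):
        try:
            _, S, fitted, _, _ = _gwr_solve(y, X, dist, bw)
        except ValueError:
            return np.inf
        return _aicc_from(y, fitted, np.trace(S))

    bw, fbw, trace = _golden_section(f, lo, hi, tol=tol)
    if not np.isfinite(fbw):
        raise ValueError("AICc undefined at every candidate bandwidth "
                         "(n - 2 - tr(S) <= 0 throughout the bracket)")
    return float(bw), tuple(trace)


def fit_gwr(y, X, coords, bandwidth: float, term_names=None) -> LocalFit:
    """Fixed-Gaussian-kernel GWR at a given bandwidth.

    ``X`` must already contain the intercept column if one is wanted.
    Reported per-unit t-values use the exact local covariance
    C_i C_i' sigma^2; local R^2 uses the same kernel weights as estimation.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    coords, _ = _check_coords(coords)
    n, p = X.shape
    if term_names is None:
        term_names = tuple(f"x{j}" for j in range(p))
    dist, _ = _pairwise(coords)
    betas, S, fitted, C_all, K = _gwr_solve(y, X, dist, bandwidth)
    resid = y - fitted
    trS = np.trace(S)
    aicc = _aicc_from(y, fitted, trS)
    # local inference: Var(beta_i) = sigma2 * C_i C_i'
    dof = max(n - trS, 1.0)
    sigma2 = (resid @ resid) / dof
    se = np.empty((n, p))
    for i in range(n):
        se[i] = np.sqrt(np.clip(np.einsum("pj,pj->p", C_all[i], C_all[i]) * sigma2, 1e-300, None))
    local_t = betas / se
    # kernel-weighted local R2
    local_r2 = np.empty(n)
    for i in range(n):
        wi = K[i]
        ybar_w = (wi * y).sum() / wi.sum()
        tss = (wi * (y - ybar_w) ** 2).sum()
        rss = (wi * resid**2).sum()
        local_r2[i] = np.clip(1 - rss / tss, 0.0, 1.0) if tss > 0 else np.nan
    return LocalFit(
        "GWR", tuple(term_names), np.full(p, float(bandwidth)), betas, local_t,
        float(trS), _term_enp_gwr(S, X, C_all), aicc, local_r2, resid, fitted,
    )


def _term_enp_gwr(S, X, C_all):
    """Per-term effective parameters tr(R_k) with R_k[i, :] = X[i,k] * C_all[i][k, :]."""
    n, p, _ = C_all.shape
    out = np.empty(p)
    for k in range(p):
        out[k] = sum(X[i, k] * C_all[i][k, i] for i in range(n))
    return out


def fit_mgwr(y, X, coords, term_names=None, tol: float = 1e-5,
             max_iter: int = 200, bw_tol: float = 1e-2,
             verbose: bool = False) -> LocalFit:
    """Multiscale GWR by additive back-fitting with per-term bandwidths.

    Initialization is the all-terms GWR fit at its own AICc-optimal
    bandwidth; each sweep re-selects every term's univariate bandwidth by
    AICc and re-smooths its contribution against the current partial
    residual.  Convergence is declared when the relative change of the
    residual sum of squares (SOC-RSS) drops below ``tol``.

    Per-term hat matrices are propagated through the back-fit, giving
    per-term effective parameters tr(R_k) used by
    :func:`local_significance`.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    coords, _ = _check_coords(coords)
    n, p = X.shape
    if term_names is None:
        term_names = tuple(f"x{j}" for j in range(p))
    dist, pw = _pairwise(coords)
    lo, hi = pw.min(), 2 * pw.max()

    # --- initialize from a plain GWR fit
    bw0, _ = select_bandwidth(y, X, coords)
    betas, S, fitted, C_all, _ = _gwr_solve(y, X, dist, bw0)
    contrib = betas * X  # (n, p), f_k = beta_k * x_k
    # initial per-term hat matrices from the GWR fit: R_k[i,:] = X[i,k]*C_all[i][k,:]
    R = np.empty((p, n, n))
    for k in range(p):
        for i in range(n):
            R[k, i] = X[i, k] * C_all[i][k]

    bws = np.full(p, bw0)
    resid = y - contrib.sum(axis=1)
    rss_old = resid @ resid
    soc_trace = []
    converged = False
    it = 0

    for it in range(1, max_iter + 1):
        for k in range(p):
            xk = X[:, k]
            e_k = y - contrib.sum(axis=1) + contrib[:, k]

            def f(bw, xk=xk, e_k=e_k):
                K = _kernel_matrix(dist, bw)
                Xw = K * xk[None, :]
                denom = Xw @ xk
                if (denom <= 0).any():
                    return np.inf
                beta = (Xw @ e_k) / denom
                fit_k = beta * xk
                # hat diag of the univariate smoother: x_i * w_ii x_i / denom_i
                tr = (xk**2 / denom * 1.0).sum()  # w_ii = 1 at d=0
                return _aicc_from(e_k, fit_k, tr)

            bw_k, _, _ = _golden_section(f, lo, hi, tol=bw_tol)
            K = _kernel_matrix(dist, bw_k)
            Xw = K * xk[None, :]
            denom = Xw @ xk
            beta_k = (Xw @ e_k) / denom
            Sk = (xk[:, None] * Xw) / denom[:, None]  # maps e_k -> f_k
            # propagate the term's hat matrix: f_k = S_k (y - sum_{j!=k} R_j y)
            R[k] = Sk @ (np.eye(n) - R.sum(axis=0) + R[k])
            contrib[:, k] = beta_k * xk
            betas[:, k] = beta_k
            bws[k] = bw_k

        resid = y - contrib.sum(axis=1)
        rss = resid @ resid
        soc = abs(rss - rss_old) / rss if rss > 0 else 0.0
        soc_trace.append(float(soc))
        rss_old = rss
        if soc < tol:
            converged = True
            break

    if not converged:
        raise RuntimeError(
            f"MGWR back-fitting did not converge in {max_iter} sweeps; "
            f"SOC trace tail: {soc_trace[-5:]}"
        )

    S_total = R.sum(axis=0)
    trS = float(np.trace(S_total))
    enp_terms = np.array([np.trace(R[k]) for k in range(p)])
    fitted = contrib.sum(axis=1)
    aicc = _aicc_from(y, fitted, trS)
    dof = max(n - trS, 1.0)
    sigma2 = (resid @ resid) / dof
    # per-term local SEs via the term hat matrices: Var(f_k) = sigma2 diag(R_k R_k')
    local_t = np.empty((n, p))
    for k in range(p):
        var_f = sigma2 * np.einsum("ij,ij->i", R[k], R[k])
        xk = X[:, k]
        with np.errstate(divide="ignore", invalid="ignore"):
            se_beta = np.sqrt(var_f) / np.abs(xk)
        se_beta[~np.isfinite(se_beta)] = np.nan
        local_t[:, k] = betas[:, k] / se_beta
    # local R2 with the intercept term's kernel (broadest honest choice: per-unit
    # average of the per-term kernels)
    Kbar = np.mean([_kernel_matrix(dist, b) for b in bws], axis=0)
    local_r2 = np.empty(n)
    for i in range(n):
        wi = Kbar[i]
        ybar_w = (wi * y).sum() / wi.sum()
        tss = (wi * (y - ybar_w) ** 2).sum()
        rss_i = (wi * resid**2).sum()
        local_r2[i] = np.clip(1 - rss_i / tss, 0.0, 1.0) if tss > 0 else np.nan
    return LocalFit(
        "MGWR", tuple(term_names), bws.copy(), betas.copy(), local_t,
        trS, enp_terms, aicc, local_r2, resid, fitted,
        converged=True, iterations=it, soc_trace=tuple(soc_trace),
    )


def local_significance(fit: LocalFit, alpha: float = 0.05) -> np.ndarray:
    """Per-unit per-term significance mask with ENP-adjusted alpha.

    The per-term threshold is alpha_adj = alpha * (terms / enp_k): terms
    whose effective parameter count exceeds one face a stricter local
    test, compensating for the multiplicity of dependent local tests.
    """
    if alpha == 0:
        return np.zeros_like(fit.local_t, dtype=bool)
    n, p = fit.local_t.shape
    dof = max(fit.n - fit.enp, 1.0)
    mask = np.zeros((n, p), dtype=bool)
    enp_terms = np.clip(fit.enp_terms, 1.0, None)
    for k in range(p):
        a_adj = alpha * p / enp_terms[k]
        a_adj = min(max(a_adj, np.finfo(float).tiny), alpha)
        tcrit = stats.t.ppf(1 - a_adj / 2, dof)
        t = fit.local_t[:, k]
        mask[:, k] = np.abs(np.nan_to_num(t, nan=0.0)) > tcrit
    return mask
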