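"""Synthetic areal datasets with known spatial ground truth.

The generators produce unit tables with exactly the statistical
structure the analysis stages assume, so every method can be validated
end-to-end without external data:

* layouts — regular lattices (queen contiguity), rings, and a 31-unit
  ring-plus-chords graph standing in for a provincial study area;
* covariates — correlated Gaussians pushed through the spatial filter
  (I - delta W)^-1, which induces positive spatial autocorrelation of
  strength delta;
* outcomes — a spatial-lag process y = (I - rho W)^-1 (X beta + eps), a
  spatial-error process y = X beta + (I - lambda W)^-1 eps, or spatially
  varying coefficient (SVC) surfaces drawn from a small library
  (constant, linear east-west gradient, Gaussian bumps);
* stratified outcomes — L strata whose between-strata variance share is
  solved analytically to hit a target explanatory power q.

Randomness is NumPy's PCG64 via ``default_rng(seed)``; the same spec and
seed always reproduce the same dataset bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geodetector import Stratification
from .weights import SpatialWeights, from_adjacency_pairs, row_standardize

__all__ = [
    "Layout",
    "SyntheticDataset",
    "make_lattice",
    "make_ring",
    "simulate_covariates",
    "simulate_sar_outcome",
    "simulate_sem_outcome",
    "simulate_svc_outcome",
    "simulate_stratified",
    "simulate_study_like",
    "surface",
]


@dataclass(frozen=True)
class Layout:
    unit_ids: tuple
    coords: np.ndarray  # (n, 2) planar
    weights: SpatialWeights  # binary
    weights_std: SpatialWeights  # row-standardized

    @property
    def n(self) -> int:
        return len(self.unit_ids)


@dataclass(frozen=True)
class SyntheticDataset:
    table: pd.DataFrame  # id, outcome, covariates, x, y coords
    layout: Layout
    truth: dict  # generating parameters / surfaces / strata


def _ids(n):
    width = len(str(n - 1))
    return tuple(f"u{str(i).zfill(width)}" for i in range(n))


def make_lattice(rows: int, cols: int) -> Layout:
    """rows x cols grid with queen contiguity and cell-center coordinates."""
    n = rows * cols
    if n < 4:
        raise ValueError("need at least 4 units")
    ids = _ids(n)
    coords = np.array([(c + 0.5, r + 0.5) for r in range(rows) for c in range(cols)])
    pairs = []
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols:
                        j = rr * cols + cc
                        if i < j:
                            pairs.append((ids[i], ids[j]))
    w = from_adjacency_pairs(pairs, ids)
    return Layout(w.unit_ids, coords[_order(ids, w.unit_ids)], w, row_standardize(w))


def make_ring(n: int, chords=()) -> Layout:
    """Cycle graph of n units on a circle, optionally with extra chords."""
    if n < 4:
        raise ValueError("need at least 4 units")
    ids = _ids(n)
    theta = 2 * np.pi * np.arange(n) / n
    coords = np.column_stack([np.cos(theta), np.sin(theta)]) * (n / (2 * np.pi))
    pairs = [(ids[i], ids[(i + 1) % n]) for i in range(n)]
    pairs += [(ids[a], ids[b]) for a, b in chords]
    w = from_adjacency_pairs(pairs, ids)
    return Layout(w.unit_ids, coords[_order(ids, w.unit_ids)], w, row_standardize(w))


def _order(ids, sorted_ids):
    pos = {u: i for i, u in enumerate(ids)}
    return [pos[u] for u in sorted_ids]


def simulate_covariates(layout: Layout, corr, delta=0.0, seed=None,
                        names=None) -> pd.DataFrame:
    """Correlated unit-level covariates with optional spatial smoothing.

    Draws iid rows from N(0, corr) and applies the spatial filter
    (I - delta W)^-1 (row-standardized W) to every column, then rescales
    each column back to unit variance.  The filter leaves cross-column
    correlations intact while inducing spatial autocorrelation that
    grows with delta in [0, 1).
    """
    corr = np.atleast_2d(np.asarray(corr, dtype=float))
    p = corr.shape[0]
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ValueError("correlation matrix not positive definite") from None
    deltas = np.broadcast_to(np.asarray(delta, dtype=float), (p,))
    if (np.abs(deltas) >= 1).any():
        raise ValueError("smoothing delta must lie in (-1, 1)")
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((layout.n, p)) @ chol.T
    W = layout.weights_std.matrix
    I = np.eye(layout.n)
    X = np.empty_like(Z)
    for j in range(p):
        if deltas[j] == 0:
            X[:, j] = Z[:, j]
        else:
            X[:, j] = np.linalg.solve(I - deltas[j] * W, Z[:, j])
            X[:, j] /= X[:, j].std(ddof=0)
    if names is None:
        names = [f"x{j + 1}" for j in range(p)]
    return pd.DataFrame(X, columns=list(names), index=list(layout.unit_ids))


def simulate_sar_outcome(layout: Layout, X, beta, rho: float, sigma: float = 1.0,
                         seed=None):
    """Spatial-lag outcome y = (I - rho W)^-1 (intercept + X beta + eps)."""
    _check_param(rho, "rho")
    rng = np.random.default_rng(seed)
    Xm = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    eps = rng.normal(0, sigma, layout.n)
    signal = beta[0] + Xm @ beta[1:] + eps
    y = np.linalg.solve(np.eye(layout.n) - rho * layout.weights_std.matrix, signal)
    return y, {"model": "sar", "beta": beta.tolist(), "rho": rho, "sigma": sigma}


def simulate_sem_outcome(layout: Layout, X, beta, lam: float, sigma: float = 1.0,
                         seed=None):
    """Spatial-error outcome y = intercept + X beta + (I - lambda W)^-1 eps."""
    _check_param(lam, "lambda")
    rng = np.random.default_rng(seed)
    Xm = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    eps = rng.normal(0, sigma, layout.n)
    u = np.linalg.solve(np.eye(layout.n) - lam * layout.weights_std.matrix, eps)
    y = beta[0] + Xm @ beta[1:] + u
    return y, {"model": "sem", "beta": beta.tolist(), "lambda": lam, "sigma": sigma}


def _check_param(v, name):
    if not (-0.999 < v < 0.999):
        raise ValueError(f"{name} = {v} outside the stationary interval of a "
                         "row-standardized W (max eigenvalue 1)")


def surface(kind: str, coords, value: float = 1.0, scale: float = 1.0,
            centers=None, seed=None):
    """Coefficient surface library: 'constant', 'gradient_ew', 'bumps'.

    * constant — beta(u, v) = value everywhere;
    * gradient_ew — linear east-west gradient, rescaled to [0, value];
    * bumps — sum of Gaussian bumps of length-scale ``scale`` at
      ``centers`` (default: 4 random interior points), amplitude value.
    """
    coords = np.asarray(coords, dtype=float)
    u = coords[:, 0]
    if kind == "constant":
        return np.full(len(coords), float(value))
    if kind == "gradient_ew":
        span = u.max() - u.min()
        return value * (u - u.min()) / (span if span > 0 else 1.0)
    if kind == "bumps":
        rng = np.random.default_rng(seed)
        if centers is None:
            lo, hi = coords.min(axis=0), coords.max(axis=0)
            centers = lo + (hi - lo) * rng.random((4, 2))
        out = np.zeros(len(coords))
        for c in np.atleast_2d(centers):
            d2 = ((coords - c) ** 2).sum(axis=1)
            out += value * np.exp(-0.5 * d2 / scale**2)
        return out
    raise ValueError(f"unknown surface kind {kind!r}")


def simulate_svc_outcome(layout: Layout, X, surfaces, sigma: float = 1.0, seed=None):
    """Spatially varying coefficient outcome.

    ``surfaces`` is a list of per-unit coefficient vectors, one per
    design column including the intercept: y_i = sum_k beta_k(i) x_ik + eps_i.
    """
    rng = np.random.default_rng(seed)
    Xm = np.column_stack([np.ones(layout.n), np.asarray(X, dtype=float)])
    B = np.column_stack(surfaces)
    if B.shape != Xm.shape:
        raise ValueError(f"need {Xm.shape[1]} surfaces of length {layout.n}")
    y = (B * Xm).sum(axis=1) + rng.normal(0, sigma, layout.n)
    return y, {"model": "svc", "surfaces": B, "sigma": sigma}


def simulate_stratified(layout: Layout, L: int, target_q: float, sigma_w: float = 1.0,
                        seed=None):
    """Stratified outcome whose expected explanatory power equals target_q.

    Units are assigned to L near-equal strata; stratum means are equally
    spaced and scaled so the between-strata share of total variance is
    target_q given within-stratum SD sigma_w:

        spread = sigma_w * sqrt(q / (1 - q)) / sd(grid).

    ``target_q = 1`` with sigma_w > 0 is infeasible and rejected;
    sigma_w = 0 yields PD = 1 exactly.
    """
    if L < 2:
        raise ValueError("need at least 2 strata")
    if not (0 <= target_q < 1) and not (target_q == 1 and sigma_w == 0):
        raise ValueError("target_q must lie in [0, 1) (or exactly 1 with sigma_w = 0)")
    rng = np.random.default_rng(seed)
    labels = np.sort(np.arange(layout.n) % L) + 1
    rng.shuffle(labels)
    grid = np.arange(L, dtype=float)
    grid -= grid.mean()
    if target_q == 0 or grid.std() == 0:
        means = np.zeros(L)
    elif sigma_w == 0:
        means = grid
    else:
        c = sigma_w * np.sqrt(target_q / (1 - target_q)) / grid.std(ddof=0)
        means = c * grid
    y = means[labels - 1] + rng.normal(0, sigma_w, layout.n)
    strat = Stratification(labels)
    truth = {"model": "stratified", "L": L, "target_q": target_q,
             "sigma_w": sigma_w, "means": means.tolist()}
    return y, strat, truth


# ---------------------------------------------------------------------------
# study-scale one-call fixture

STUDY_COVARIATES = (
    "gdp_per_capita",
    "household_size",
    "education_years",
    "hospital_beds",
    "pm25",
    "consumption_pc",
    "urbanization",
)


def simulate_study_like(seed: int = 0) -> SyntheticDataset:
    """A 31-unit province-like dataset with built-in collinearity and SVC truth.

    The layout is a 31-unit ring with cross-chords (keeping every unit
    connected, degrees 2-4).  Seven covariates mimic a typical
    determinant table: consumption and urbanization are near-linear
    combinations of GDP (pairwise target correlations 0.93/0.88/0.82),
    forcing a collinear block that VIF screening should prune.
    Covariates are strongly spatially smoothed (delta = 0.8), so the
    outcome inherits the pronounced positive autocorrelation
    characteristic of provincial health outcomes.  The outcome is an SVC
    process in which education and GDP effects strengthen toward the
    west (negative east-west gradient) while household size has a weak
    constant negative effect; noise SD 0.3.
    """
    rng = np.random.default_rng(seed)
    n = 31
    chords = [(i, (i + 7) % n) for i in range(0, n, 5)]
    layout = make_ring(n, chords=chords)
    corr = np.eye(7)
    pairs = {(0, 5): 0.93, (0, 6): 0.88, (5, 6): 0.82,  # gdp/consumption/urbanization
             (0, 2): 0.25, (2, 6): 0.20, (0, 3): 0.15}
    for (a, b), r in pairs.items():
        corr[a, b] = corr[b, a] = r
    # nudge to the nearest PD matrix if needed
    evals = np.linalg.eigvalsh(corr)
    if evals.min() <= 1e-8:  # pragma: no cover - current block is PD
        corr += (abs(evals.min()) + 1e-6) * np.eye(7)
        d = np.sqrt(np.diag(corr))
        corr = corr / d[:, None] / d[None, :]
    X = simulate_covariates(layout, corr, delta=0.8,
                            seed=rng.integers(2**31), names=STUDY_COVARIATES)
    coords = layout.coords
    u = coords[:, 0]
    west_strength = (u.max() - u) / (u.max() - u.min())  # 1 in the west, 0 east
    surfaces = [
        np.full(n, 0.0),                      # intercept
        0.3 + 0.5 * west_strength,            # gdp: stronger in the west
        np.full(n, -0.2),                     # household size: weak constant
        0.4 + 0.8 * west_strength,            # education: strongest western effect
        np.full(n, 0.05),                     # hospital beds: near-null
        np.full(n, -0.05),                    # pm25: near-null
        np.full(n, 0.1),                      # consumption
        np.full(n, 0.1),                      # urbanization
    ]
    y, truth = simulate_svc_outcome(
        layout, X.to_numpy(), surfaces, sigma=0.3, seed=rng.integers(2**31)
    )
    table = pd.DataFrame({"id": list(layout.unit_ids), "life_expectancy": y})
    for c in STUDY_COVARIATES:
        table[c] = X[c].to_numpy()
    table["coord_x"] = coords[:, 0]
    table["coord_y"] = coords[:, 1]
    truth = dict(truth)
    truth["west_strength"] = west_strength
    truth["collinear_block"] = ("gdp_per_capita", "consumption_pc", "urbanization")
    return SyntheticDataset(table, layout, truth)
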