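"""Global and local Moran statistics for areal data.

The global statistic

    I = n / S0 * (z' W z) / (z' z),   z_i = x_i - mean(x),  S0 = sum(W)

measures overall spatial clustering of a variable over the neighbor
graph; its expectation under the null of no spatial structure is
-1/(n-1).  Inference is available analytically (randomization-assumption
z-test) or by permutation.

The local decomposition (LISA)

    I_i = z_i * sum_j w_ij z_j / (sum_k z_k^2 / n)

attributes clustering to individual units; with a row-standardized W the
mean of the local statistics equals the global I.  Each significant unit
is labeled HH/LL/HL/LH by the quadrant of (own deviation, neighbor-mean
deviation), the four patterns of a LISA cluster map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .weights import SpatialWeights

__all__ = ["MoranResult", "LisaResult", "global_moran", "local_moran"]


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected_I: float
    z_score: float
    p_value: float
    method: str
    permutations: int | None = None
    seed: int | None = None


@dataclass(frozen=True)
class LisaResult:
    unit_ids: tuple
    local_I: np.ndarray
    p_values: np.ndarray
    labels: tuple
    alpha: float
    permutations: int
    seed: int | None


def _validated(x, w: SpatialWeights):
    x = np.asarray(x, dtype=float)
    if x.shape != (w.n,):
        raise ValueError(f"length mismatch: {x.shape[0]} values for {w.n} units")
    mask = w.nonisland_mask()
    xm = x[mask]
    # constant up to float noise counts as zero variance
    if np.ptp(xm) <= 1e-12 * max(1.0, np.abs(xm).max()):
        raise ValueError("zero variance: Moran's I undefined for constant x")
    return x, mask


def _moran_stat(z, wm, s0):
    return len(z) / s0 * (z @ wm @ z) / (z @ z)


def global_moran(
    x,
    w: SpatialWeights,
    method: str = "normal",
    permutations: int = 999,
    seed: int | None = None,
) -> MoranResult:
    """Global Moran's I with analytic or permutation inference.

    ``method='normal'`` uses the randomization-assumption variance for a
    two-tailed z-test; ``method='permutation'`` relabels x over units and
    reports a two-tailed pseudo p-value.  Island units are excluded from
    all sums.
    """
    x, mask = _validated(x, w)
    z_full = np.zeros_like(x)
    xs = x[mask]
    wm = w.matrix[np.ix_(mask, mask)]
    n = mask.sum()
    z = xs - xs.mean()
    s0 = wm.sum()
    if s0 == 0:
        raise ValueError("weight matrix sums to zero among non-island units")
    I = _moran_stat(z, wm, s0)
    e_i = -1.0 / (n - 1)

    if method == "normal":
        # randomization-assumption moments (Cliff & Ord)
        s1 = 0.5 * ((wm + wm.T) ** 2).sum()
        s2 = ((wm.sum(axis=1) + wm.sum(axis=0)) ** 2).sum()
        b2 = n * (z**4).sum() / (z**2).sum() ** 2
        num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2) - b2 * (
            (n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2
        )
        den = (n - 1) * (n - 2) * (n - 3) * s0**2
        var = num / den - e_i**2 if den != 0 else np.nan
        zscore = (I - e_i) / np.sqrt(var)
        p = 2 * stats.norm.sf(abs(zscore))
        return MoranResult(I, e_i, zscore, p, "normal")
    elif method == "permutation":
        if permutations < 1:
            raise ValueError("need at least 1 permutation")
        rng = np.random.default_rng(seed)
        sims = np.empty(permutations)
        for k in range(permutations):
            zp = rng.permutation(z)
            sims[k] = _moran_stat(zp, wm, s0)
        zscore = (I - sims.mean()) / sims.std(ddof=1)
        extreme = np.abs(sims - e_i) >= abs(I - e_i) - 1e-15
        p = (extreme.sum() + 1) / (permutations + 1)
        return MoranResult(I, e_i, zscore, min(p, 1.0), "permutation", permutations, seed)
    raise ValueError(f"unknown method {method!r}")


def local_moran(
    x,
    w: SpatialWeights,
    permutations: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
) -> LisaResult:
    """Local Moran with conditional-permutation p-values and HH/LL/HL/LH labels.

    Unit i's own value is held fixed; its neighbor values are drawn
    without replacement from the remaining n-1 observations, the standard
    conditional randomization for LISA maps.  Labels are assigned from the
    sign quadrant of (z_i, lag_i) for units with p_i < alpha; everything
    else is 'ns'.
    """
    if permutations < 1:
        raise ValueError("need at least 1 permutation")
    x, mask = _validated(x, w)
    if not w.standardized:
        raise ValueError("local_moran expects a row-standardized W")
    n = w.n
    z = x - x[mask].mean()
    z[~mask] = 0.0
    m2 = (z[mask] ** 2).sum() / mask.sum()
    lag = w.matrix @ z
    local_I = z * lag / m2

    rng = np.random.default_rng(seed)
    p = np.ones(n)
    idx_all = np.arange(n)
    for i in idx_all:
        if not mask[i]:
            continue
        wi = w.matrix[i]
        nbrs = np.nonzero(wi)[0]
        if nbrs.size == 0:
            continue
        pool = z[np.setdiff1d(idx_all[mask], [i])]
        # draw |nbrs| values per permutation from the conditional pool
        draws = np.empty((permutations, nbrs.size))
        for k in range(permutations):
            draws[k] = rng.choice(pool, size=nbrs.size, replace=False)
        sim_lag = draws @ wi[nbrs]
        sim_I = z[i] * sim_lag / m2
        extreme = np.abs(sim_I) >= abs(local_I[i]) - 1e-15
        p[i] = (extreme.sum() + 1) / (permutations + 1)

    labels = []
    for i in idx_all:
        if not mask[i] or p[i] >= alpha:
            labels.append("ns")
        elif z[i] >= 0:
            labels.append("HH" if lag[i] >= 0 else "HL")
        else:
            labels.append("LH" if lag[i] >= 0 else "LL")
    return LisaResult(
        w.unit_ids, local_I, p, tuple(labels), alpha, permutations, seed
    )
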