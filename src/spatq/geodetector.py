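"""Geographical-detector statistics for stratified spatial heterogeneity.

The core quantity is the power-of-determinant (q / PD) statistic of a
stratification h = 1..L of N units:

    PD = 1 - (sum_h N_h * sigma_h^2) / (N * sigma^2) = 1 - SSW / SST,

with population variances, so PD lies in [0, 1]: the share of the
outcome's variance explained by the strata.  Four detectors build on it:

* factor detector — PD of one stratification, with the noncentral-F
  significance test of the q-statistic;
* interaction detector — PD of the overlay (cartesian intersection) of
  two stratifications, classified as weakening / enhancing / independent
  by comparison with the single-factor PDs;
* risk detector — per-stratum outcome means with pairwise Welch t-tests,
  identifying the stratum (value interval) with the highest outcome;
* ecological detector — an F-ratio comparing the within-stratum sums of
  squares of two competing stratifications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "Stratification",
    "FactorDetection",
    "InteractionResult",
    "RiskTable",
    "EcoDetection",
    "factor_detector",
    "interaction_detector",
    "risk_detector",
    "ecological_detector",
    "overlay",
]

_EQ_TOL = 1e-9  # tolerance for the measure-zero "Independent" equality case


@dataclass(frozen=True)
class Stratification:
    labels: np.ndarray  # per-unit stratum label 1..L
    provenance: object = None  # DiscretizationScheme or categorical source

    def __post_init__(self):
        lab = np.asarray(self.labels)
        uniq = np.unique(lab)
        if uniq.size < 2:
            raise ValueError("a stratification needs at least 2 strata")
        # normalize to consecutive 1..L
        remap = {u: i for i, u in enumerate(uniq, start=1)}
        object.__setattr__(self, "labels",
                           np.array([remap[v] for v in lab], dtype=int))

    @property
    def L(self) -> int:
        return int(self.labels.max())

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class FactorDetection:
    pd: float
    p_value: float
    strata_n: np.ndarray
    strata_mean: np.ndarray
    strata_var: np.ndarray  # population variances
    N: int
    sigma2: float


@dataclass(frozen=True)
class InteractionResult:
    pd_a: float
    pd_b: float
    pd_ab: float
    type: str
    dropped_cells: int = 0


@dataclass(frozen=True)
class RiskTable:
    strata_mean: np.ndarray
    significant: np.ndarray  # (L, L) bool, symmetric, diagonal False
    tested: np.ndarray  # (L, L) bool: pair had enough data for a test
    optimal_stratum: int
    optimal_interval: tuple
    max_mean: float
    alpha: float


@dataclass(frozen=True)
class EcoDetection:
    F: float
    significant: bool
    alpha: float


def _groups(outcome, strat: Stratification):
    y = np.asarray(outcome, dtype=float)
    if y.shape != strat.labels.shape:
        raise ValueError("outcome and stratification length mismatch")
    return y, [y[strat.labels == h] for h in range(1, strat.L + 1)]


def factor_detector(outcome, strat: Stratification) -> FactorDetection:
    """PD (q) statistic with the noncentral-F significance test.

    The transformed statistic F = (N-L)/(L-1) * q/(1-q) follows a
    noncentral F(L-1, N-L; lambda) distribution under the null of no
    stratified heterogeneity, with noncentrality
    lambda = (1/sigma^2) * [sum_h ybar_h^2 - (sum_h sqrt(N_h) ybar_h)^2 / N].
    """
    y, groups = _groups(outcome, strat)
    N = len(y)
    sigma2 = y.var()  # population variance
    if sigma2 == 0:
        raise ValueError("zero total variance")
    if any(len(g) == 0 for g in groups):  # pragma: no cover - labels normalized
        raise ValueError("empty stratum")
    n_h = np.array([len(g) for g in groups])
    m_h = np.array([g.mean() for g in groups])
    v_h = np.array([g.var() for g in groups])
    ssw = (n_h * v_h).sum()
    sst = N * sigma2
    pd_ = 1.0 - ssw / sst
    L = strat.L
    if N - L <= 0 or pd_ >= 1.0 - 1e-15:
        p = 0.0 if pd_ > 0 else 1.0
    else:
        F = (N - L) / (L - 1) * pd_ / (1.0 - pd_)
        lam = (np.sum(m_h**2) - (np.sum(np.sqrt(n_h) * m_h)) ** 2 / N) / sigma2
        lam = max(lam, 0.0)
        p = float(stats.ncf.sf(F, L - 1, N - L, lam))
    return FactorDetection(float(pd_), p, n_h, m_h, v_h, N, float(sigma2))


def overlay(strat_a: Stratification, strat_b: Stratification):
    """Cartesian intersection of two stratifications; empty cells drop out."""
    if strat_a.n != strat_b.n:
        raise ValueError("stratifications cover different unit sets")
    combo = strat_a.labels * (strat_b.labels.max() + 1) + strat_b.labels
    uniq, new = np.unique(combo, return_inverse=True)
    n_cells_possible = strat_a.L * strat_b.L
    dropped = n_cells_possible - uniq.size
    if uniq.size < 2:
        raise ValueError("overlay leaves fewer than 2 strata")
    return Stratification(new + 1), dropped


def interaction_detector(outcome, strat_a, strat_b) -> InteractionResult:
    """Two-factor overlay PD with the five-way synergy classification.

    Categories (with equality tolerance for the knife-edge cases):
    pd_ab < min -> "Weaken, nonlinear"; min <= pd_ab <= max ->
    "Weaken, univariate"; max < pd_ab < sum -> "Enhanced, bivariate";
    pd_ab == sum -> "Independent"; pd_ab > sum -> "Enhance, nonlinear".
    """
    ov, dropped = overlay(strat_a, strat_b)
    pd_a = factor_detector(outcome, strat_a).pd
    pd_b = factor_detector(outcome, strat_b).pd
    pd_ab = factor_detector(outcome, ov).pd
    kind = classify_interaction(pd_a, pd_b, pd_ab)
    return InteractionResult(pd_a, pd_b, pd_ab, kind, dropped)


def classify_interaction(pd_a: float, pd_b: float, pd_ab: float,
                         tol: float = _EQ_TOL) -> str:
    """Total classification of a (pd_a, pd_b, pd_ab) triple."""
    lo, hi, s = min(pd_a, pd_b), max(pd_a, pd_b), pd_a + pd_b
    if abs(pd_ab - s) <= tol:
        return "Independent"
    if pd_ab > s:
        return "Enhance, nonlinear"
    if pd_ab > hi + tol:
        return "Enhanced, bivariate"
    if pd_ab < lo - tol:
        return "Weaken, nonlinear"
    return "Weaken, univariate"


def risk_detector(outcome, strat: Stratification, alpha: float = 0.05) -> RiskTable:
    """Per-stratum means with pairwise Welch (unequal-variance) t-tests.

    Strata with fewer than 2 units are kept in the means but excluded
    from testing.  The optimal stratum is the argmax of the stratum
    means; ``optimal_interval`` is its observed outcome range (when the
    stratification came from discretizing a factor, use
    ``DiscretizationScheme.interval_of`` for the factor-value interval).
    """
    y, groups = _groups(outcome, strat)
    L = strat.L
    means = np.array([g.mean() for g in groups])
    sig = np.zeros((L, L), dtype=bool)
    tested = np.zeros((L, L), dtype=bool)
    any_test = False
    for a in range(L):
        for b in range(a + 1, L):
            ga, gb = groups[a], groups[b]
            if len(ga) < 2 or len(gb) < 2:
                continue
            t, p = stats.ttest_ind(ga, gb, equal_var=False)
            tested[a, b] = tested[b, a] = True
            any_test = True
            if p < alpha:
                sig[a, b] = sig[b, a] = True
    if not any_test:
        raise ValueError("no testable stratum pair (all strata have < 2 units)")
    best = int(np.argmax(means)) + 1
    interval = (float(y[strat.labels == best].min()),
                float(y[strat.labels == best].max()))
    return RiskTable(means, sig, tested, best, interval, float(means.max()), alpha)


def ecological_detector(outcome, strat_a, strat_b, alpha: float = 0.05) -> EcoDetection:
    """F-ratio of within-stratum sums of squares of two stratifications.

    F = (N_a (N_b - 1) SSW_a) / (N_b (N_a - 1) SSW_b).  Significance is
    two-sided — either factor may be the stronger one — so the ratio is
    compared with both tails of F(N_a - 1, N_b - 1) at level alpha.
    """
    y, groups_a = _groups(outcome, strat_a)
    _, groups_b = _groups(outcome, strat_b)
    ssw_a = sum(((g - g.mean()) ** 2).sum() for g in groups_a)
    ssw_b = sum(((g - g.mean()) ** 2).sum() for g in groups_b)
    if ssw_b == 0:
        raise ValueError("zero within-stratum sum of squares in denominator")
    n_a = n_b = len(y)
    F = (n_a * (n_b - 1) * ssw_a) / (n_b * (n_a - 1) * ssw_b)
    hi = stats.f.ppf(1 - alpha / 2, n_a - 1, n_b - 1)
    lo = stats.f.ppf(alpha / 2, n_a - 1, n_b - 1)
    return EcoDetection(float(F), bool(F > hi or F < lo), alpha)
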