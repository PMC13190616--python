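"""Continuous-to-categorical classification and PD-maximizing scheme search.

The geographical-detector statistics require categorical strata, so each
continuous determinant must first be discretized.  Five classical map
classification methods are implemented:

* ``natural_breaks`` — exact Fisher–Jenks dynamic programming, minimizing
  the within-class sum of squared deviations;
* ``quantile`` — equal-count classes;
* ``equal_interval`` — equal-width classes over the data range;
* ``geometric_interval`` — class widths in geometric progression
  (multiplicative breaks on data shifted positive when needed);
* ``std_dev`` — breaks at half-standard-deviation steps around the mean.

Interval convention everywhere: half-open [low, high), with the final
interval closed.

:func:`optimize_discretization` sweeps methods x class counts (3–8 by
default), scores each candidate stratification by the factor detector's
PD value against the outcome, and returns the argmax — the
"explanatory power maximization" rule for choosing a scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "METHODS",
    "DiscretizationScheme",
    "OptimizationResult",
    "classify",
    "optimize_discretization",
]

METHODS = ("natural_breaks", "quantile", "equal_interval",
           "geometric_interval", "std_dev")


@dataclass(frozen=True)
class DiscretizationScheme:
    method: str
    k: int  # requested class count
    breaks: tuple  # ascending interior cut points
    assignment: np.ndarray  # per-unit stratum label 1..L
    L: int  # realized stratum count

    def counts(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.L + 1)[1:]

    def interval_of(self, stratum: int, values) -> tuple:
        """Observed value range of one stratum."""
        v = np.asarray(values, dtype=float)[self.assignment == stratum]
        return float(v.min()), float(v.max())


@dataclass(frozen=True)
class OptimizationResult:
    best: DiscretizationScheme
    best_pd: float
    best_p: float
    table: tuple  # rows: (method, k, pd, p)
    skipped: tuple = field(default_factory=tuple)  # rows: (method, k, reason)


def _assign(values, breaks):
    """Half-open [low, high) assignment; last interval closed."""
    return np.searchsorted(np.asarray(breaks), values, side="right") + 1


def _fisher_jenks_breaks(values, k):
    """Exact minimal within-class SSD partition of sorted values into k classes.

    O(k n^2) dynamic program over prefix sums; returns interior break
    points placed midway between adjacent class-boundary values.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    c1 = np.concatenate([[0.0], np.cumsum(v)])
    c2 = np.concatenate([[0.0], np.cumsum(v**2)])

    def ssd(i, j):  # within-class SSD of v[i:j]
        m = j - i
        s = c1[j] - c1[i]
        return (c2[j] - c2[i]) - s * s / m

    cost = np.full((k + 1, n + 1), np.inf)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = np.inf, c - 1
            for i in range(c - 1, j):
                val = cost[c - 1, i] + ssd(i, j)
                if val < best:
                    best, arg = val, i
            cost[c, j] = best
            back[c, j] = arg
    cuts = []
    j = n
    for c in range(k, 0, -1):
        i = back[c, j]
        if c > 1:
            cuts.append(0.5 * (v[i - 1] + v[i]))
        j = i
    return tuple(sorted(cuts))


def _geometric_breaks(values, k):
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    shift = 0.0
    if lo <= 0:
        shift = 1.0 - lo
        lo, hi = lo + shift, hi + shift
    g = (hi / lo) ** (1.0 / k)
    return tuple(lo * g**i - shift for i in range(1, k))


def _stddev_breaks(values, k):
    """k-1 consecutive half-SD breaks around the mean, inside the data range.

    Candidate breaks are mean + m*(s/2) for integer m; the most
    mean-centered window of k-1 in-range breaks is chosen.  Returns None
    when the range cannot host k-1 such breaks (caller marks infeasible).
    """
    v = np.asarray(values, dtype=float)
    mu, s = v.mean(), v.std(ddof=0)
    lo, hi = v.min(), v.max()
    ms = np.arange(-4 * k, 4 * k + 1)
    cand = mu + ms * (s / 2.0)
    inside = (cand > lo) & (cand < hi)
    cand, ms = cand[inside], ms[inside]
    if len(cand) < k - 1:
        return None
    # pick the window whose |m| values are most centered on zero
    best_win, best_score = None, np.inf
    for start in range(len(cand) - (k - 2)):
        win = ms[start : start + k - 1]
        score = np.abs(win).sum()
        if score < best_score:
            best_score, best_win = score, cand[start : start + k - 1]
    return tuple(best_win)


def classify(values, method: str, k: int) -> DiscretizationScheme:
    """Discretize a continuous vector into k ordered strata.

    Returns a scheme whose realized stratum count L may be below k if a
    method produces empty classes (labels are renumbered 1..L); the
    optimizer treats L < k as an infeasible candidate.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if not np.isfinite(v).all():
        raise ValueError("non-finite values")
    if np.unique(v).size < 2:
        raise ValueError("all values equal: nothing to discretize")
    if not (2 <= k <= n - 1):
        raise ValueError(f"k = {k} outside [2, n-1]")
    if k > np.unique(v).size:
        raise ValueError(f"k = {k} exceeds the number of distinct values")

    if method == "quantile":
        qs = np.quantile(v, np.linspace(0, 1, k + 1)[1:-1], method="linear")
        breaks = tuple(np.unique(qs))
    elif method == "equal_interval":
        breaks = tuple(np.linspace(v.min(), v.max(), k + 1)[1:-1])
    elif method == "natural_breaks":
        breaks = _fisher_jenks_breaks(v, k)
    elif method == "geometric_interval":
        breaks = _geometric_breaks(v, k)
    elif method == "std_dev":
        b = _stddev_breaks(v, k)
        breaks = b if b is not None else ()
    else:
        raise ValueError(f"unknown method {method!r}")

    breaks = tuple(np.unique(breaks))
    assignment = _assign(v, breaks)
    # renumber to drop empty classes
    present = np.unique(assignment)
    remap = {old: new for new, old in enumerate(present, start=1)}
    assignment = np.array([remap[a] for a in assignment])
    L = len(present)
    return DiscretizationScheme(method, k, breaks, assignment, L)


def optimize_discretization(
    outcome,
    factor,
    methods=METHODS,
    k_range=range(3, 9),
) -> OptimizationResult:
    """Argmax-PD search over classification methods and class counts.

    Candidates whose realized strata are fewer than requested or contain
    singleton strata are skipped (the risk detector's t-tests need
    within-stratum variance) and reported with reasons.  Ties break
    toward fewer classes, then method order as listed in ``METHODS``.
    """
    from .geodetector import Stratification, factor_detector

    outcome = np.asarray(outcome, dtype=float)
    factor = np.asarray(factor, dtype=float)
    if outcome.shape != factor.shape:
        raise ValueError("outcome and factor must share unit ordering/length")

    rows, skipped = [], []
    best = None
    for method in methods:
        for k in k_range:
            try:
                scheme = classify(factor, method, k)
            except ValueError as e:
                skipped.append((method, k, str(e)))
                continue
            if scheme.L < k:
                skipped.append((method, k, "empty strata (realized L < k)"))
                continue
            if (scheme.counts() < 2).any():
                skipped.append((method, k, "singleton stratum"))
                continue
            det = factor_detector(outcome, Stratification(scheme.assignment, scheme))
            rows.append((method, k, det.pd, det.p_value))
            key = (-det.pd, k, methods.index(method))
            if best is None or key < best[0]:
                best = (key, scheme, det)
    if best is None:
        raise ValueError("all discretization candidates infeasible")
    _, scheme, det = best
    return OptimizationResult(scheme, det.pd, det.p_value, tuple(rows), tuple(skipped))
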