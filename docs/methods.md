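# Methods

This note documents the statistical models implemented in `spatq`, the
conventions and numerical choices behind them, what the synthetic
generators emulate, and the package's known limitations.

## Spatial weights

Queen contiguity treats two units as neighbors if their polygons share at
least one boundary point (edge or single vertex). Real administrative
borders carry sliver mismatches, so coordinates are snapped to a
configurable grid (default 1e-8 map units) before the intersects test;
the predicate itself is shapely's exact geometry test over an STRtree.
Unit ids are sorted lexicographically once at construction and every
matrix and vector in the package follows that order.

Units with no neighbors (true islands) keep an all-zero row, are flagged
on the weights object, raise a loud warning, and are excluded from all
spatial sums. They are never connected heuristically: whether and how to
bridge an island province to the mainland is a substantive modelling
decision the analyst must make explicitly. Row-standardization divides
each row by its sum (island rows stay zero) and is idempotent.

## Moran statistics

Global Moran's I uses the cross-product form with island units removed
from all sums. Analytic inference uses the randomization-assumption
moments (the Cliff–Ord variance involving S₀, S₁, S₂ and the sample
kurtosis) with a two-tailed normal test. Permutation inference relabels
the values over units and reports the two-tailed pseudo p-value
(b + 1)/(m + 1); it is invariant to positive affine transforms of the
data because deviations enter both numerator and denominator.

The local statistic is the standard I_i = z_i Σ_j w_ij z_j / (Σ z²/n),
whose mean over units equals the global I for a row-standardized W; this
identity is asserted in tests to 1e-10. Local p-values use conditional
permutation — unit i's value is held fixed and its neighbors' values are
drawn without replacement from the remaining n − 1 — with 999 draws by
default and a mandatory seed. Significant units are labeled by the
quadrant of (own deviation, neighbor-mean deviation): HH, LL, HL, LH;
everything else is "ns". Default significance threshold: 0.05.

## Global regression

All variables are z-standardized (population SD) before fitting by
default, making coefficients comparable and the intercept of a
standardized fit zero; a flag disables this.

VIF pruning computes VIF_j = 1/(1 − R²_j) by regressing each covariate on
the others and iteratively removes the largest-VIF covariate until all
fall below the threshold (default 5).

The LM diagnostics are the standard score tests on OLS residuals (plain
and robust, lag and error forms, each χ²(1)). The selection rule is the
classic flowchart: follow the significant plain test; when both are
significant, follow the robust form that survives (ties break to the
smaller robust p). The recommendation is logged, and both spatial models
are fitted regardless so the comparison table is always complete.

SLM and SEM are estimated by maximum likelihood via the concentrated
log-likelihood in the spatial parameter. The log-determinant
ln|I − ρW| = Σ ln(1 − ρ·eig_i) uses a dense eigendecomposition of the
row-standardized W — for W derived from a symmetric binary matrix the
spectrum is real (similarity to a symmetric matrix), and at the n ≤ a few
thousand scale this package targets the dense solve is exact and cheap.
The search is bounded by the eigenvalue interval (1/min eig, 1/max eig)
and solved by bounded scalar minimization to 1e-10. Standard errors come
from the observed information: a central finite-difference Hessian of the
full log-likelihood in (spatial parameter, β, ln σ²) at the optimum, with
asymptotic normal z-tests, matching the output shape of the standard
spatial-econometrics tools.

Conventions worth stating because tools differ:

* SLM fitted values include the lag term (ŷ = ρ̂Wy + Xβ̂), so residuals
  are the model innovations — the quantity whose Moran test should be
  non-significant when the model is right.
* Pseudo-R² for SLM/SEM is the squared Pearson correlation of observed
  and fitted outcome (R² is not otherwise defined for these models).
* AIC counts β's, σ², and the spatial parameter as free parameters, so
  OLS/SLM/SEM AICs are internally comparable.

## Local regression

GWR solves a weighted least-squares problem at every focal unit with
fixed Gaussian kernel weights exp(−½(d/bw)²) on planar Euclidean
distances. Coordinates that look like lon/lat (range check) are not
silently accepted as planar: the package targets projected coordinates.
The hat matrix is accumulated row by row, giving the effective number of
parameters tr(S) and the corrected criterion

AICc = n ln σ̂² + n ln 2π + n(n + tr S)/(n − 2 − tr S).

Bandwidth selection is a golden-section search of AICc on
[min pairwise distance, 2 × max pairwise distance]; the search trace is
returned for audit. One caveat documented deliberately: under exactly
constant coefficients the AICc profile in bandwidth is nearly flat with
occasional shallow interior minima, so the selected single bandwidth is
usually — not always — near the bracket maximum. The multiscale model
below resolves the scales much more sharply.

MGWR back-fits one univariate smoother per term (intercept included):
initialize from the all-terms GWR fit; each sweep re-selects every term's
bandwidth by AICc against the current partial residual and re-smooths its
contribution; converge when the relative change in the residual sum of
squares (SOC-RSS) falls below 1e-5 (trace retained; non-convergence at
200 sweeps is an error, not a silent return). Bandwidths are re-selected
every sweep rather than frozen after the first — slower but faithful to
the published algorithm. Per-term hat matrices are propagated through the
back-fit (R_k ← S_k(I − Σ_{j≠k} R_j)), yielding per-term effective
parameters tr(R_k) used in two places: per-term local t-values (variance
of the term contribution divided through the covariate), and the
per-term alpha adjustment α_k = α · p / enp_k (capped at α) in
`local_significance`, which compensates for the multiplicity of dependent
local tests. Local R² uses the estimation kernel (GWR) or the mean of
the per-term kernels (MGWR).

## Discretization

Interval convention everywhere: half-open [low, high), final interval
closed. The five methods:

* **natural breaks** — exact Fisher–Jenks dynamic programming (O(kn²))
  minimizing within-class sum of squared deviations; deterministic, no
  heuristic initialization; verified against exhaustive search in tests.
* **quantile** — equal-count classes from linear-interpolation quantiles.
* **equal interval** — equal widths across the data range.
* **geometric interval** — multiplicative breaks b_i = min·gⁱ with
  g = (max/min)^(1/k); when min ≤ 0 the data are shifted by (1 − min)
  first and the breaks shifted back. The originating GIS algorithm is
  proprietary; this documented approximation is the package's contract.
* **standard deviation** — candidate breaks at mean + m·(s/2) for integer
  m; the most mean-centered window of k − 1 in-range breaks is used, and
  when the data range cannot host k − 1 half-SD breaks the candidate is
  infeasible rather than silently coarser.

A scheme that produces empty classes is renumbered to its realized L;
the optimizer treats L < k, or any singleton stratum (the risk detector's
t-tests need within-stratum variance), as infeasible and reports the
skip reason. `optimize_discretization` scores every feasible
(method, k ∈ 3..8) candidate by the factor detector's PD against the
outcome and returns the argmax; ties break to fewer classes, then method
order. At study scale (n ≈ 31) this maximization inflates null PD — a
factor independent of the outcome still reaches best-PD ≈ 0.3–0.4 — so
PD values selected this way must lean on the significance test, not the
point value alone.

## Geodetector

PD uses population variances throughout, making PD ≡ 1 − SSW/SST exactly
and guaranteeing PD ∈ [0, 1]; sample-variance conventions would break
both at small n. The factor significance test is the noncentral-F
transformation of the q-statistic: F = (N−L)/(L−1) · q/(1−q) against
F(L−1, N−L; λ) with λ = (Σ ȳ_h² − (Σ √N_h ȳ_h)²/N)/σ².

Interactions overlay two stratifications by cartesian intersection;
cells emptied by the data are dropped and counted (dropping breaks the
refinement inequality PD_ab ≥ max(PD_a, PD_b), so the user must see it).
The five-category classification compares PD_ab with min, max, and sum
of the single-factor PDs; the measure-zero "Independent" equality case
carries an explicit 1e-9 tolerance. The risk detector uses Welch
(unequal-variance) t-tests on all stratum pairs with N_h ≥ 2. The
ecological detector's F-ratio of within-stratum sums of squares is
tested two-sided — either factor may be the stronger — so the verdict is
symmetric under swapping the factors.

## Synthetic data

The generators produce exactly the structures the methods assume, plus
ground truth, so every validation quantity is computed against a known
answer. Randomness is NumPy's PCG64 (`default_rng(seed)`); same spec and
seed is bit-identical.

* **Layouts**: queen-contiguity lattices (unit squares, cell-center
  coordinates), rings, and a 31-unit ring-plus-chords graph standing in
  for a provincial study area (degrees 2–4, fully connected). Real
  border geometry is deliberately not required by any test.
* **Covariates**: iid rows from N(0, C) pushed through the spatial
  filter (I − δW)⁻¹ per column, then rescaled to unit variance. The
  filter preserves cross-column correlation while inducing positive
  spatial autocorrelation increasing in δ ∈ (−1, 1).
* **Outcomes**: spatial-lag y = (I − ρW)⁻¹(Xβ + ε); spatial-error
  y = Xβ + (I − λW)⁻¹ε; spatially varying coefficients
  y_i = Σ_k β_k(u_i, v_i)x_ik + ε_i with a surface library (constant,
  linear east–west gradient, Gaussian bumps of configurable
  length-scale). Noise is Gaussian throughout.
* **Stratified outcomes**: L near-equal strata with equally spaced means
  scaled by c = σ_w √(q/(1−q)) / sd(grid), so the expected
  between-strata variance share — hence the expected PD — equals the
  target q.
* **Study-like fixture** (`simulate_study_like`): 31 units, seven
  determinants named after a typical provincial table (GDP per capita,
  household size, education years, hospital beds, PM2.5, consumption,
  urbanization). The GDP–consumption–urbanization block has target
  correlations 0.93/0.88/0.82 (population VIFs ≈ 29/19/5), so VIF
  screening prunes it, mirroring the collinearity a real determinant
  table exhibits. Covariate smoothing δ = 0.8 gives the outcome the
  pronounced positive autocorrelation (Moran's I ≈ 0.5 on average)
  characteristic of provincial health outcomes. The outcome is an SVC
  process whose education and GDP effects strengthen westward, with a
  weak constant negative household-size effect and near-null healthcare
  and PM2.5 effects; noise SD 0.3 on unit-variance covariates.

What the generators do **not** emulate: non-Gaussian and heteroskedastic
noise, measurement error in the determinants, real border topology,
missing data, and temporal dynamics. Passing the validation battery
therefore demonstrates correctness of the statistical machinery under
the stated assumptions, not robustness of substantive conclusions drawn
from any real dataset.

## Problem sizes used in validation

The test suite and the acceptance script size their simulations to keep
a full run fast while leaving comfortable statistical margins: test-size
calibration uses 500 null replicates on an 8×8 lattice with 199
permutations; parameter recovery uses 100 replicates at n = 400 (20×20
lattice) for ρ and λ and 50 replicates at n = 1000 for the stratified
generator; MGWR scale separation uses 50 replicates at n = 100; the
modelling-storyline check uses 20 replicates at n = 64.

## Known limitations

* Dense weight matrices and dense eigendecompositions cap practical
  problem sizes at a few thousand units; no sparse/Chebyshev
  log-determinant approximations are provided.
* No adaptive (nearest-neighbor) kernels, bootstrap bandwidth inference,
  or Monte Carlo tests of coefficient spatial variability in GWR/MGWR.
* No higher-order contiguity, k-nearest-neighbor, or distance-band
  weights; no polygon repair beyond coordinate snapping.
* Geodetector interactions are pairwise only.
* The MGWR per-term alpha adjustment is a documented package choice; the
  literature has no single standard for local-test multiplicity in MGWR.
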