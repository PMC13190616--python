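# spatq

Spatial determinant analysis for areal health outcomes: spatial
autocorrelation, spatial econometric regression, multiscale local
regression, and geographical-detector statistics — in one tested Python
package, with synthetic data generators that carry known ground truth so
the whole workflow can be validated end to end.

## Who this is for

Spatial epidemiologists and health geographers analyzing an outcome
(e.g., provincial life expectancy) over n areal units with a handful of
socioeconomic and environmental determinants. The package covers the
standard multi-tier workflow:

1. **Spatial weights** — first-order queen contiguity from GeoJSON
   polygons (units are neighbors if they share at least one boundary
   point), or an explicit adjacency-pair list; row-standardization;
   islands flagged, never silently bridged.
2. **Spatial autocorrelation** — global Moran's I

   *I* = n Σᵢ Σⱼ wᵢⱼ zᵢ zⱼ / (Σᵢ Σⱼ wᵢⱼ · Σᵢ zᵢ²),  zᵢ = xᵢ − x̄,

   with analytic (randomization) or permutation inference, and the local
   decomposition *Iᵢ* = zᵢ Σⱼ wᵢⱼ zⱼ / (Σₖ zₖ²/n) with conditional-
   permutation p-values and HH/LL/HL/LH cluster labels.
3. **Global regression** — OLS with iterative VIF pruning (threshold 5),
   Lagrange-multiplier diagnostics (plain and robust, lag and error)
   driving the classic model choice, and maximum-likelihood spatial lag
   (y = ρWy + Xβ + ε) and spatial error (y = Xβ + u, u = λWu + ε)
   models via the concentrated log-likelihood with an exact eigenvalue
   log-determinant.
4. **Local regression** — GWR with a fixed Gaussian kernel
   w = exp(−½ (d/bw)²) and AICc-selected bandwidth, and multiscale GWR
   (MGWR) whose back-fitting loop gives every term its own bandwidth —
   its operating spatial scale — with per-term effective parameters for
   adjusted local inference.
5. **Geodetector** — the power-of-determinant statistic
   PD = 1 − Σₕ Nₕσₕ² / (Nσ²) of a stratification (factor detector with
   the noncentral-F test), two-factor overlay interactions classified as
   weakening/enhancing/independent, per-stratum risk tables with Welch
   t-tests, and the ecological F-comparison — fed by five discretization
   methods (Fisher–Jenks natural breaks, quantile, equal interval,
   geometric interval, standard deviation) searched over 3–8 classes
   under the explanatory-power-maximization rule.
6. **Pipeline** — one configured call running the full sequence and
   writing machine-readable CSV/JSON report tables.

## Worked example

```python
import numpy as np, pandas as pd
from spatq import (RegressionSpec, fit_ols, fit_slm, lm_diagnostics,
                   residual_moran)
from spatq import synthetic as syn

lay = syn.make_lattice(10, 10)                      # 100 units, queen weights
X = syn.simulate_covariates(lay, np.eye(2), delta=0.3, seed=1)
y, truth = syn.simulate_sar_outcome(lay, X.to_numpy(),
                                    beta=[0, 1, 2], rho=0.6, seed=2)
df = pd.DataFrame({"y": y, "x1": X.iloc[:, 0], "x2": X.iloc[:, 1]})
spec = RegressionSpec("y", ("x1", "x2"))

ols = fit_ols(df, spec)
print(residual_moran(ols, lay.weights_std).p_value)  # 0.0000 — OLS leaves
                                                     # spatial structure
lm = lm_diagnostics(ols, lay.weights_std, df, spec)
print(lm.recommendation)                             # 'SLM'
slm = fit_slm(df, spec, lay.weights_std)
print(round(slm.spatial_param, 3))                   # 0.673 — near true 0.6
print(residual_moran(slm, lay.weights_std).p_value)  # 0.686 — innovations
                                                     # are white noise
```

The numbers shown are what the script prints for these seeds: OLS on
lag-generated data leaves significantly autocorrelated residuals, the
diagnostics point to the lag model, the ML fit recovers the generating
spatial parameter, and its innovations pass the Moran test — the
canonical modelling sequence on data where the truth is known.

The `examples/` directory has one short narrative script per capability
(Moran/LISA, global models, GWR/MGWR, geodetector, full pipeline); each
prints its results with a line on what they mean. A thin CLI covers the
two shell-shaped entry points:

```bash
spatq simulate --model study --seed 7 --out data/
spatq pipeline --config config.json
```

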