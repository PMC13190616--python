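"""End-to-end orchestration of the spatial determinant analysis.

One configured run reproduces the whole study sequence on a unit table:

1. build the spatial weights (queen contiguity from GeoJSON, or an
   adjacency-pair list) and row-standardize them;
2. global Moran's I and the LISA cluster map of the outcome;
3. OLS with VIF pruning of the collinear covariates, residual Moran,
   and LM diagnostics;
4. SLM and SEM by maximum likelihood, with the LM recommendation
   flagged as the selected model;
5. GWR and MGWR on the pruned covariate set;
6. a four-model comparison table (residual Moran's I, R-squared,
   AIC/AICc, log-likelihood);
7. per-factor PD-optimal discretization and the four detectors
   (factor, interaction, risk, ecological) on the *unpruned* covariate
   list — the detectors are immune to collinearity, so nothing is
   dropped there.

Every stochastic step takes its seed from the config; rerunning the same
config on the same inputs reproduces the report exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import discretize, geodetector, gwr, moran, regression, weights

__all__ = ["PipelineConfig", "StudyReport", "run_pipeline", "model_comparison"]


@dataclass(frozen=True)
class PipelineConfig:
    table: str | None  # unit-table CSV path
    outcome: str
    covariates: tuple
    geojson: str | None = None
    adjacency: str | None = None
    id_column: str = "id"
    coord_columns: tuple = ("coord_x", "coord_y")
    alpha: float = 0.05
    permutations: int = 999
    seed: int = 0
    vif_threshold: float = 5.0
    k_range: tuple = (3, 8)
    methods: tuple = discretize.METHODS
    out_dir: str | None = None

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("covariates", "coord_columns", "k_range", "methods"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class StudyReport:
    config: PipelineConfig
    input_hash: str
    moran_global: moran.MoranResult = None
    lisa: moran.LisaResult = None
    collinearity: regression.CollinearityReport = None
    ols: regression.GlobalFit = None
    lm: regression.LmDiagnostics = None
    slm: regression.GlobalFit = None
    sem: regression.GlobalFit = None
    selected_model: str = None
    gwr_fit: gwr.LocalFit = None
    mgwr_fit: gwr.LocalFit = None
    comparison: pd.DataFrame = None
    discretization: dict = field(default_factory=dict)  # factor -> OptimizationResult
    factor_pd: pd.DataFrame = None
    risk: dict = field(default_factory=dict)
    ecological: pd.DataFrame = None
    interaction_pd: pd.DataFrame = None
    interaction_type: pd.DataFrame = None
    log: list = field(default_factory=list)


def _hash_inputs(table: pd.DataFrame, w: weights.SpatialWeights, config) -> str:
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(table, index=True).values.tobytes())
    h.update(np.ascontiguousarray(w.matrix).tobytes())
    cfg_items = {k: v for k, v in config.__dict__.items() if k != "out_dir"}
    h.update(json.dumps(sorted(cfg_items.items(), key=str), default=str).encode())
    return h.hexdigest()[:16]


def _load_inputs(config: PipelineConfig, table=None, w=None, coords=None):
    if table is None:
        table = pd.read_csv(config.table)
    table = table.sort_values(config.id_column).reset_index(drop=True)
    if w is None:
        if config.geojson:
            polys = weights.read_geojson_polygons(config.geojson, config.id_column)
            w = weights.queen_contiguity(polys)
        elif config.adjacency:
            pairs = weights.read_adjacency_file(config.adjacency)
            w = weights.from_adjacency_pairs(pairs, table[config.id_column].tolist())
        else:
            raise ValueError("config must provide geometry or adjacency input")
    if list(table[config.id_column]) != list(w.unit_ids):
        raise ValueError("unit ids in table and weights disagree")
    if coords is None:
        cx, cy = config.coord_columns
        coords = table[[cx, cy]].to_numpy(dtype=float)
    return table, w, coords


def model_comparison(fits: dict, w: weights.SpatialWeights) -> pd.DataFrame:
    """Four-row comparison table: residual Moran's I (p), R2, AIC/AICc, log-lik.

    ``fits`` maps model name -> GlobalFit or LocalFit.  Local fits report
    AICc (the criterion that selected their bandwidths) in the AIC row,
    and a pseudo-R2 from squared observed-fitted correlation.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to compare")
    rows = {"moran_residual_I": {}, "moran_residual_p": {}, "r2": {},
            "aic": {}, "log_likelihood": {}}
    n_ref = None
    for name, fit in fits.items():
        n = fit.n
        if n_ref is None:
            n_ref = n
        elif n != n_ref:
            raise ValueError("fits cover different unit sets")
        mres = moran.global_moran(fit.residuals, w, method="normal")
        rows["moran_residual_I"][name] = mres.I
        rows["moran_residual_p"][name] = mres.p_value
        if isinstance(fit, gwr.LocalFit):
            y = fit.fitted + fit.residuals
            rows["r2"][name] = float(np.corrcoef(y, fit.fitted)[0, 1] ** 2)
            rows["aic"][name] = fit.aicc
            rss = float(fit.residuals @ fit.residuals)
            rows["log_likelihood"][name] = float(
                -0.5 * n * (np.log(2 * np.pi * rss / n) + 1))
        else:
            rows["r2"][name] = fit.r2
            rows["aic"][name] = fit.aic
            rows["log_likelihood"][name] = fit.log_likelihood
    df = pd.DataFrame(rows).T
    order = df.loc["aic"].rank(method="min").astype(int)
    df.loc["aic_rank"] = order
    return df


def run_pipeline(config: PipelineConfig, table=None, w=None, coords=None) -> StudyReport:
    """Run the full analysis; optionally pass preloaded inputs.

    Writes CSV/JSON artifacts to ``config.out_dir`` when set.
    """
    table, w, coords = _load_inputs(config, table, w, coords)
    wstd = weights.row_standardize(w)
    report = StudyReport(config, _hash_inputs(table, w, config))
    log = report.log
    y = table[config.outcome].to_numpy(dtype=float)
    rng = np.random.default_rng(config.seed)

    # 1-2. autocorrelation
    report.moran_global = moran.global_moran(
        y, wstd, method="permutation", permutations=config.permutations,
        seed=int(rng.integers(2**31)))
    log.append(f"global Moran I={report.moran_global.I:.4f} "
               f"p={report.moran_global.p_value:.4g}")
    report.lisa = moran.local_moran(
        y, wstd, permutations=config.permutations,
        seed=int(rng.integers(2**31)), alpha=config.alpha)

    # 3. OLS + VIF + LM
    spec_all = regression.RegressionSpec(config.outcome, config.covariates)
    report.collinearity = regression.vif_prune(table, spec_all, config.vif_threshold)
    pruned = tuple(c for c in config.covariates
                   if c not in report.collinearity.dropped)
    log.append(f"VIF pruning dropped: {report.collinearity.dropped or 'nothing'}")
    spec = regression.RegressionSpec(config.outcome, pruned)
    report.ols = regression.fit_ols(table, spec)
    report.lm = regression.lm_diagnostics(report.ols, wstd, table, spec,
                                          alpha=config.alpha)
    report.selected_model = report.lm.recommendation
    log.append(f"LM recommendation: {report.selected_model}")

    # 4. spatial models (both fitted; recommendation is a flag)
    report.slm = regression.fit_slm(table, spec, wstd)
    report.sem = regression.fit_sem(table, spec, wstd)

    # 5. local models on the pruned set
    dfz = table[[config.outcome, *pruned]].astype(float)
    dfz = (dfz - dfz.mean()) / dfz.std(ddof=0)
    yz = dfz[config.outcome].to_numpy()
    Xz = np.column_stack([np.ones(len(table)), dfz[list(pruned)].to_numpy()])
    names = ("intercept", *pruned)
    bw, _ = gwr.select_bandwidth(yz, Xz, coords)
    report.gwr_fit = gwr.fit_gwr(yz, Xz, coords, bw, term_names=names)
    report.mgwr_fit = gwr.fit_mgwr(yz, Xz, coords, term_names=names)
    log.append(f"GWR bw={bw:.3g}; MGWR bws="
               + np.array2string(report.mgwr_fit.bandwidths, precision=3))

    # 6. model comparison
    report.comparison = model_comparison(
        {"OLS": report.ols, "SLM": report.slm, "SEM": report.sem,
         "GWR": report.gwr_fit, "MGWR": report.mgwr_fit}, wstd)

    # 7. detectors on the full (unpruned) factor list
    k_lo, k_hi = config.k_range
    strats, pd_rows = {}, []
    for c in config.covariates:
        opt = discretize.optimize_discretization(
            y, table[c].to_numpy(dtype=float),
            methods=config.methods, k_range=range(k_lo, k_hi + 1))
        report.discretization[c] = opt
        strats[c] = geodetector.Stratification(opt.best.assignment, opt.best)
        det = geodetector.factor_detector(y, strats[c])
        pd_rows.append((c, det.pd, det.p_value, opt.best.method, opt.best.k))
    report.factor_pd = pd.DataFrame(
        pd_rows, columns=["factor", "pd", "p", "method", "k"]
    ).set_index("factor")

    for c in config.covariates:
        report.risk[c] = geodetector.risk_detector(y, strats[c], alpha=config.alpha)

    covs = list(config.covariates)
    eco = pd.DataFrame(index=covs, columns=covs, dtype=object)
    ipd = pd.DataFrame(np.nan, index=covs, columns=covs)
    ityp = pd.DataFrame(index=covs, columns=covs, dtype=object)
    for i, a in enumerate(covs):
        ipd.loc[a, a] = report.factor_pd.loc[a, "pd"]
        for b in covs[i + 1:]:
            e = geodetector.ecological_detector(y, strats[a], strats[b],
                                                alpha=config.alpha)
            eco.loc[a, b] = "Y" if e.significant else "N"
            inter = geodetector.interaction_detector(y, strats[a], strats[b])
            ipd.loc[a, b] = ipd.loc[b, a] = inter.pd_ab
            ityp.loc[a, b] = ityp.loc[b, a] = inter.type
    report.ecological = eco
    report.interaction_pd = ipd
    report.interaction_type = ityp

    if config.out_dir:
        _write_artifacts(report, table, wstd, config)
    return report


def _write_artifacts(report: StudyReport, table, wstd, config: PipelineConfig):
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = list(wstd.unit_ids)

    with open(out / "report.json", "w") as fh:
        json.dump({
            "input_hash": report.input_hash,
            "seed": config.seed,
            "moran_global": {"I": report.moran_global.I,
                             "p": report.moran_global.p_value},
            "vif": report.collinearity.vif,
            "dropped": list(report.collinearity.dropped),
            "lm": {"lm_lag": report.lm.lm_lag, "p_lm_lag": report.lm.p_lm_lag,
                   "lm_error": report.lm.lm_error,
                   "p_lm_error": report.lm.p_lm_error,
                   "recommendation": report.lm.recommendation},
            "selected_model": report.selected_model,
            "gwr_bandwidth": float(report.gwr_fit.bandwidths[0]),
            "mgwr_bandwidths": report.mgwr_fit.bandwidths.tolist(),
            "log": report.log,
        }, fh, indent=2)

    pd.DataFrame({
        "id": ids,
        "local_I": report.lisa.local_I,
        "p": report.lisa.p_values,
        "label": list(report.lisa.labels),
    }).to_csv(out / "lisa.csv", index=False)

    report.comparison.to_csv(out / "model_comparison.csv")
    report.factor_pd.to_csv(out / "factor_pd.csv")
    report.interaction_pd.to_csv(out / "interaction_pd.csv")
    report.interaction_type.to_csv(out / "interaction_type.csv")
    report.ecological.to_csv(out / "ecological.csv")

    loc = pd.DataFrame({"id": ids})
    for j, t in enumerate(report.mgwr_fit.term_names):
        loc[f"beta_{t}"] = report.mgwr_fit.local_coefficients[:, j]
        loc[f"t_{t}"] = report.mgwr_fit.local_t[:, j]
    loc["local_r2"] = report.mgwr_fit.local_r2
    loc.to_csv(out / "mgwr_local.csv", index=False)

    risk_rows = []
    for c, rt in report.risk.items():
        risk_rows.append((c, rt.optimal_stratum, rt.optimal_interval[0],
                          rt.optimal_interval[1], rt.max_mean))
    pd.DataFrame(risk_rows, columns=["factor", "optimal_stratum", "interval_lo",
                                     "interval_hi", "max_mean"]
                 ).to_csv(out / "risk.csv", index=False)
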