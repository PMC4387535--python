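"""End-to-end orchestration: simulate -> select -> fit -> predict -> validate
-> coverage -> report.

All randomness flows from one root seed; each stage derives its own seed as
``(root * 1_000_003 + crc32(stage_name)) mod 2^31`` so stages can be rerun in
isolation and the whole pipeline is bit-reproducible.  Stage timings go to
the logger only; the report JSON contains nothing non-deterministic.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coverage as cov
from . import io, selection, synthetic, validation
from . import stgp
from .grids import RasterGrid, write_ascii_grid

logger = logging.getLogger(__name__)


def stage_seed(root_seed: int, stage: str) -> int:
    return (root_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    grid_size: int = 50
    cell_size: float = 0.2              # degrees; 50 x 0.2 = 10 degree extent
    n_clusters: int = 300
    n_waves: int = 2
    n_zones: tuple[int, int] = (3, 3)
    # generating model (defaults at the fitted real-data magnitudes)
    model: dict = field(default_factory=lambda: {
        "beta": {"intercept": 0.1815, "accessibility": 0.0044, "evi": -0.0045,
                 "landcover": -0.0035, "nightlights": 0.0016},
        "sigma2": 7e-4, "kappa": float(np.exp(-0.47)), "nugget": 2.2e-3,
        "rho": -0.47, "nu": 1.0,
    })
    candidates: list[str] = field(default_factory=lambda: list(synthetic.LAYER_NAMES))
    holdout_fraction: float = 0.10
    interval: float = 0.95
    buffer_radius: float = 0.0
    un_p: float = 0.175
    national_coverage: float = 0.397    # intervention coverage applied per zone
    population_total: float = 1e6
    n_starts: int = 3
    run_coverage: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the artefact bundle under ``config.out_dir``.

    Returns the report dict (also written as ``report.json``): selection
    ranking, fitted-parameter summary table, model-comparison table,
    validation metrics and semivariogram, and zonal coverage comparison.
    """
    import scipy

    from . import __version__
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("u5mbg %s (numpy %s, scipy %s), root seed %d",
                __version__, np.__version__, scipy.__version__, config.seed)
    report: dict = {"config": {"seed": config.seed, "grid_size": config.grid_size,
                               "n_clusters": config.n_clusters,
                               "n_waves": config.n_waves,
                               "interval": config.interval}}
    t_all = time.perf_counter()

    # -- simulate ----------------------------------------------------------
    t0 = time.perf_counter()
    grid = RasterGrid(x_origin=3.0, y_origin=4.0, cell_size=config.cell_size,
                      n_rows=config.grid_size, n_cols=config.grid_size)
    stack = synthetic.gen_covariate_stack(grid, stage_seed(config.seed, "covariates"))
    zones = synthetic.gen_zone_raster(grid, *config.n_zones)
    true_model = stgp.STGPModel.from_dict(config.model)
    clusters, truth = synthetic.simulate_survey(
        stack, true_model, config.n_clusters, config.n_waves,
        seed=stage_seed(config.seed, "survey"), zones=zones)
    pop = synthetic.gen_population_raster(
        grid, stage_seed(config.seed, "population"),
        total=config.population_total, stack=stack)
    io.write_clusters(clusters, out / "clusters.csv")
    for name, layer in stack.layers.items():
        write_ascii_grid(out / f"cov_{name}.asc", grid, layer)
    write_ascii_grid(out / "population.asc", grid, pop)
    write_ascii_grid(out / "zones.asc", grid, zones.astype(float))
    io.write_model_json(true_model, out / "true_model.json",
                        extra={"seed": config.seed, "n_clipped": truth.n_clipped})
    pd.DataFrame({
        "cluster_id": clusters["cluster_id"],
        "true_lon": truth.true_lonlat[:, 0], "true_lat": truth.true_lonlat[:, 1],
        "linear_predictor": truth.linear_predictor, "gp": truth.gp,
    }).to_csv(out / "truth.csv", index=False)
    logger.info("simulate: %d clusters in %.1fs", len(clusters),
                time.perf_counter() - t0)

    # -- covariate selection ----------------------------------------------
    t0 = time.perf_counter()
    Z = stack.values_at(clusters["lon"].to_numpy(), clusters["lat"].to_numpy(),
                        config.candidates, buffer_radius=config.buffer_radius)
    X = pd.DataFrame(Z, columns=config.candidates)
    ranking = selection.best_subset_bic(X, clusters["p_under5"].to_numpy())
    selected = list(ranking[0].subset)
    report["selection"] = {
        "selected": selected,
        "table": selection.ranking_table(ranking).head(10).to_dict("records"),
    }
    io.write_json(report["selection"], out / "selection.json")
    logger.info("select: %s in %.1fs", selected, time.perf_counter() - t0)

    # -- fit + model comparison -------------------------------------------
    t0 = time.perf_counter()
    fit_cfg = stgp.FitConfig(seed=stage_seed(config.seed, "fit"),
                             interval=config.interval,
                             buffer_radius=config.buffer_radius,
                             n_starts=config.n_starts)
    train, test = validation.holdout_split(
        clusters, config.holdout_fraction, seed=stage_seed(config.seed, "holdout"))
    fit_full = stgp.fit(clusters, stack, selected, fit_cfg)
    report["fit"] = {
        "parameters": fit_full.summaries.round(6).to_dict("index"),
        "loglik": fit_full.loglik, "dic": fit_full.dic, "p_d": fit_full.p_d,
        "range_deg": fit_full.model.range_deg,
        "range_km": fit_full.model.range_deg * stgp.KM_PER_DEGREE,
        "convergence": fit_full.convergence,
    }
    io.write_json(report["fit"], out / "fit.json")
    # comparison menu: top subsets from the selection ranking
    menu, seen = [], set()
    for r in ranking:
        if r.subset not in seen:
            menu.append(list(r.subset))
            seen.add(r.subset)
        if len(menu) == 3:
            break
    fits = [fit_full if m == selected else stgp.fit(clusters, stack, m, fit_cfg)
            for m in menu]
    report["model_comparison"] = stgp.compare_models(fits).to_dict("records")
    logger.info("fit: range %.2f deg in %.1fs", fit_full.model.range_deg,
                time.perf_counter() - t0)

    # -- predict -----------------------------------------------------------
    t0 = time.perf_counter()
    wave = config.n_waves - 1
    surface = stgp.predict(fit_full, stack, wave, fit_cfg)
    write_ascii_grid(out / "surface_mean.asc", grid, surface.mean)
    write_ascii_grid(out / "surface_lower.asc", grid, surface.lower)
    write_ascii_grid(out / "surface_upper.asc", grid, surface.upper)
    report["surface"] = {"wave": wave, "interval": surface.interval,
                         "n_clipped": surface.n_clipped,
                         "mean_of_mean": float(np.nanmean(surface.mean)),
                         "mean_width": float(np.nanmean(surface.width))}
    logger.info("predict: wave %d in %.1fs", wave, time.perf_counter() - t0)

    # -- validate ----------------------------------------------------------
    t0 = time.perf_counter()
    fit_train = stgp.fit(train, stack, selected, fit_cfg)
    X_test = np.column_stack([
        np.ones(len(test)),
        stack.values_at(test["lon"].to_numpy(), test["lat"].to_numpy(), selected,
                        buffer_radius=config.buffer_radius)])
    mu, _ = stgp.predict_points(fit_train, X_test,
                                test[["lon", "lat"]].to_numpy(dtype=float),
                                test["time"].to_numpy(dtype=float),
                                include_nugget=True)
    hm = validation.holdout_metrics(test["p_under5"].to_numpy(), mu)
    cpo = validation.loo_cpo(fit_full)
    resid = validation.loo_residuals(fit_full)
    sv = validation.residual_semivariogram(
        resid, clusters[["lon", "lat"]].to_numpy(dtype=float),
        seed=stage_seed(config.seed, "semivariogram"))
    validation.semivariogram_table(sv).to_csv(out / "semivariogram.csv", index=False)
    frac_in = float(np.mean((sv.gamma >= sv.lower) & (sv.gamma <= sv.upper)))
    report["validation"] = {
        "n_test": len(test), "mpe": hm.mpe, "mae": hm.mae, "rmse": hm.rmse,
        "pearson_r": hm.pearson_r, "cpo_min": float(cpo.min()),
        "cpo_log_sum": float(np.log(cpo).sum()),
        "semivariogram_fraction_in_envelope": frac_in,
    }
    io.write_json(report["validation"], out / "validation.json")
    logger.info("validate: r=%.3f in %.1fs", hm.pearson_r, time.perf_counter() - t0)

    # -- coverage application ---------------------------------------------
    if config.run_coverage:
        t0 = time.perf_counter()
        u5_mean, u5_lo, u5_hi = cov.under5_surface(surface, pop)
        zone_ids = sorted(int(z) for z in np.unique(zones))
        zprops = {z: float(np.nansum(u5_mean[zones == z]) / pop[zones == z].sum())
                  for z in zone_ids}
        census = cov.census_adjustment(pop, zprops, zones)
        uniform = cov.uniform_adjustment(pop, config.un_p)
        per_method = {
            "mbg": {z: (cov.zonal_aggregate(u5_mean, zones)[z],
                        cov.zonal_aggregate(u5_lo, zones)[z],
                        cov.zonal_aggregate(u5_hi, zones)[z]) for z in zone_ids},
            "census": {z: (v, v, v) for z, v in cov.zonal_aggregate(census, zones).items()},
            "un_uniform": {z: (v, v, v)
                           for z, v in cov.zonal_aggregate(uniform, zones).items()},
        }
        cover = {z: config.national_coverage for z in zone_ids}
        estimates = {m: cov.unprotected(d, cover, m) for m, d in per_method.items()}
        table = cov.compare_methods(estimates)
        table.to_csv(out / "coverage.csv", index=False)
        report["coverage"] = {
            "national_under5_mbg": float(np.nansum(u5_mean)),
            "national_under5_un": float(uniform.sum()),
            "national_unprotected_mbg":
                float(np.nansum(u5_mean)) * (1 - config.national_coverage),
            "comparison": table.round(4).to_dict("records"),
        }
        logger.info("coverage in %.1fs", time.perf_counter() - t0)

    io.write_json(report, out / "report.json")
    logger.info("pipeline done in %.1fs", time.perf_counter() - t_all)
    return report
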