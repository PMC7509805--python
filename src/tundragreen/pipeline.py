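"""Pipeline orchestration: stage sequencing, file contracts, manifests.

Runs the full synthetic-archive analysis end to end: generate inputs,
cross-calibrate sensors, build annual NDVI_max tables, propagate
uncertainty through a Monte-Carlo ensemble, detect and classify
trends, correlate greenness with summer warmth, attribute trend
classes to drivers, and validate against field productivity.  Every
stage writes CSV into the run directory; a manifest records the config
hash, master seed, and per-stage row counts so completed stages can be
skipped on rerun.
"""

from __future__ import annotations

import json
import logging
import pathlib

import numpy as np
import pandas as pd

from . import calibration as calib
from . import drivers as drv
from . import trends as trd
from . import validation as val
from .climate import swi_from_monthly_table, synthesize_swi
from .config import RunConfig
from .ensemble import run_ensemble, summarize
from .phenology import build_ndvimax_table
from .synthetic import (annual_ndvimax_truth, generate_sites,
                        simulate_drivers, simulate_field_series,
                        simulate_observations, simulate_temperature_ensemble)

logger = logging.getLogger(__name__)

__all__ = ["run", "REQUIRED_COLUMNS", "read_table"]

REQUIRED_COLUMNS = {
    "observations": ["site_id", "year", "doy", "sensor", "red", "nir", "ndvi"],
    "sites": ["site_id", "zone", "x", "y"],
    "monthly_temperature": ["dataset", "cell", "year", "month", "value"],
    "ndvimax": ["site_id", "year", "ndvimax"],
}


def read_table(path, kind: str) -> pd.DataFrame:
    """Read a pipeline CSV, failing with the file and column named."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS.get(kind, []) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing} for {kind} table")
    return df


def _manifest_path(outdir):
    return pathlib.Path(outdir) / "manifest.json"


def _load_manifest(outdir):
    p = _manifest_path(outdir)
    if p.exists():
        return json.loads(p.read_text())
    return {"stages": {}}


def _save_manifest(outdir, manifest):
    _manifest_path(outdir).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run(config: RunConfig, resume: bool = True) -> pathlib.Path:
    """Execute the configured stages in dependency order.

    Returns the run directory.  With ``resume``, stages whose outputs
    exist under a matching config hash are skipped.
    """
    config.validate()
    g, a = config.generator, config.analysis
    outdir = pathlib.Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _load_manifest(outdir) if resume else {"stages": {}}
    if manifest.get("config_hash") not in (None, config.config_hash()):
        logger.info("config changed; restarting all stages")
        manifest = {"stages": {}}
    manifest["config_hash"] = config.config_hash()
    manifest["seed"] = config.seed
    import tundragreen
    manifest["version"] = getattr(tundragreen, "__version__", "unknown")

    years = range(g.year_start, g.year_end + 1)
    rng_root = np.random.SeedSequence(config.seed)
    seeds = {name: int(s.generate_state(1)[0] % (2**31))
             for name, s in zip(["sites", "temps", "obs", "drivers", "field",
                                 "calib", "ensemble", "analysis"],
                                rng_root.spawn(8))}

    def done(stage):
        return resume and stage in manifest["stages"]

    def mark(stage, **info):
        manifest["stages"][stage] = info
        _save_manifest(outdir, manifest)

    # --- simulate ---------------------------------------------------------
    if not done("simulate"):
        sites = generate_sites(g.n_sites, g.frac_greening, g.frac_browning,
                               seed=seeds["sites"], frac_barren=g.frac_barren)
        temps = simulate_temperature_ensemble(
            g.n_temperature_datasets, g.temperature_cells, years,
            warming_rate=g.warming_rate, seed=seeds["temps"])
        obs, truth = simulate_observations(
            sites, years, noise_sd=g.noise_sd, seed=seeds["obs"],
            swi_anomaly=temps["swi_anomaly_true"].to_dict(),
            interannual_sd=g.interannual_sd, return_truth=True)
        driver_table = simulate_drivers(sites, g.n_predictors, seed=seeds["drivers"])
        anpp = simulate_field_series(truth, "ANPP", g.field_coupling,
                                     seed=seeds["field"],
                                     site_ids=sites["site_id"].iloc[:1])
        sites.to_csv(outdir / "sites.csv", index=False)
        obs.to_csv(outdir / "observations.csv", index=False)
        truth.to_csv(outdir / "ndvimax_truth.csv", index=False)
        temps["monthly"].to_csv(outdir / "monthly_temperature.csv", index=False)
        driver_table.to_csv(outdir / "drivers.csv", index=False)
        anpp.to_csv(outdir / "field_series.csv", index=False)
        mark("simulate", sites=len(sites), observations=len(obs))
    sites = read_table(outdir / "sites.csv", "sites")
    obs = read_table(outdir / "observations.csv", "observations")
    monthly = read_table(outdir / "monthly_temperature.csv", "monthly_temperature")
    driver_table = pd.read_csv(outdir / "drivers.csv")
    field_series = pd.read_csv(outdir / "field_series.csv")

    # --- calibrate --------------------------------------------------------
    if not done("calibrate"):
        rng = np.random.default_rng(seeds["calib"])
        models, reports = {}, []
        present = set(obs["sensor"].unique())
        for sensor in sorted(present - {a.reference_sensor}):
            samples = calib.build_paired_samples(obs, sensor, a.reference_sensor,
                                                 rng, sites=sites)
            if len(samples) < 30:
                logger.warning("only %d paired samples for %s; left uncalibrated",
                               len(samples), sensor)
                continue
            model = calib.fit_calibration(samples, rng, target_sensor=sensor,
                                          reference_sensor=a.reference_sensor,
                                          train_fraction=a.train_fraction)
            models[sensor] = model
            reports.append({"sensor": sensor, **model.fit_metrics})
        calibrated = calib.apply_calibration(obs, models, a.reference_sensor,
                                             sites=sites) if (models and a.calibrate) else obs
        calibrated.to_csv(outdir / "observations_calibrated.csv", index=False)
        pd.DataFrame(reports).to_csv(outdir / "calibration_report.csv", index=False)
        mark("calibrate", sensors=sorted(models), rows=len(calibrated))
    calibrated = read_table(outdir / "observations_calibrated.csv", "observations")

    # --- ndvimax (point estimate at mid-spar) -----------------------------
    if not done("ndvimax"):
        spar_mid = 0.5 * (a.spar_low + a.spar_high)
        table = build_ndvimax_table(calibrated, spar=spar_mid,
                                    window_years=a.window_years,
                                    min_obs=a.min_obs, min_doy_span=a.min_doy_span)
        table.to_csv(outdir / "ndvimax.csv", index=False)
        mark("ndvimax", rows=len(table))
    ndvimax = read_table(outdir / "ndvimax.csv", "ndvimax")

    # --- run-ensemble -----------------------------------------------------
    ens = None
    if "run-ensemble" in config.stages:
        ens = run_ensemble(obs, n_sims=a.n_sims, master_seed=seeds["ensemble"],
                           sites=sites, spar_range=(a.spar_low, a.spar_high),
                           calibrate=a.calibrate, reference_sensor=a.reference_sensor,
                           window_years=a.window_years, min_obs=a.min_obs,
                           min_doy_span=a.min_doy_span,
                           monthly_temperature=monthly,
                           swi_per_year_choice=a.swi_per_year_choice)
        mark("run-ensemble", n_sims=a.n_sims, failures=len(ens.failures))

    # --- trends -----------------------------------------------------------
    retained = trd.screen_sites(ndvimax, a.barren_threshold, a.min_record_years)
    rng_an = np.random.default_rng(seeds["analysis"])
    results = []
    pw = a.prewhiten or None
    for site in retained:
        s = ndvimax[ndvimax["site_id"] == site].set_index("year")["ndvimax"]
        if s.notna().sum() < 4:
            continue
        res = trd.classify_trend(s.to_numpy(), s.index.to_numpy(), alpha=a.alpha,
                                 prewhiten=pw, unit_id=site)
        results.append({"unit_id": site, "period": f"{res.period[0]}-{res.period[1]}",
                        "sen_slope": res.sen_slope, "mk_p": res.mk_p,
                        "class": res.trend_class, "alpha": a.alpha})
    trend_df = pd.DataFrame(results)
    trend_df.to_csv(outdir / "trends.csv", index=False)
    pct = trd.class_percentages(trend_df["class"]) if len(trend_df) else {}
    mark("trends", sites=len(trend_df), **{f"pct_{k}": v for k, v in pct.items()})

    # --- correlate --------------------------------------------------------
    swi_tables = swi_from_monthly_table(monthly)
    swi_real = synthesize_swi(swi_tables, rng_an, per_year=a.swi_per_year_choice)
    swi_mean = swi_real.groupby("year")["swi"].mean()
    zone_anom = trd.aggregate_zone(ndvimax[ndvimax["site_id"].isin(retained)],
                                   sites.set_index("site_id")["zone"])
    arctic = (ndvimax[ndvimax["site_id"].isin(retained)]
              .assign(anom=lambda d: d["ndvimax"]
                      - d.groupby("site_id")["ndvimax"].transform("mean"))
              .groupby("year")["anom"].mean())
    corr_rows = []
    for mode in ("current-year", "two-year-mean", "detrended"):
        r = trd.correlate_ndvi_swi(arctic, swi_mean, mode=mode, unit_id="Arctic")
        corr_rows.append({"unit_id": "Arctic", "mode": mode, "r_s": r.r_s,
                          "p": r.p, "n": r.n, "ok": r.ok})
    pd.DataFrame(corr_rows).to_csv(outdir / "correlations.csv", index=False)
    zone_anom.to_csv(outdir / "zone_anomalies.csv", index=False)
    mark("correlate", rows=len(corr_rows))

    # --- drivers ----------------------------------------------------------
    if "drivers" in config.stages and len(trend_df):
        classes = trend_df.set_index("unit_id")["class"]
        try:
            ds = drv.prepare_dataset(classes, driver_table, rng_an,
                                     corr_threshold=a.corr_threshold)
            fitted = drv.fit_classifier(ds, rng_an, n_estimators=a.rf_trees,
                                        train_fraction=a.train_fraction)
            importance = drv.variable_importance(fitted, rng_an)
            importance.rename("importance").to_csv(outdir / "driver_importance.csv")
            mark("drivers", accuracy=fitted.accuracy,
                 screened_out=list(ds.screened_out))
        except ValueError as exc:
            logger.warning("driver attribution skipped: %s", exc)
            mark("drivers", skipped=str(exc))

    # --- validate ---------------------------------------------------------
    if "validate" in config.stages and len(field_series):
        rows = []
        for (site, kind), gdf in field_series.groupby(["site_id", "kind"]):
            nd = ndvimax[ndvimax["site_id"] == site].set_index("year")["ndvimax"]
            fs = gdf.set_index("year")["value"]
            res = val.validate(nd, fs, mode="current", n_sims=min(a.n_sims, 1000),
                               rng=rng_an, pairing=f"{kind} temporal",
                               subsample_fraction=a.subsample_fraction)
            rows.append({"pairing": res.pairing, "mode": res.mode,
                         "r_s_median": res.r_s_median, "ci_low": res.ci_low,
                         "ci_high": res.ci_high, "n": res.n_units, "ok": res.ok})
        pd.DataFrame(rows).to_csv(outdir / "validation.csv", index=False)
        mark("validate", rows=len(rows))

    # --- report -----------------------------------------------------------
    if ens is not None and "report" in config.stages:
        per_draw_classes = []
        n_eval = min(ens.n_sims, 25)  # trend classification per draw is the slow part
        for i in range(n_eval):
            if i in ens.failures:
                continue
            tbl = ens.draw_table(i)
            keep = trd.screen_sites(tbl, a.barren_threshold, a.min_record_years)
            cls = []
            for site in keep:
                s = tbl[tbl["site_id"] == site].set_index("year")["ndvimax"].dropna()
                if len(s) < 4:
                    continue
                cls.append(trd.classify_trend(s.to_numpy(), s.index.to_numpy(),
                                              alpha=a.alpha, prewhiten=pw).trend_class)
            per_draw_classes.append(cls)
        if len(per_draw_classes) >= 2:
            summary = trd.summarize_classes(per_draw_classes)
            summary.to_csv(outdir / "class_summary.csv", index=False)
            mark("report", draws_summarized=len(per_draw_classes))
    _save_manifest(outdir, manifest)
    return outdir
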