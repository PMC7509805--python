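"""Monte-Carlo propagation of radiometric, calibration, and smoothing
uncertainty.

Each draw independently (1) perturbs every red/NIR reflectance pair by
a uniform factor within its sensor's radiometric bound (±7/5/3% for
L5/L7/L8) and recomputes NDVI, (2) rebuilds the cross-sensor
calibration from the perturbed archive, (3) draws the spline smoothing
parameter uniformly from [0.68, 0.72] and re-estimates every annual
NDVI_max, and (4) resamples the temperature-ensemble SWI.  Statistics
computed on each draw are summarised by their median and the
2.5th/97.5th percentile bounds (the 95% Monte-Carlo confidence
interval).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calibration as calib
from .climate import swi_from_monthly_table, synthesize_swi
from .phenology import build_ndvimax_table
from .synthetic import DEFAULT_SENSORS, bands_to_ndvi

logger = logging.getLogger(__name__)

__all__ = ["SimulationEnsemble", "EnsembleSummary", "perturb_reflectance",
           "run_ensemble", "summarize"]

DEFAULT_BOUNDS = {sid: s.radiometric_bound for sid, s in DEFAULT_SENSORS.items()}
SPAR_RANGE = (0.68, 0.72)


@dataclass
class SimulationEnsemble:
    """Per-draw NDVI_max tables (and optional SWI realizations)."""
    n_sims: int
    master_seed: int
    draw_seeds: tuple
    site_ids: tuple
    years: tuple
    ndvimax: np.ndarray          # (n_sims, n_sites, n_years), NaN where unobserved
    swi: list = field(default_factory=list)   # per-draw SWI tables (may be empty)
    failures: tuple = ()
    provenance: dict = field(default_factory=dict)

    def draw_table(self, i: int) -> pd.DataFrame:
        df = pd.DataFrame(self.ndvimax[i], index=list(self.site_ids),
                          columns=list(self.years))
        out = df.stack().rename("ndvimax").reset_index()
        out.columns = ["site_id", "year", "ndvimax"]
        return out


@dataclass(frozen=True)
class EnsembleSummary:
    statistic: str
    median: object
    ci_low: object
    ci_high: object
    n_draws: int


def perturb_reflectance(obs: pd.DataFrame, sensor_bounds: dict | None = None,
                        rng=None) -> pd.DataFrame:
    """Uniform radiometric perturbation of red and NIR reflectance.

    Each band of each observation is multiplied by an independent
    factor drawn uniformly from [1 - b, 1 + b] where b is the sensor's
    fractional bound; NDVI is recomputed from the perturbed bands.
    """
    if sensor_bounds is None:
        sensor_bounds = DEFAULT_BOUNDS
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    unknown = set(obs["sensor"].unique()) - set(sensor_bounds)
    if unknown:
        raise ValueError(f"no radiometric bound for sensor(s): {sorted(unknown)}")
    for sid, b in sensor_bounds.items():
        if b < 0:
            raise ValueError(f"radiometric bound for {sid} must be >= 0, got {b}")
    out = obs.copy()
    b = obs["sensor"].map(sensor_bounds).to_numpy(dtype=float)
    n = len(obs)
    f_red = 1.0 + b * rng.uniform(-1.0, 1.0, n)
    f_nir = 1.0 + b * rng.uniform(-1.0, 1.0, n)
    out["red"] = obs["red"].to_numpy() * f_red
    out["nir"] = obs["nir"].to_numpy() * f_nir
    out["ndvi"] = bands_to_ndvi(out["red"].to_numpy(), out["nir"].to_numpy())
    return out


def _draw_seeds(master_seed: int, n_sims: int) -> np.ndarray:
    """Counter-based per-draw seeds from one master seed (below 2**31)."""
    ss = np.random.SeedSequence(master_seed)
    return np.array([int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_sims)])


def run_ensemble(obs: pd.DataFrame, n_sims: int = 1000, master_seed: int = 0,
                 sites: pd.DataFrame | None = None,
                 sensor_bounds: dict | None = None,
                 spar_range: tuple = SPAR_RANGE,
                 calibrate: bool = True, reference_sensor: str = "L7",
                 window_years: int = 17, min_obs: int = 10,
                 min_doy_span: float = 30.0,
                 monthly_temperature: pd.DataFrame | None = None,
                 swi_per_year_choice: bool = False,
                 min_calibration_samples: int = 30) -> SimulationEnsemble:
    """End-to-end Monte-Carlo ensemble of annual NDVI_max time series.

    Every draw perturbs reflectance within sensor bounds, optionally
    refits and applies the cross-sensor calibration, draws spar
    uniformly from ``spar_range``, rebuilds the per-site annual NDVI_max
    table, and (when a monthly temperature ensemble is supplied)
    resamples a synthetic SWI realization.  Draws are seeded
    independently from the master seed and a failed draw is recorded
    without aborting the ensemble.
    """
    if n_sims < 2:
        raise ValueError(f"n_sims must be >= 2, got {n_sims}")
    seeds = _draw_seeds(master_seed, n_sims)
    site_ids = tuple(sorted(obs["site_id"].unique()))
    years = tuple(range(int(obs["year"].min()), int(obs["year"].max()) + 1))
    site_pos = {s: i for i, s in enumerate(site_ids)}
    year_pos = {y: i for i, y in enumerate(years)}
    values = np.full((n_sims, len(site_ids), len(years)), np.nan)
    swi_draws = []
    swi_tables = None
    if monthly_temperature is not None:
        swi_tables = swi_from_monthly_table(monthly_temperature)

    sensors_present = set(obs["sensor"].unique())
    failures = []
    for i in range(n_sims):
        rng = np.random.default_rng(seeds[i])
        try:
            perturbed = perturb_reflectance(obs, sensor_bounds, rng)
            if calibrate and reference_sensor in sensors_present and len(sensors_present) > 1:
                models = {}
                for sensor in sorted(sensors_present - {reference_sensor}):
                    samples = calib.build_paired_samples(
                        perturbed, sensor, reference_sensor, rng, sites=sites)
                    if len(samples) >= min_calibration_samples:
                        models[sensor] = calib.fit_calibration(
                            samples, rng, target_sensor=sensor,
                            reference_sensor=reference_sensor,
                            min_samples=min_calibration_samples)
                    else:
                        logger.info("draw %d: %d paired samples for %s; "
                                    "sensor left uncalibrated", i, len(samples), sensor)
                if models:
                    perturbed = calib.apply_calibration(
                        perturbed, models, reference_sensor, sites=sites)
            spar = float(rng.uniform(*spar_range))
            table = build_ndvimax_table(perturbed, spar=spar,
                                        window_years=window_years,
                                        min_obs=min_obs, min_doy_span=min_doy_span)
            si = table["site_id"].map(site_pos).to_numpy()
            yi = table["year"].map(year_pos).to_numpy()
            values[i, si, yi] = table["ndvimax"].to_numpy()
            if swi_tables is not None:
                swi_draws.append(synthesize_swi(swi_tables, rng,
                                                per_year=swi_per_year_choice))
        except Exception:  # draw-level fault tolerance
            logger.exception("Monte-Carlo draw %d failed", i)
            failures.append(i)
    if failures:
        logger.warning("%d/%d draws failed", len(failures), n_sims)
    return SimulationEnsemble(
        n_sims=n_sims, master_seed=master_seed, draw_seeds=tuple(int(s) for s in seeds),
        site_ids=site_ids, years=years, ndvimax=values, swi=swi_draws,
        failures=tuple(failures),
        provenance={"spar_range": spar_range, "calibrate": calibrate,
                    "window_years": window_years})


def summarize(draw_values, statistic=None, name: str = "statistic") -> EnsembleSummary:
    """Median and 95% percentile CI of a statistic across ensemble draws.

    ``draw_values`` is either an iterable of per-draw values (scalars or
    equal-length vectors) or a SimulationEnsemble, in which case
    ``statistic`` maps each per-draw NDVI_max table to a value.
    Percentiles use linear interpolation between order statistics.
    """
    if isinstance(draw_values, SimulationEnsemble):
        ens = draw_values
        ok = [i for i in range(ens.n_sims) if i not in set(ens.failures)]
        vals = [statistic(ens.draw_table(i)) for i in ok]
    else:
        vals = [statistic(v) for v in draw_values] if statistic else list(draw_values)
    if len(vals) < 2:
        raise ValueError(f"need >= 2 successful draws to summarize, got {len(vals)}")
    arr = np.asarray(vals, dtype=float)
    med = np.median(arr, axis=0)
    lo = np.percentile(arr, 2.5, axis=0)
    hi = np.percentile(arr, 97.5, axis=0)
    if arr.ndim == 1:
        med, lo, hi = float(med), float(lo), float(hi)
    return EnsembleSummary(statistic=name, median=med, ci_low=lo, ci_high=hi,
                           n_draws=len(vals))
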