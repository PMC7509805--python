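"""Synthetic multi-sensor tundra reflectance archive with known ground truth.

Emulates the statistical structure of a sparse Landsat-style record over
Arctic tundra: seasonal NDVI trajectories with a summer peak, long-term
greening/browning trends at configurable fractions of sites, systematic
inter-sensor NDVI offsets, multiplicative radiometric noise, irregular
clear-sky sampling whose per-summer density grows through the record,
temperature-coupled interannual anomalies, environmental driver
covariates with known class effects, and field-productivity series with
a prescribed rank coupling to true greenness.  Every latent quantity a
downstream stage estimates (trend class, slope, peak day-of-year,
NDVI-temperature coupling) is stored so recovery can be tested.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st

logger = logging.getLogger(__name__)

ZONES = ("High", "Low", "Oro")
SUMMER_DOY = (152, 243)  # June 1 - Aug 31 (non-leap)

__all__ = [
    "SensorModel",
    "DEFAULT_SENSORS",
    "DEFAULT_DENSITY_SCHEDULE",
    "generate_sites",
    "seasonal_ndvi",
    "annual_ndvimax_truth",
    "apply_sensor_offset",
    "ndvi_to_bands",
    "bands_to_ndvi",
    "simulate_observations",
    "simulate_temperature_ensemble",
    "simulate_drivers",
    "simulate_field_series",
    "write_world",
]


@dataclass(frozen=True)
class SensorModel:
    """One satellite sensor: its NDVI bias and radiometric uncertainty.

    ``ndvi_offset`` is the additive systematic NDVI bias relative to the
    reference sensor (L7, offset 0).  ``radiometric_bound`` is the
    fractional reflectance perturbation bound used by the Monte-Carlo
    stage (±7/5/3% for L5/L7/L8).
    """
    sensor_id: str
    ndvi_offset: float
    radiometric_bound: float
    active_years: tuple

    def __post_init__(self):
        if not (0 < self.radiometric_bound <= 0.1):
            raise ValueError(
                f"radiometric_bound for {self.sensor_id} must be in (0, 0.1], "
                f"got {self.radiometric_bound}")


DEFAULT_SENSORS = {
    "L5": SensorModel("L5", ndvi_offset=-0.02, radiometric_bound=0.07, active_years=(1984, 2011)),
    "L7": SensorModel("L7", ndvi_offset=0.0, radiometric_bound=0.05, active_years=(1999, 2016)),
    "L8": SensorModel("L8", ndvi_offset=+0.02, radiometric_bound=0.03, active_years=(2013, 2016)),
}

# Expected clear-sky summer scenes per site: anchors matching observed medians
# of 0, 2, 4 and 7 scenes in 1985, 1995, 2005, 2015; linear in between.
_DENSITY_ANCHORS = [(1984, 0.2), (1985, 0.3), (1995, 2.0), (2005, 4.0), (2015, 7.0), (2016, 7.3)]


def DEFAULT_DENSITY_SCHEDULE(year):
    years = [a[0] for a in _DENSITY_ANCHORS]
    vals = [a[1] for a in _DENSITY_ANCHORS]
    return float(np.interp(year, years, vals))


_ZONE_BASE_RANGE = {"High": (0.12, 0.35), "Low": (0.30, 0.65), "Oro": (0.25, 0.60)}


def generate_sites(n_sites: int, frac_greening: float = 0.37, frac_browning: float = 0.05,
                   seed: int = 0, frac_barren: float = 0.05,
                   domain_km: float = 1000.0,
                   slope_range: tuple = (0.001, 0.003),
                   coupling_range: tuple = (0.002, 0.008)) -> pd.DataFrame:
    """Sampling-site truth table.

    Trend classes are assigned to exact rounded counts of the requested
    fractions and shuffled across sites.  A fixed fraction of sites is
    barren (base NDVI_max < 0.10) to exercise downstream screening.
    Zones stripe the planar domain north to south: High Arctic at large
    y, Low Arctic in the middle, Oro Arctic at small y.
    """
    for name, val in [("frac_greening", frac_greening), ("frac_browning", frac_browning),
                      ("frac_barren", frac_barren)]:
        if not 0 <= val <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {val}")
    if frac_greening + frac_browning > 1:
        raise ValueError(
            f"frac_greening + frac_browning must be <= 1, got "
            f"{frac_greening} + {frac_browning}")
    if n_sites < 1:
        raise ValueError(f"n_sites must be >= 1, got {n_sites}")

    rng = np.random.default_rng(seed)
    n_green = int(round(n_sites * frac_greening))
    n_brown = int(round(n_sites * frac_browning))
    n_green = min(n_green, n_sites)
    n_brown = min(n_brown, n_sites - n_green)
    classes = np.array(["greening"] * n_green + ["browning"] * n_brown
                       + ["none"] * (n_sites - n_green - n_brown))
    rng.shuffle(classes)

    x = rng.uniform(0, domain_km, n_sites)
    y = rng.uniform(0, domain_km, n_sites)
    zone = np.where(y > 2 * domain_km / 3, "High",
                    np.where(y > domain_km / 4, "Low", "Oro"))

    lo = np.array([_ZONE_BASE_RANGE[z][0] for z in zone])
    hi = np.array([_ZONE_BASE_RANGE[z][1] for z in zone])
    base = rng.uniform(lo, hi)
    barren = np.zeros(n_sites, dtype=bool)
    n_barren = int(round(n_sites * frac_barren))
    if n_barren:
        idx = rng.choice(n_sites, size=n_barren, replace=False)
        barren[idx] = True
        base[idx] = rng.uniform(0.02, 0.08, n_barren)

    slope_mag = rng.uniform(slope_range[0], slope_range[1], n_sites)
    sign = np.where(classes == "greening", 1.0, np.where(classes == "browning", -1.0, 0.0))
    slope = slope_mag * sign

    return pd.DataFrame({
        "site_id": [f"s{i:05d}" for i in range(n_sites)],
        "zone": zone,
        "x": x,
        "y": y,
        "trend_class_true": classes,
        "trend_slope_true": slope,
        "peak_doy_true": rng.uniform(197, 213, n_sites),
        "base_ndvimax": base,
        "temp_coupling": rng.uniform(coupling_range[0], coupling_range[1], n_sites),
        "barren_flag": barren,
    })


def seasonal_ndvi(doy, peak_doy, annual_max, winter_ndvi=None,
                  half_width: float = 25.0, steepness: float = 7.0):
    """Bell-shaped seasonal NDVI trajectory, exact at the peak.

    A symmetric double-logistic (green-up and senescence inflections at
    peak_doy ± half_width) normalised so the curve equals ``annual_max``
    exactly at ``peak_doy`` and relaxes to a winter floor far from it.
    """
    doy = np.asarray(doy, dtype=float)
    annual_max = np.asarray(annual_max, dtype=float)
    if winter_ndvi is None:
        winter_ndvi = np.maximum(0.02, 0.15 * annual_max)
    u = (doy - np.asarray(peak_doy, dtype=float))

    def bump(v):
        up = 1.0 / (1.0 + np.exp(-(v + half_width) / steepness))
        down = 1.0 / (1.0 + np.exp((v - half_width) / steepness))
        return up * down

    g = bump(u) / bump(np.zeros_like(u))
    return winter_ndvi + (annual_max - winter_ndvi) * g


def annual_ndvimax_truth(sites: pd.DataFrame, years, swi_anomaly=None,
                         interannual_sd: float = 0.0, seed: int | None = None) -> pd.DataFrame:
    """True annual NDVI_max per site and year.

    value = base + slope * (year - mid-record year)
          + temp_coupling * SWI anomaly (+ optional idiosyncratic noise).
    ``swi_anomaly`` maps year -> degC anomaly shared by all sites.
    """
    years = np.asarray(list(years), dtype=int)
    mid = years.mean()
    anom = np.zeros(years.size)
    if swi_anomaly is not None:
        anom = np.array([float(swi_anomaly.get(int(y), 0.0)) for y in years])
    base = sites["base_ndvimax"].to_numpy()[:, None]
    slope = sites["trend_slope_true"].to_numpy()[:, None]
    coup = sites["temp_coupling"].to_numpy()[:, None]
    vals = base + slope * (years - mid)[None, :] + coup * anom[None, :]
    if interannual_sd > 0:
        rng = np.random.default_rng(seed)
        vals = vals + rng.normal(0, interannual_sd, vals.shape)
    vals = np.clip(vals, -1.0, 1.0)
    out = pd.DataFrame(vals, index=sites["site_id"], columns=years)
    out = out.stack().rename("ndvimax_true").reset_index()
    out.columns = ["site_id", "year", "ndvimax_true"]
    return out


def ndvi_to_bands(ndvi, brightness):
    """Red/NIR reflectance pair realising a given NDVI at a given total
    brightness (red + NIR)."""
    ndvi = np.asarray(ndvi, dtype=float)
    brightness = np.asarray(brightness, dtype=float)
    nir = brightness * (1.0 + ndvi) / 2.0
    red = brightness * (1.0 - ndvi) / 2.0
    return red, nir


def bands_to_ndvi(red, nir):
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    return (nir - red) / (nir + red)


def apply_sensor_offset(ndvi, sensor: SensorModel):
    """Additive systematic NDVI bias of a sensor relative to the reference."""
    return np.clip(np.asarray(ndvi, dtype=float) + sensor.ndvi_offset, -0.99, 0.99)


def simulate_observations(sites: pd.DataFrame, years, sensors=None,
                          density_schedule=None, noise_sd: float = 0.02,
                          seed: int = 0, swi_anomaly=None,
                          interannual_sd: float = 0.01,
                          brightness_range: tuple = (0.25, 0.45),
                          return_truth: bool = False):
    """Clear-sky summer reflectance observations for every site and year.

    Per site-year the number of clear-sky scenes is Poisson with mean
    given by ``density_schedule(year)``; acquisition days are uniform
    over June 1 - Aug 31.  Each observation samples the site's seasonal
    curve for that year, applies multiplicative lognormal band noise
    (fractional sd ``noise_sd``), the acquiring sensor's additive NDVI
    offset, and converts to a red/NIR pair at a random total brightness.

    Returns an observation table (site_id, year, doy, date, sensor,
    red, nir, ndvi); with ``return_truth`` also the true annual
    NDVI_max table used.
    """
    if sensors is None:
        sensors = DEFAULT_SENSORS
    if density_schedule is None:
        density_schedule = DEFAULT_DENSITY_SCHEDULE
    years = np.asarray(list(years), dtype=int)
    for year in years:
        if not any(s.active_years[0] <= year <= s.active_years[1] for s in sensors.values()):
            raise ValueError(f"no sensor active in year {year}")
    lam = np.array([density_schedule(y) for y in years], dtype=float)
    if (lam < 0).any():
        raise ValueError("density_schedule must be non-negative")

    rng = np.random.default_rng(seed)
    if sites.empty:
        logger.warning("empty site collection; returning no observations")
        obs = pd.DataFrame(columns=["site_id", "year", "doy", "date", "sensor",
                                    "red", "nir", "ndvi"])
        return (obs, annual_ndvimax_truth(sites, years)) if return_truth else obs

    truth = annual_ndvimax_truth(sites, years, swi_anomaly=swi_anomaly,
                                 interannual_sd=interannual_sd,
                                 seed=rng.integers(2**31))
    truth_mat = truth.pivot(index="site_id", columns="year", values="ndvimax_true") \
                     .loc[sites["site_id"]]

    n_sites = len(sites)
    counts = rng.poisson(lam[None, :], size=(n_sites, years.size))
    total = int(counts.sum())
    # expand (site, year) indices according to counts
    flat = counts.ravel()
    pair_idx = np.repeat(np.arange(flat.size), flat)
    si = pair_idx // years.size
    yi = pair_idx % years.size

    doy = rng.integers(SUMMER_DOY[0], SUMMER_DOY[1] + 1, total)
    peak = sites["peak_doy_true"].to_numpy()[si]
    amax = truth_mat.to_numpy()[si, yi]
    ndvi_true = seasonal_ndvi(doy, peak, amax)

    # multiplicative lognormal band noise -> NDVI perturbation
    if noise_sd > 0:
        f_red = np.exp(rng.normal(0, noise_sd, total))
        f_nir = np.exp(rng.normal(0, noise_sd, total))
    else:
        f_red = f_nir = np.ones(total)
    # apply noise to provisional unit-brightness bands, then recompute NDVI
    red0, nir0 = ndvi_to_bands(ndvi_true, 1.0)
    ndvi_noisy = bands_to_ndvi(red0 * f_red, nir0 * f_nir)

    # sensor assignment: uniform among sensors active that year
    sensor_ids = list(sensors)
    active = np.array([[s.active_years[0] <= y <= s.active_years[1] for s in sensors.values()]
                       for y in years])  # (years, sensors)
    u = rng.random(total)
    row_active = active[yi]
    cum = np.cumsum(row_active, axis=1)
    n_active = cum[:, -1]
    pick = (u * n_active).astype(int) + 1
    sensor_choice = (cum >= pick[:, None]).argmax(axis=1)
    chosen = np.array(sensor_ids)[sensor_choice]
    offsets = np.array([sensors[s].ndvi_offset for s in sensor_ids])[sensor_choice]

    ndvi_obs = np.clip(ndvi_noisy + offsets, -0.99, 0.99)
    brightness = rng.uniform(*brightness_range, total)
    red, nir = ndvi_to_bands(ndvi_obs, brightness)

    obs = pd.DataFrame({
        "site_id": sites["site_id"].to_numpy()[si],
        "year": years[yi],
        "doy": doy,
        "sensor": chosen,
        "red": red,
        "nir": nir,
        "ndvi": bands_to_ndvi(red, nir),
    })
    obs["date"] = pd.to_datetime(obs["year"].astype(str), format="%Y") \
        + pd.to_timedelta(obs["doy"] - 1, unit="D")
    obs["date"] = obs["date"].dt.strftime("%Y-%m-%d")
    obs = obs[["site_id", "year", "doy", "date", "sensor", "red", "nir", "ndvi"]]
    if return_truth:
        return obs, truth
    return obs


# Typical tundra monthly mean air temperatures (degC), Jan..Dec.
DEFAULT_CLIMATOLOGY = (-25.0, -24.0, -18.0, -10.0, -4.0, 6.0, 11.0, 9.0, 3.0,
                       -6.0, -16.0, -22.0)
_SUMMER_MONTHS = (6, 7, 8)


def simulate_temperature_ensemble(n_datasets: int = 5, cells: int = 10, years=range(1985, 2017),
                                  warming_rate: float = 1.5625, seed: int = 0,
                                  climatology=DEFAULT_CLIMATOLOGY,
                                  year_anomaly_sd: float = 0.7,
                                  dataset_offset_sd: float = 0.3,
                                  dataset_noise_sd: float = 0.15,
                                  cell_offset_sd: float = 1.0):
    """Ensemble of gridded monthly-temperature data sets sharing one climate.

    The warming signal (``warming_rate``, degC of summer-warmth-index
    per decade) is spread equally over June-August; a shared interannual
    anomaly couples all data sets (and, via ``temp_coupling``, the NDVI
    generator); each data set adds its own systematic offset and noise.

    Returns a dict with ``monthly`` (long table: dataset, cell, year,
    month, value), ``swi_anomaly_true`` (year -> shared summer anomaly,
    degC of SWI), and ``swi_trend_true`` (degC of SWI per year).
    """
    if n_datasets < 2:
        raise ValueError(f"n_datasets must be >= 2, got {n_datasets}")
    years = np.asarray(list(years), dtype=int)
    rng = np.random.default_rng(seed)
    clim = np.asarray(climatology, dtype=float)
    per_month_trend = warming_rate / 10.0 / len(_SUMMER_MONTHS)

    year_anom = rng.normal(0, year_anomaly_sd, years.size) if year_anomaly_sd > 0 \
        else np.zeros(years.size)
    cell_off = rng.normal(0, cell_offset_sd, cells) if cell_offset_sd > 0 else np.zeros(cells)
    ds_off = rng.normal(0, dataset_offset_sd, n_datasets) if dataset_offset_sd > 0 \
        else np.zeros(n_datasets)

    rows = []
    months = np.arange(1, 13)
    is_summer = np.isin(months, _SUMMER_MONTHS)
    for d in range(n_datasets):
        for c in range(cells):
            base = clim[None, :] + cell_off[c] + ds_off[d]
            t = base + np.zeros((years.size, 12))
            t[:, is_summer] += (per_month_trend * (years - years[0]))[:, None]
            t[:, is_summer] += (year_anom / len(_SUMMER_MONTHS))[:, None]
            if dataset_noise_sd > 0:
                t = t + rng.normal(0, dataset_noise_sd, t.shape)
            df = pd.DataFrame(t, index=years, columns=months)
            df = df.stack().rename("value").reset_index()
            df.columns = ["year", "month", "value"]
            df.insert(0, "cell", c)
            df.insert(0, "dataset", f"d{d}")
            rows.append(df)
    monthly = pd.concat(rows, ignore_index=True)
    swi_anom = pd.Series(year_anom, index=years)
    return {"monthly": monthly,
            "swi_anomaly_true": swi_anom,
            "swi_trend_true": warming_rate / 10.0}


DEFAULT_CLASS_EFFECTS = {
    "delta_swi": {"greening": 1.5, "none": 0.0, "browning": -1.5},
    "soil_temp_trend": {"greening": 1.0, "none": 0.0, "browning": -1.0},
    "soil_moisture_trend": {"greening": 0.8, "none": 0.0, "browning": -0.8},
    "elevation": {"greening": 0.8, "none": 0.0, "browning": -0.5},
}


def simulate_drivers(sites: pd.DataFrame, n_predictors: int = 20,
                     informative_map: dict | None = None, seed: int = 0,
                     correlated_pair: bool = True) -> pd.DataFrame:
    """Per-site driver covariate table with known class-dependent effects.

    Informative predictors get a class-dependent mean shift (unit
    standard deviation); the remainder are pure noise.  By default one
    predictor is duplicated with small noise (r > 0.9) so correlation
    screening always has something to remove.
    """
    if informative_map is None:
        informative_map = DEFAULT_CLASS_EFFECTS
    n_extra = 1 if (correlated_pair and informative_map) else 0
    if n_predictors < len(informative_map) + n_extra:
        raise ValueError(
            f"n_predictors ({n_predictors}) must be >= number of informative "
            f"predictors ({len(informative_map) + n_extra})")
    rng = np.random.default_rng(seed)
    n = len(sites)
    cls = sites["trend_class_true"].to_numpy()
    out = {"site_id": sites["site_id"].to_numpy()}
    for name, effects in informative_map.items():
        shift = np.array([effects.get(c, 0.0) for c in cls])
        out[name] = shift + rng.normal(0, 1, n)
    if n_extra:
        first = next(iter(informative_map))
        out[f"{first}_dup"] = out[first] + rng.normal(0, 0.3, n)
    n_noise = n_predictors - len(informative_map) - n_extra
    for k in range(n_noise):
        out[f"noise_{k:02d}"] = rng.normal(0, 1, n)
    return pd.DataFrame(out)


_SPEARMAN_TO_PEARSON = lambda r_s: 2.0 * math.sin(math.pi * r_s / 6.0)

_FIELD_TRANSFORMS = {
    # strictly increasing maps from a latent z-score to field units
    "ANPP": lambda z: 60.0 * np.exp(0.35 * z),          # g dry matter m-2 yr-1
    "RWI": lambda z: np.exp(0.2 * z) / np.mean(np.exp(0.2 * z)),  # unitless, mean 1
    "GPP": lambda z: 300.0 * np.exp(0.4 * z),           # g C m-2 yr-1
}


def simulate_field_series(ndvimax_truth: pd.DataFrame, kind: str,
                          coupling: float, seed: int = 0,
                          site_ids=None, spatial: bool | None = None) -> pd.DataFrame:
    """Field-productivity series rank-coupled to true NDVI_max.

    Uses a Gaussian copula: the latent normal score of each true
    NDVI_max value is mixed with independent noise at the Pearson level
    corresponding to the requested Spearman ``coupling``, then pushed
    through a strictly increasing transform into field units (ANPP
    g m-2 yr-1, RWI unitless with mean 1, GPP gC m-2 yr-1).  The
    realised rank correlation converges to ``coupling`` as the series
    lengthens.

    ANPP and RWI are coupled through time within each site.  GPP (or
    ``spatial=True``) is coupled across sites: each site's productivity
    level tracks the rank of its median NDVI_max among sites, with mild
    independent interannual variation, mirroring a tower network whose
    spatial pattern is compared against greenness.
    """
    if not -1 <= coupling <= 1:
        raise ValueError(f"coupling must be in [-1, 1], got {coupling}")
    if kind not in _FIELD_TRANSFORMS:
        raise ValueError(f"kind must be one of {sorted(_FIELD_TRANSFORMS)}, got {kind!r}")
    if spatial is None:
        spatial = kind == "GPP"
    rng = np.random.default_rng(seed)
    df = ndvimax_truth
    if site_ids is not None:
        df = df[df["site_id"].isin(site_ids)]
    rho = _SPEARMAN_TO_PEARSON(coupling)
    if spatial:
        med = df.groupby("site_id", sort=True)["ndvimax_true"].median()
        m = len(med)
        ranks = med.rank(method="average").to_numpy()
        z_site = _st.norm.ppf(ranks / (m + 1.0))
        if abs(coupling) == 1.0:
            z = math.copysign(1.0, coupling) * z_site
        else:
            z = rho * z_site + math.sqrt(max(0.0, 1 - rho ** 2)) * rng.normal(0, 1, m)
        base = _FIELD_TRANSFORMS[kind](z)
        out = []
        for level, (site, g) in zip(base, df.groupby("site_id", sort=True)):
            jitter = np.exp(rng.normal(0, 0.05, len(g)))
            out.append(pd.DataFrame({"site_id": site, "year": g["year"].to_numpy(),
                                     "kind": kind, "value": level * jitter}))
        return pd.concat(out, ignore_index=True)
    out = []
    for site, g in df.groupby("site_id", sort=True):
        v = g["ndvimax_true"].to_numpy(dtype=float)
        n = v.size
        # normal scores of the true series (rank-based -> exact copula margin)
        ranks = pd.Series(v).rank(method="average").to_numpy()
        z_ndvi = _st.norm.ppf(ranks / (n + 1.0))
        if abs(coupling) == 1.0:
            z = math.copysign(1.0, coupling) * z_ndvi
        else:
            z = rho * z_ndvi + math.sqrt(max(0.0, 1 - rho ** 2)) * rng.normal(0, 1, n)
        vals = _FIELD_TRANSFORMS[kind](z)
        out.append(pd.DataFrame({"site_id": site, "year": g["year"].to_numpy(),
                                 "kind": kind, "value": vals}))
    return pd.concat(out, ignore_index=True)


def write_world(outdir, sites=None, observations=None, monthly_temperature=None,
                drivers=None, field_series=None, seed=None, params=None):
    """Write generator outputs as CSV plus a metadata YAML recording the seed."""
    import pathlib
    import yaml
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in [("sites", sites), ("observations", observations),
                     ("monthly_temperature", monthly_temperature),
                     ("drivers", drivers), ("field_series", field_series)]:
        if df is not None:
            path = outdir / f"{name}.csv"
            df.to_csv(path, index=False)
            written[name] = {"path": path.name, "rows": int(len(df))}
    meta = {"seed": seed, "files": written, "params": params or {}}
    with open(outdir / "metadata.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return outdir
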