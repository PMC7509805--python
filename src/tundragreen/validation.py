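"""Validation of satellite greenness against field plant productivity.

Annual NDVI_max is compared with graminoid ANPP (temporal), shrub
ring-width chronologies (temporal, usually detrended), and flux-tower
GPP (spatial, across sites) using Spearman rank correlations inside a
Monte-Carlo resampling scheme: each simulation perturbs both series
and recomputes the correlation on a random 90% subset of years (or
sites) drawn without replacement.  The reported estimate is the median
r_s with a 2.5th/97.5th-percentile confidence interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["ValidationResult", "validate"]


@dataclass(frozen=True)
class ValidationResult:
    pairing: str
    mode: str
    r_s_median: float
    ci_low: float
    ci_high: float
    n_sims: int
    n_units: int
    ok: bool = True


def _prepare_mode(ndvi: pd.Series, other: pd.Series, mode: str):
    """Align two year-indexed series under a comparison mode.

    ``lagged-k`` replaces NDVI_y with the mean over years y-1 .. y-k
    (k >= 1); ``multi-year-mean-k`` with the mean over y .. y-k+1;
    ``detrended`` uses OLS-on-year residuals of both series.
    """
    ndvi = ndvi.dropna()
    other = other.dropna()
    if mode.startswith("lagged-") or mode.startswith("multi-year-mean-"):
        if mode.startswith("lagged-"):
            k = int(mode.split("-")[-1])
            lags = range(1, k + 1)
        else:
            k = int(mode.split("-")[-1])
            lags = range(0, k)
        stacked = pd.concat([ndvi.reindex(other.index - lag).set_axis(other.index)
                             for lag in lags], axis=1)
        ndvi = stacked.mean(axis=1, skipna=False).dropna()
    years = ndvi.index.intersection(other.index)
    x = ndvi.loc[years].to_numpy(dtype=float)
    y = other.loc[years].to_numpy(dtype=float)
    if mode == "detrended" and len(years) > 2:
        yr = np.asarray(years, dtype=float)
        x = x - np.polyval(np.polyfit(yr, x, 1), yr)
        y = y - np.polyval(np.polyfit(yr, y, 1), yr)
    return x, y, len(years)


def validate(ndvimax: pd.Series, field_series: pd.Series, mode: str = "current",
             n_sims: int = 1000, rng=None, pairing: str = "",
             ndvi_noise_sd: float = 0.01, field_noise_frac: float = 0.05,
             subsample_fraction: float = 0.9,
             min_overlap: int = 8, spatial: bool = False,
             min_sites: int = 5) -> ValidationResult:
    """Monte-Carlo Spearman correlation between NDVI_max and a field metric.

    Temporal pairings index both series by year; the spatial (GPP)
    pairing indexes both by site (one median value per site).  Each
    simulation adds normal noise to NDVI_max (sd ``ndvi_noise_sd``,
    NDVI units), multiplies the field series by lognormal noise of
    fractional sd ``field_noise_frac``, subsamples
    floor(subsample_fraction * n) units without replacement, and
    computes r_s.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    mode_key = "current" if spatial else mode
    if mode_key in ("current", "detrended"):
        x, y, n = _prepare_mode(ndvimax, field_series, mode_key)
    else:
        x, y, n = _prepare_mode(ndvimax, field_series, mode)
    floor = min_sites if spatial else min_overlap
    if n < floor:
        logger.warning("only %d overlapping units for %s/%s; validation skipped",
                       n, pairing, mode)
        return ValidationResult(pairing, mode, float("nan"), float("nan"),
                                float("nan"), 0, n, ok=False)
    k = int(np.floor(subsample_fraction * n))
    draws = np.empty(n_sims)
    noiseless = ndvi_noise_sd == 0 and field_noise_frac == 0
    for i in range(n_sims):
        xi = x + (rng.normal(0, ndvi_noise_sd, n) if ndvi_noise_sd > 0 else 0.0)
        yi = y * (np.exp(rng.normal(0, field_noise_frac, n))
                  if field_noise_frac > 0 else 1.0)
        idx = rng.choice(n, size=k, replace=False) if k < n else np.arange(n)
        r, _ = stats.spearmanr(xi[idx], yi[idx])
        draws[i] = r
    if noiseless and k == n:
        pass  # degenerate case: identical draws, zero-width CI
    return ValidationResult(
        pairing=pairing, mode=mode,
        r_s_median=float(np.median(draws)),
        ci_low=float(np.percentile(draws, 2.5)),
        ci_high=float(np.percentile(draws, 97.5)),
        n_sims=n_sims, n_units=n, ok=True)
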