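"""Trend detection, classification, and summary statistics.

Implements the rank-based machinery used to label sites as greening or
browning: the Mann-Kendall test for a monotonic trend (tie-corrected,
with an exact null distribution for short series), the Theil-Sen slope,
trend-free pre-whitening for serially correlated series, NDVI_max-SWI
rank correlations, zone-level aggregation, class-percentage summaries
with greening:browning ratios, and the fire-rotation arithmetic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

TREND_CLASSES = ("browning", "none", "greening")

__all__ = [
    "MannKendallResult",
    "TrendResult",
    "CorrelationResult",
    "mann_kendall",
    "theil_sen",
    "prewhiten_series",
    "classify_trend",
    "screen_sites",
    "correlate_ndvi_swi",
    "aggregate_zone",
    "class_percentages",
    "greening_browning_ratio",
    "summarize_classes",
    "fire_rotation",
]


@dataclass(frozen=True)
class MannKendallResult:
    s: float
    tau: float
    var_s: float
    p: float
    n: int
    method: str  # "exact" or "normal"


@dataclass(frozen=True)
class TrendResult:
    unit_id: object
    period: tuple
    sen_slope: float
    mk_p: float
    trend_class: str
    alpha_used: float


@dataclass(frozen=True)
class CorrelationResult:
    unit_id: object
    r_s: float
    p: float
    mode: str
    n: int
    ok: bool = True


@lru_cache(maxsize=32)
def _exact_s_distribution(n: int) -> np.ndarray:
    """Null distribution of the MK S statistic for n distinct values.

    Counts permutations by inversion number (the classic recursion for
    Mahonian numbers); S = n(n-1)/2 - 2 * inversions.  Returns an array
    ``counts`` where counts[i] is the number of permutations with i
    inversions, i = 0 .. n(n-1)/2.
    """
    counts = np.array([1], dtype=float)
    for k in range(2, n + 1):
        # convolve with a run of k ones: permutations of k items add 0..k-1 inversions
        counts = np.convolve(counts, np.ones(k))
    return counts


def _exact_p(s: int, n: int) -> float:
    counts = _exact_s_distribution(n)
    total = counts.sum()
    m = n * (n - 1) // 2
    # inversions i correspond to S = m - 2i; S >= |s| <=> i <= (m - |s|) / 2
    i_max = (m - abs(s)) // 2
    tail = counts[: int(i_max) + 1].sum() / total
    if s == 0:
        return 1.0
    return min(1.0, 2.0 * tail)


def mann_kendall(values, times=None) -> MannKendallResult:
    """Mann-Kendall test for a monotonic trend.

    S is the sum over ordered pairs of sign(x_j - x_i); its variance is
    tie-corrected.  For n <= 10 with no ties in values or times the exact
    permutation null distribution is used; otherwise a normal
    approximation with continuity correction.

    Missing values are dropped (pairs with their time stamps).
    """
    x = np.asarray(values, dtype=float)
    if times is None:
        t = np.arange(x.size, dtype=float)
    else:
        t = np.asarray(times, dtype=float)
    keep = np.isfinite(x) & np.isfinite(t)
    x, t = x[keep], t[keep]
    order = np.argsort(t, kind="stable")
    x, t = x[order], t[order]
    n = x.size
    if n < 4:
        raise ValueError(f"Mann-Kendall requires >= 4 non-missing values, got {n}")

    dx = np.sign(x[None, :] - x[:, None])
    dt = np.sign(t[None, :] - t[:, None])
    iu = np.triu_indices(n, k=1)
    s = float(np.sum(dx[iu] * dt[iu]))

    # tie-corrected variance
    def _tie_term(v):
        _, cnt = np.unique(v, return_counts=True)
        cnt = cnt[cnt > 1]
        return np.sum(cnt * (cnt - 1) * (2 * cnt + 5))

    var_s = (n * (n - 1) * (2 * n + 5) - _tie_term(x) - _tie_term(t)) / 18.0

    n_pairs = n * (n - 1) / 2
    tx = np.sum([c * (c - 1) / 2 for c in np.unique(x, return_counts=True)[1]])
    tt = np.sum([c * (c - 1) / 2 for c in np.unique(t, return_counts=True)[1]])
    denom = math.sqrt((n_pairs - tx) * (n_pairs - tt))
    tau = s / denom if denom > 0 else 0.0

    has_ties = tx > 0 or tt > 0
    if n <= 10 and not has_ties:
        p = _exact_p(int(round(s)), n)
        method = "exact"
    else:
        if var_s <= 0:
            p = 1.0
        else:
            if s > 0:
                z = (s - 1) / math.sqrt(var_s)
            elif s < 0:
                z = (s + 1) / math.sqrt(var_s)
            else:
                z = 0.0
            p = 2.0 * stats.norm.sf(abs(z))
        method = "normal"
    return MannKendallResult(s=s, tau=tau, var_s=var_s, p=p, n=n, method=method)


def theil_sen(values, times=None) -> float:
    """Theil-Sen slope: the median of all pairwise slopes.

    Pairs with duplicate time points are skipped.
    """
    x = np.asarray(values, dtype=float)
    t = np.arange(x.size, dtype=float) if times is None else np.asarray(times, dtype=float)
    keep = np.isfinite(x) & np.isfinite(t)
    x, t = x[keep], t[keep]
    if x.size < 2:
        raise ValueError("Theil-Sen requires >= 2 values")
    i, j = np.triu_indices(x.size, k=1)
    dt = t[j] - t[i]
    ok = dt != 0
    if not ok.any():
        raise ValueError("all time points are duplicated; no slope defined")
    return float(np.median((x[j] - x[i])[ok] / dt[ok]))


def _lag1_autocorr(x: np.ndarray) -> float:
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        return 0.0
    return float(np.dot(x[:-1], x[1:]) / denom)


def prewhiten_series(values, times=None, variant: str = "yuepilon"):
    """Remove lag-1 autocorrelation before trend testing.

    ``yuepilon`` is trend-free pre-whitening: the Theil-Sen trend is
    removed, the AR(1) component of the residuals is filtered out, and
    the trend is added back (blended series).  ``zhang`` iterates slope
    and autocorrelation estimates on the whitened series until they
    stabilise.  Returns (series, times, slope) where slope is the
    Theil-Sen slope on the original scale.
    """
    x = np.asarray(values, dtype=float)
    t = np.arange(x.size, dtype=float) if times is None else np.asarray(times, dtype=float)
    keep = np.isfinite(x) & np.isfinite(t)
    x, t = x[keep], t[keep]
    if variant == "yuepilon":
        b = theil_sen(x, t)
        detrended = x - b * t
        r1 = _lag1_autocorr(detrended)
        white = detrended[1:] - r1 * detrended[:-1]
        blended = white + b * t[1:]
        return blended, t[1:], b
    if variant == "zhang":
        r1 = _lag1_autocorr(x)
        b = theil_sen(x, t)
        for _ in range(50):
            white = (x[1:] - r1 * x[:-1]) / (1.0 - r1) if abs(1.0 - r1) > 1e-12 else x[1:]
            b_new = theil_sen(white, t[1:])
            detrended = x - b_new * t
            r1_new = _lag1_autocorr(detrended)
            if abs(b_new - b) < 1e-12 and abs(r1_new - r1) < 1e-12:
                b, r1 = b_new, r1_new
                break
            b, r1 = b_new, r1_new
        white = (x[1:] - r1 * x[:-1]) / (1.0 - r1) if abs(1.0 - r1) > 1e-12 else x[1:]
        return white, t[1:], b
    raise ValueError(f"unknown pre-whitening variant: {variant!r}")


def classify_trend(values, times=None, alpha: float = 0.10,
                   prewhiten: str | None = "yuepilon",
                   unit_id=None, period=None) -> TrendResult:
    """Classify a series as greening, browning, or no trend.

    greening: positive Theil-Sen slope with MK p <= alpha; browning:
    negative slope with p <= alpha; otherwise none.  With ``prewhiten``
    set ("yuepilon" or "zhang") the MK p-value is computed on the
    pre-whitened series; the reported slope is always on the original
    series.
    """
    x = np.asarray(values, dtype=float)
    t = np.arange(x.size, dtype=float) if times is None else np.asarray(times, dtype=float)
    slope = theil_sen(x, t)
    if prewhiten:
        series, times_pw, slope = prewhiten_series(x, t, variant=prewhiten)
        mk = mann_kendall(series, times_pw)
    else:
        mk = mann_kendall(x, t)
    if mk.p <= alpha and slope > 0:
        cls = "greening"
    elif mk.p <= alpha and slope < 0:
        cls = "browning"
    else:
        cls = "none"
    if period is None:
        tt = t[np.isfinite(t)]
        period = (int(tt.min()), int(tt.max())) if tt.size else (None, None)
    return TrendResult(unit_id=unit_id, period=period, sen_slope=slope,
                       mk_p=mk.p, trend_class=cls, alpha_used=alpha)


def screen_sites(ndvimax: pd.DataFrame, barren_threshold: float = 0.10,
                 min_years: int = 10,
                 site_col: str = "site_id", value_col: str = "ndvimax") -> list:
    """Sites retained for trend analysis.

    Excludes barren sites (mean NDVI_max below ``barren_threshold``) and
    short records (fewer than ``min_years`` years with a value).
    """
    g = ndvimax.dropna(subset=[value_col]).groupby(site_col)[value_col]
    summary = g.agg(["mean", "count"])
    ok = (summary["mean"] >= barren_threshold) & (summary["count"] >= min_years)
    return summary.index[ok].tolist()


def correlate_ndvi_swi(ndvi: pd.Series, swi: pd.Series, mode: str = "current-year",
                       min_overlap: int = 8, unit_id=None) -> CorrelationResult:
    """Spearman correlation between annual NDVI_max and SWI.

    Both inputs are indexed by year.  Modes: ``current-year`` pairs the
    same years; ``two-year-mean`` replaces SWI_y with the mean of the
    current and preceding year's SWI (the first year, lacking a
    predecessor, is dropped); ``detrended`` correlates the residuals of
    each series after an OLS fit on calendar year.
    """
    ndvi = ndvi.dropna()
    swi = swi.dropna()
    if mode == "two-year-mean":
        prev = swi.reindex(swi.index - 1)
        prev.index = swi.index
        swi = ((swi + prev) / 2.0).dropna()
    years = ndvi.index.intersection(swi.index)
    if len(years) < min_overlap:
        return CorrelationResult(unit_id=unit_id, r_s=float("nan"), p=float("nan"),
                                 mode=mode, n=len(years), ok=False)
    x = ndvi.loc[years].to_numpy(dtype=float)
    y = swi.loc[years].to_numpy(dtype=float)
    if mode == "detrended":
        yr = np.asarray(years, dtype=float)
        x = x - np.polyval(np.polyfit(yr, x, 1), yr)
        y = y - np.polyval(np.polyfit(yr, y, 1), yr)
    r, p = stats.spearmanr(x, y)
    return CorrelationResult(unit_id=unit_id, r_s=float(r), p=float(p),
                             mode=mode, n=len(years), ok=True)


def aggregate_zone(ndvimax: pd.DataFrame, zones: pd.Series,
                   site_col: str = "site_id", year_col: str = "year",
                   value_col: str = "ndvimax") -> pd.DataFrame:
    """Zone-mean anomaly series.

    Each site's values are first converted to anomalies relative to its
    own period mean, then averaged across the sites of each zone with
    equal weights.  Returns a tidy frame (zone, year, anomaly, n_sites).
    """
    df = ndvimax.dropna(subset=[value_col]).copy()
    site_mean = df.groupby(site_col)[value_col].transform("mean")
    df["anomaly"] = df[value_col] - site_mean
    df["zone"] = df[site_col].map(zones)
    out = (df.groupby(["zone", year_col])["anomaly"]
             .agg(["mean", "count"])
             .rename(columns={"mean": "anomaly", "count": "n_sites"})
             .reset_index())
    return out


def class_percentages(classes) -> dict:
    """Percentage of units in each trend class (browning / none / greening)."""
    s = pd.Series(list(classes))
    if s.empty:
        raise ValueError("no trend classes supplied")
    pct = s.value_counts(normalize=True) * 100.0
    return {c: float(pct.get(c, 0.0)) for c in TREND_CLASSES}


def greening_browning_ratio(pct_greening: float, pct_browning: float) -> float:
    """How many times more common greening is than browning.

    A draw with zero browning yields an infinite ratio, which is
    reported as such rather than dropped.
    """
    if pct_browning == 0:
        return math.inf
    return pct_greening / pct_browning


def summarize_classes(per_draw_classes) -> pd.DataFrame:
    """Class percentages and greening:browning ratio with ensemble CI.

    ``per_draw_classes`` is an iterable of per-draw class collections
    (one entry per Monte-Carlo draw).  Returns one row per statistic
    with the median and the 2.5th/97.5th percentile bounds across draws.
    Infinite ratios (no browning in a draw) propagate into the
    percentiles.
    """
    rows = {c: [] for c in TREND_CLASSES}
    ratios = []
    for classes in per_draw_classes:
        pct = class_percentages(classes)
        for c in TREND_CLASSES:
            rows[c].append(pct[c])
        ratios.append(greening_browning_ratio(pct["greening"], pct["browning"]))
    records = []
    for name, vals in list(rows.items()) + [("greening_browning_ratio", ratios)]:
        v = np.asarray(vals, dtype=float)
        records.append({
            "statistic": name,
            "median": float(np.median(v)),
            "ci_low": float(np.percentile(v, 2.5)),
            "ci_high": float(np.percentile(v, 97.5)),
            "n_draws": len(vals),
            "n_infinite": int(np.sum(np.isinf(v))),
        })
    return pd.DataFrame.from_records(records)


def fire_rotation(burned_fraction: float, window_years: float) -> float:
    """Fire rotation: years to burn an area equal to the whole domain once.

    rotation = observation window / fraction of sites burned.  A burned
    fraction of zero leaves the rotation undefined (NaN, with warning).
    """
    if not 0 <= burned_fraction <= 1:
        raise ValueError(f"burned_fraction must be in [0, 1], got {burned_fraction}")
    if burned_fraction == 0:
        warnings.warn("burned fraction is zero; fire rotation undefined")
        return float("nan")
    return window_years / burned_fraction
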