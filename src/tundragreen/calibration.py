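"""Cross-sensor NDVI calibration.

Different sensors carry small systematic NDVI biases that, left in
place, masquerade as trends once the sensor mix changes through time.
Calibration maps each non-reference sensor's NDVI onto the reference
sensor (L7): per site, 15-day moving-median NDVI series are built for
both sensors from observations pooled across the years both were
flying; one 15-day period with at least five observations from each
sensor is selected at random; and a random-forest regression predicts
reference NDVI from target NDVI, the period midpoint (day of year), and
the site's planar coordinates.  Two-thirds of the sites train the
model; the withheld third yields the honest fit metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import r2_score

from .synthetic import SUMMER_DOY

logger = logging.getLogger(__name__)

HALF_WINDOW = 7  # 15-day window centered on the midpoint

__all__ = ["PairedCalibrationSample", "CalibrationModel",
           "build_paired_samples", "fit_calibration", "apply_calibration"]


@dataclass
class CalibrationModel:
    """Fitted target-sensor -> reference-sensor NDVI mapping.

    The forest is trained on the paired inter-sensor *difference*
    (reference minus target) rather than on the reference value itself;
    predicting the typically small, slowly varying difference and adding
    it back to the input avoids the regression-dilution shrinkage that a
    direct value-on-value fit suffers when the paired medians are noisy.
    The exposed mapping is still (ndvi_in, doy, x, y) -> ndvi_out.
    """
    target_sensor: str
    reference_sensor: str
    regressor: object
    doy_range: tuple
    train_sites: tuple
    test_sites: tuple
    fit_metrics: dict = field(default_factory=dict)
    train_fraction: float = 2.0 / 3.0

    def predict(self, ndvi, doy, x, y):
        ndvi = np.asarray(ndvi, dtype=float)
        X = np.column_stack([ndvi,
                             np.asarray(doy, dtype=float),
                             np.asarray(x, dtype=float),
                             np.asarray(y, dtype=float)])
        return ndvi + self.regressor.predict(X)


def build_paired_samples(obs: pd.DataFrame, target_sensor: str,
                         reference_sensor: str, rng,
                         min_obs_per_period: int = 5,
                         sites: pd.DataFrame | None = None) -> pd.DataFrame:
    """One paired 15-day moving-median NDVI sample per eligible site.

    Per site, overlap years are those in which both sensors observed the
    site; observations are pooled across overlap years; 15-day medians
    are computed at every 1-day midpoint across the summer; periods with
    fewer than ``min_obs_per_period`` observations for either sensor are
    excluded; and one eligible period is selected uniformly at random.

    ``sites`` (site_id, x, y) attaches coordinates; if omitted they are
    taken from the observation table when present, else set to 0.
    """
    for s in (target_sensor, reference_sensor):
        if s not in set(obs["sensor"].unique()):
            logger.warning("sensor %s absent from observations; empty pairing", s)
            return pd.DataFrame(columns=["site_id", "doy_mid", "ndvi_target",
                                         "ndvi_reference", "x", "y",
                                         "n_target", "n_reference"])
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    coords = None
    if sites is not None:
        coords = sites.set_index("site_id")[["x", "y"]]

    midpoints = np.arange(SUMMER_DOY[0] + HALF_WINDOW, SUMMER_DOY[1] - HALF_WINDOW + 1)
    rows = []
    sub = obs[obs["sensor"].isin([target_sensor, reference_sensor])]
    for site, g in sub.groupby("site_id", sort=True):
        yr_t = set(g.loc[g["sensor"] == target_sensor, "year"])
        yr_r = set(g.loc[g["sensor"] == reference_sensor, "year"])
        overlap = yr_t & yr_r
        if not overlap:
            continue
        g = g[g["year"].isin(overlap)]
        doy_t = g.loc[g["sensor"] == target_sensor, "doy"].to_numpy()
        val_t = g.loc[g["sensor"] == target_sensor, "ndvi"].to_numpy()
        doy_r = g.loc[g["sensor"] == reference_sensor, "doy"].to_numpy()
        val_r = g.loc[g["sensor"] == reference_sensor, "ndvi"].to_numpy()
        in_t = np.abs(doy_t[None, :] - midpoints[:, None]) <= HALF_WINDOW
        in_r = np.abs(doy_r[None, :] - midpoints[:, None]) <= HALF_WINDOW
        n_t = in_t.sum(axis=1)
        n_r = in_r.sum(axis=1)
        eligible = np.flatnonzero((n_t >= min_obs_per_period) & (n_r >= min_obs_per_period))
        if eligible.size == 0:
            continue
        pick = int(eligible[rng.integers(eligible.size)])
        med_t = float(np.median(val_t[in_t[pick]]))
        med_r = float(np.median(val_r[in_r[pick]]))
        if coords is not None and site in coords.index:
            sx, sy = coords.loc[site, "x"], coords.loc[site, "y"]
        elif {"x", "y"} <= set(g.columns):
            sx, sy = g["x"].iloc[0], g["y"].iloc[0]
        else:
            sx = sy = 0.0
        rows.append((site, int(midpoints[pick]), med_t, med_r, float(sx), float(sy),
                     int(n_t[pick]), int(n_r[pick])))
    if not rows:
        logger.warning("no overlap years between %s and %s at any site",
                       target_sensor, reference_sensor)
    return pd.DataFrame(rows, columns=["site_id", "doy_mid", "ndvi_target",
                                       "ndvi_reference", "x", "y",
                                       "n_target", "n_reference"])


def fit_calibration(samples: pd.DataFrame, rng, target_sensor: str = "",
                    reference_sensor: str = "L7",
                    min_samples: int = 30, train_fraction: float = 2.0 / 3.0,
                    n_estimators: int = 100, min_samples_leaf: int = 5) -> CalibrationModel:
    """Random-forest NDVI cross-calibration with a site-level 2/3-1/3 split.

    Features are (target NDVI, period midpoint DOY, x, y); the forest
    learns the paired inter-sensor difference (see CalibrationModel).
    Sites (not samples) are partitioned so the held-out metrics (r2,
    RMSE, bias = mean(predicted - reference)) are honest about spatial
    generalisation.
    """
    if len(samples) < min_samples:
        raise ValueError(
            f"calibration requires >= {min_samples} paired samples, got {len(samples)}")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    site_ids = np.asarray(sorted(samples["site_id"].unique()))
    perm = rng.permutation(site_ids.size)
    n_train = max(1, int(round(train_fraction * site_ids.size)))
    n_train = min(n_train, site_ids.size - 1)
    train_sites = set(site_ids[perm[:n_train]])
    test_sites = set(site_ids[perm[n_train:]])

    feats = ["ndvi_target", "doy_mid", "x", "y"]
    tr = samples[samples["site_id"].isin(train_sites)]
    te = samples[samples["site_id"].isin(test_sites)]
    reg = RandomForestRegressor(n_estimators=n_estimators,
                                min_samples_leaf=min_samples_leaf,
                                random_state=int(rng.integers(2**31)))
    reg.fit(tr[feats].to_numpy(),
            (tr["ndvi_reference"] - tr["ndvi_target"]).to_numpy())
    pred = te["ndvi_target"].to_numpy() + reg.predict(te[feats].to_numpy())
    resid = pred - te["ndvi_reference"].to_numpy()
    metrics = {
        "r2": float(r2_score(te["ndvi_reference"], pred)) if len(te) > 1 else float("nan"),
        "rmse": float(np.sqrt(np.mean(resid ** 2))),
        "bias": float(np.mean(resid)),
        "n_train": int(len(tr)),
        "n_test": int(len(te)),
        "bias_before": float(np.mean(te["ndvi_target"] - te["ndvi_reference"])),
    }
    return CalibrationModel(target_sensor=target_sensor,
                            reference_sensor=reference_sensor,
                            regressor=reg,
                            doy_range=(float(samples["doy_mid"].min()),
                                       float(samples["doy_mid"].max())),
                            train_sites=tuple(sorted(train_sites)),
                            test_sites=tuple(sorted(test_sites)),
                            fit_metrics=metrics,
                            train_fraction=train_fraction)


def apply_calibration(obs: pd.DataFrame, models: dict,
                      reference_sensor: str = "L7",
                      sites: pd.DataFrame | None = None) -> pd.DataFrame:
    """Cross-calibrate an observation table to the reference sensor.

    ``models`` maps target sensor id -> fitted CalibrationModel.
    Reference-sensor rows (and rows from sensors with no model) pass
    through unchanged; calibrated NDVI is clipped to [-1, 1].
    Observations outside a model's training DOY range are predicted at
    the range boundary and counted in the log.
    """
    if obs.empty:
        return obs.copy()
    out = obs.copy()
    if sites is not None and "x" not in out.columns:
        out = out.merge(sites[["site_id", "x", "y"]], on="site_id", how="left")
    for sensor, model in models.items():
        mask = out["sensor"] == sensor
        if not mask.any():
            continue
        doy = out.loc[mask, "doy"].to_numpy(dtype=float)
        lo, hi = model.doy_range
        n_out = int(np.sum((doy < lo) | (doy > hi)))
        if n_out:
            logger.info("%d %s observations outside calibration DOY range [%g, %g]; "
                        "clamped to boundary", n_out, sensor, lo, hi)
        doy = np.clip(doy, lo, hi)
        x = out.loc[mask, "x"].to_numpy(dtype=float) if "x" in out.columns else np.zeros(mask.sum())
        y = out.loc[mask, "y"].to_numpy(dtype=float) if "y" in out.columns else np.zeros(mask.sum())
        pred = model.predict(out.loc[mask, "ndvi"].to_numpy(), doy, x, y)
        out.loc[mask, "ndvi"] = np.clip(pred, -1.0, 1.0)
    return out
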