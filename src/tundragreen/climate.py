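"""Summer warmth index (SWI) and synthetic multi-dataset SWI realizations.

SWI is the annual sum of mean monthly air temperatures strictly above
0 degC — a cumulative summer heat load in degC widely used for Arctic
climatologies.  Gridded temperature products disagree; that structural
uncertainty is propagated by building synthetic SWI realizations in
which each cell's series is drawn at random from one of the member
data sets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["compute_swi", "synthesize_swi", "swi_from_monthly_table"]


def compute_swi(monthly: pd.DataFrame, unit_col: str = "cell") -> pd.DataFrame:
    """Annual SWI per unit from a long monthly-mean table.

    ``monthly`` has columns (unit, year, month, value) with value in
    degC.  Years with missing or non-finite months are dropped with a
    warning.  SWI_y = sum over months of T_{y,m} where T > 0 (strict);
    exact zeros do not contribute.
    """
    df = monthly.copy()
    bad = ~np.isfinite(df["value"])
    if bad.any():
        dropped = df.loc[bad, [unit_col, "year"]].drop_duplicates()
        logger.warning("dropping %d unit-years with non-finite temperatures", len(dropped))
        df = df.merge(dropped.assign(_bad=True), on=[unit_col, "year"], how="left")
        df = df[df["_bad"].isna()].drop(columns="_bad")
    counts = df.groupby([unit_col, "year"])["month"].nunique()
    incomplete = counts[counts < 12]
    if len(incomplete):
        logger.warning("dropping %d unit-years with missing months", len(incomplete))
        df = df.set_index([unit_col, "year"]).drop(index=incomplete.index).reset_index()
    pos = df["value"].where(df["value"] > 0.0, 0.0)
    out = (df.assign(_pos=pos)
             .groupby([unit_col, "year"])["_pos"].sum()
             .rename("swi").reset_index())
    return out


def swi_from_monthly_table(monthly: pd.DataFrame, unit_col: str = "cell") -> dict:
    """SWI per data set from a long table with a ``dataset`` column."""
    return {name: compute_swi(g, unit_col=unit_col)
            for name, g in monthly.groupby("dataset")}


def synthesize_swi(datasets: dict, rng, per_year: bool = False,
                   unit_col: str = "cell") -> pd.DataFrame:
    """One synthetic SWI realization from an ensemble of SWI tables.

    ``datasets`` maps name -> SWI table (unit, year, swi) on identical
    unit/year grids.  Every cell's values are taken from one member
    data set chosen uniformly at random — by default the same data set
    for all years of a cell within a draw; with ``per_year`` the choice
    is independent per (cell, year).  A single data set passes through
    with a warning.
    """
    names = sorted(datasets)
    if len(names) == 1:
        logger.warning("single SWI data set supplied; passthrough realization")
        out = datasets[names[0]].copy()
        out["source"] = names[0]
        return out
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng

    mats = []
    ref_index = None
    for name in names:
        piv = datasets[name].pivot(index=unit_col, columns="year", values="swi").sort_index()
        if ref_index is None:
            ref_index = (piv.index, piv.columns)
        else:
            same_units = piv.index.equals(ref_index[0])
            same_years = piv.columns.equals(ref_index[1])
            if not (same_units and same_years):
                missing_u = list(ref_index[0].symmetric_difference(piv.index))
                missing_y = list(ref_index[1].symmetric_difference(piv.columns))
                raise ValueError(
                    f"data set {name!r} grid mismatch; differing units {missing_u[:5]} "
                    f"and years {missing_y[:5]}")
        mats.append(piv.to_numpy())
    stack = np.stack(mats)  # (dataset, unit, year)
    n_units, n_years = stack.shape[1], stack.shape[2]
    if per_year:
        choice = rng.integers(len(names), size=(n_units, n_years))
    else:
        choice = np.repeat(rng.integers(len(names), size=(n_units, 1)), n_years, axis=1)
    vals = np.take_along_axis(stack, choice[None, :, :], axis=0)[0]
    out = pd.DataFrame(vals, index=ref_index[0], columns=ref_index[1])
    out = out.stack().rename("swi").reset_index()
    out.columns = [unit_col, "year", "swi"]
    src = pd.DataFrame(np.asarray(names)[choice], index=ref_index[0], columns=ref_index[1])
    out["source"] = src.stack().to_numpy()
    return out
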