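"""Covariate extraction at track locations and within-year scaling.

Each regularized location is matched to the containing 0.5-degree prey
cell of its calendar year, the containing 0.01-degree bathymetry cell, and
the containing 0.01-degree SST cell of its calendar month.  Simpson's
diversity D and total biomass are computed from the eight matched species
biomasses, and all covariates are z-scored within calendar year over the
matched rows before modelling.

Cell containment is half-open, [origin, origin + resolution) in both axes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .simdata import EnvGrid, PreyGrid

logger = logging.getLogger(__name__)


class UndefinedDiversityError(ValueError):
    """Simpson's D is undefined when total biomass is zero."""


class DegenerateScalingError(ValueError):
    """A covariate is constant within a year, so z-scoring is undefined."""


def simpson_diversity(biomass) -> float:
    """Simpson's diversity index D = 1 - sum_i (n_i / N)^2.

    D is the probability that two biomass units drawn at random belong to
    different species: 0 for a single species, 1 - 1/S for S equally
    abundant species.  Undefined (error) for an all-zero vector.
    """
    b = np.asarray(biomass, dtype=float)
    if np.any(b < 0):
        raise ValueError("biomass must be nonnegative")
    total = b.sum()
    if total <= 0:
        raise UndefinedDiversityError("all-zero biomass vector")
    p = b / total
    return float(1.0 - np.sum(p * p))


def match_covariates(tracks_df: pd.DataFrame, prey: PreyGrid, env: EnvGrid) -> pd.DataFrame:
    """Match every location to prey and environmental covariates.

    ``tracks_df`` needs columns id, seg_id, date, lon, lat (x_km/y_km are
    carried through when present).  Returns one row per location with a
    biomass column per species, ``biomass_all``, ``diversity``, ``bathy``,
    ``sst`` and a boolean ``matched``; unmatched locations (outside a grid
    or in a missing year/month) keep NaN covariates and are excluded from
    model fitting downstream.
    """
    df = tracks_df.copy()
    df["date"] = pd.to_datetime(df["date"])
    lon = df["lon"].to_numpy(dtype=float)
    lat = df["lat"].to_numpy(dtype=float)
    years = df["date"].dt.year.to_numpy()
    months = df["date"].dt.month.to_numpy()
    n = len(df)

    bio = np.full((n, len(prey.species)), np.nan)
    bathy = np.full(n, np.nan)
    sst = np.full(n, np.nan)

    in_prey = prey.inside(lon, lat)
    in_env = env.inside(lon, lat)
    pi, pj = prey.cell_index(lon, lat)
    ei, ej = env.cell_index(lon, lat)

    ok = np.zeros(n, dtype=bool)
    for r in range(n):
        year_ok = years[r] in prey.years
        sst_ok = (int(years[r]), int(months[r])) in env.sst_seasonal
        if not (in_prey[r] and in_env[r] and year_ok and sst_ok):
            continue
        y = prey.years.index(years[r])
        bio[r] = prey.biomass[y, :, pi[r], pj[r]]
        bathy[r] = env.bathymetry[ei[r], ej[r]]
        sst[r] = env.sst_seasonal[(int(years[r]), int(months[r]))] + env.sst_anom[ei[r], ej[r]]
        ok[r] = True

    for k, sp in enumerate(prey.species):
        df[f"biomass_{sp}"] = bio[:, k]
    df["biomass_all"] = bio.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tot = bio.sum(axis=1)
        dvr = 1.0 - np.nansum((bio / tot[:, None]) ** 2, axis=1)
    dvr[~ok] = np.nan
    dvr[ok & (tot <= 0)] = np.nan  # undefined diversity: treated as unmatched
    ok = ok & ~((tot <= 0) & ok)
    df["diversity"] = dvr
    df["bathy"] = bathy
    df["sst"] = sst
    df["matched"] = ok
    df["year"] = years
    n_miss = int((~ok).sum())
    if n_miss:
        logger.warning("%d of %d locations unmatched (outside grids or missing year/month)",
                       n_miss, n)
    return df


def covariate_columns(prey: PreyGrid) -> list:
    return [f"biomass_{sp}" for sp in prey.species] + ["biomass_all", "diversity", "bathy", "sst"]


def scale_by_year(table: pd.DataFrame, columns: list) -> pd.DataFrame:
    """Append ``_z`` columns: z-scored within calendar year over matched rows.

    Uses the sample (n-1) SD.  Raises :class:`DegenerateScalingError` when a
    covariate is constant within a year.
    """
    df = table.reset_index(drop=True)
    if "year" not in df:
        df["year"] = pd.to_datetime(df["date"]).dt.year
    rows = df["matched"] if "matched" in df else pd.Series(True, index=df.index)
    for col in columns:
        z = np.full(len(df), np.nan)
        for year, grp in df[rows].groupby("year"):
            v = grp[col].to_numpy(dtype=float)
            sd = np.std(v, ddof=1) if len(v) > 1 else 0.0
            if not np.isfinite(sd) or sd == 0.0:
                raise DegenerateScalingError(f"covariate {col!r} constant in year {year}")
            z[grp.index.to_numpy()] = (v - v.mean()) / sd
        df[f"{col}_z"] = z
    return df
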