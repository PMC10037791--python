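"""Synthetic biologging data with known ground truth.

Generates every input the downstream pipeline consumes: gridded prey biomass
for eight fish species (yearly, 0.5 deg), bathymetry and monthly SST
(0.01 deg), a weekly sea-ice concentration series, satellite-telemetry tracks
with Argos-like error and irregular sampling, and time-depth dive records.

Tracks are simulated from the same generative model the estimator assumes: a
first-difference correlated random walk on local-km displacements,

    d_t = gamma_t * d_{t-1} + eta_t,        eta_t ~ N(0, Sigma_d)
    logit(gamma_t) = beta_0 + b_k + sum_j beta_j x_j(pos_t) + eps_t,

with individual random intercepts b_k ~ N(0, sigma_b^2) and per-step noise
eps_t ~ N(0, sigma_gamma^2).  Covariates x_j are evaluated along the track
from the generated fields and standardized by the field mean/SD, so the
true coefficients are on the same per-SD scale the fitted model reports.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .geo import TangentPlane

logger = logging.getLogger(__name__)

SPECIES = (
    "arctic_cod",
    "capelin",
    "n_sand_lance",
    "p_sand_lance",
    "staghorn_sculpin",
    "shorthorn_sculpin",
    "moustache_sculpin",
    "rainbow_smelt",
)

ARGOS_CLASSES = ("3", "2", "1", "0", "A", "B")

#: default per-class location-error SDs in km (config-overridable)
DEFAULT_OBS_SD = {"3": 0.25, "2": 0.5, "1": 1.5, "0": 4.0, "A": 6.0, "B": 10.0}

#: default class sampling frequencies (the class mix of real deployments
#: varies by tag and habitat; this mix leans on the mid-quality classes)
DEFAULT_CLASS_FREQ = {"3": 0.10, "2": 0.20, "1": 0.30, "0": 0.20, "A": 0.10, "B": 0.10}


class SimConfigError(ValueError):
    """Raised for invalid simulation configuration."""


@dataclass
class SimConfig:
    """Configuration of the synthetic study.

    Defaults describe a single open-water season of a coastal seal
    population: 25 individuals tracked for 100 four-hour steps, fixes
    observed every ~1.2 h on average with occasional multi-hour gaps,
    persistence driven by prey diversity (positive) and bathymetry
    (negative) on the logit scale.
    """

    n_individuals: int = 25
    steps_per_track: int = 100
    step_hours: float = 4.0
    covariate_names: tuple = ("diversity", "bathy")
    true_beta: tuple = (0.5, 0.5, -0.5)  # intercept then one slope per covariate
    sigma_b: float = 0.3
    sigma_gamma: float = 0.3
    disp_cov: tuple = ((1.2, 0.2), (0.2, 1.0))  # km^2 per 4-h step
    obs_error_sd_by_class: dict = field(default_factory=lambda: dict(DEFAULT_OBS_SD))
    class_freq: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_FREQ))
    mean_fix_interval_h: float | None = 1.2
    gap_rate: float = 0.01
    gap_length_h: tuple = (13.0, 30.0)
    dive_rate: float = 8.0  # mean dives per step at gamma = 0.5
    dive_coupling: float = -1.5  # d log(rate) / d gamma
    # spatial domain (eastern-Hudson-Bay-like extent) and grid resolutions
    lon_extent: tuple = (-84.0, -76.0)
    lat_extent: tuple = (54.0, 60.0)
    prey_res: float = 0.5
    env_res: float = 0.01
    year: int = 2009
    start_date: str = "2009-07-15"
    start_spread_days: float = 30.0
    # field-generation parameters
    biomass_mean: tuple = (120.0, 90.0, 60.0, 30.0, 25.0, 20.0, 15.0, 10.0)
    biomass_log_sd: float = 0.6
    prey_range_deg: float = 1.0  # Gaussian-kernel SD of the log-biomass fields
    bathy_range_deg: float = 0.8
    bathy_depth_range: tuple = (20.0, 250.0)  # min/max water-column depth, m
    sst_anom_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1 or self.steps_per_track < 3:
            raise SimConfigError("need >= 1 individual and >= 3 steps per track")
        if self.step_hours <= 0:
            raise SimConfigError("step_hours must be positive")
        if self.prey_res <= 0 or self.env_res <= 0:
            raise SimConfigError("grid resolutions must be positive")
        if self.lon_extent[1] <= self.lon_extent[0] or self.lat_extent[1] <= self.lat_extent[0]:
            raise SimConfigError("empty spatial extent")
        if self.sigma_b < 0 or self.sigma_gamma < 0:
            raise SimConfigError("sigma_b and sigma_gamma must be nonnegative")
        if len(self.true_beta) != len(self.covariate_names) + 1:
            raise SimConfigError("true_beta must have one intercept plus one slope per covariate")
        S = np.asarray(self.disp_cov, dtype=float)
        if S.shape != (2, 2) or not np.allclose(S, S.T) or np.any(np.linalg.eigvalsh(S) <= 0):
            raise SimConfigError("disp_cov must be symmetric positive-definite 2x2")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent, process-stable substream for a named stage."""
        tag = zlib.crc32(stream.encode()) % 2**31
        return np.random.default_rng(np.random.SeedSequence([self.seed, tag]))

    def plane(self) -> TangentPlane:
        return TangentPlane(float(np.mean(self.lon_extent)), float(np.mean(self.lat_extent)))


# ---------------------------------------------------------------------------
# gridded types


@dataclass
class PreyGrid:
    """Yearly biomass of 8 species on a half-open 0.5-deg grid."""

    species: tuple
    west: float
    south: float
    res: float
    years: tuple
    biomass: np.ndarray  # (n_years, n_species, n_lat, n_lon), nonnegative

    def cell_index(self, lon, lat):
        i = np.floor((np.asarray(lat) - self.south) / self.res).astype(int)
        j = np.floor((np.asarray(lon) - self.west) / self.res).astype(int)
        return i, j

    def inside(self, lon, lat):
        i, j = self.cell_index(lon, lat)
        return (i >= 0) & (i < self.biomass.shape[2]) & (j >= 0) & (j < self.biomass.shape[3])

    def biomass_at(self, lon: float, lat: float, year: int) -> np.ndarray:
        """Biomass vector (one entry per species) of the containing cell."""
        if year not in self.years:
            raise KeyError(f"year {year} not in prey grid")
        y = self.years.index(year)
        i, j = self.cell_index(lon, lat)
        return self.biomass[y, :, int(i), int(j)]


@dataclass
class EnvGrid:
    """Bathymetry (time-invariant) and monthly SST on a 0.01-deg grid.

    SST is stored as a spatial anomaly field plus a (year, month) seasonal
    mean, so sst(lon, lat, year, month) = seasonal[(year, month)] +
    anomaly(lon, lat).
    """

    west: float
    south: float
    res: float
    bathymetry: np.ndarray  # (n_lat, n_lon), m elevation (<= 0 offshore)
    sst_anom: np.ndarray  # (n_lat, n_lon), deg C
    sst_seasonal: dict  # (year, month) -> deg C

    def cell_index(self, lon, lat):
        i = np.floor((np.asarray(lat) - self.south) / self.res).astype(int)
        j = np.floor((np.asarray(lon) - self.west) / self.res).astype(int)
        return i, j

    def inside(self, lon, lat):
        i, j = self.cell_index(lon, lat)
        return (i >= 0) & (i < self.bathymetry.shape[0]) & (j >= 0) & (j < self.bathymetry.shape[1])

    def bathymetry_at(self, lon, lat):
        i, j = self.cell_index(lon, lat)
        return self.bathymetry[i, j]

    def sst_at(self, lon, lat, year: int, month: int):
        key = (int(year), int(month))
        if key not in self.sst_seasonal:
            raise KeyError(f"no SST for year/month {key}")
        i, j = self.cell_index(lon, lat)
        return self.sst_seasonal[key] + self.sst_anom[i, j]


@dataclass
class IceSeries:
    """Weekly sea-ice concentration (percent of area covered)."""

    week_start: pd.DatetimeIndex
    concentration: np.ndarray  # percent in [0, 100]


@dataclass
class TruthTrack:
    """Simulated track on the exact step lattice, with latent truth.

    ``gamma[i]`` is the persistence governing the displacement that starts
    at position ``i`` (NaN where no previous displacement exists, i.e. at
    the first and last position).  ``covariates[name][i]`` is the
    standardized covariate value used at that step.
    """

    individual: str
    times: pd.DatetimeIndex
    lon: np.ndarray
    lat: np.ndarray
    x_km: np.ndarray
    y_km: np.ndarray
    gamma: np.ndarray
    b0: float
    covariates: dict


@dataclass
class RawTrack:
    """Irregular, error-prone Argos-like observations of one individual."""

    individual: str
    times: pd.DatetimeIndex
    lon: np.ndarray
    lat: np.ndarray
    quality: np.ndarray  # Argos class labels


@dataclass
class DiveRecord:
    """One dive: start time, duration, depths, bottom time."""

    individual: str
    start: pd.Timestamp
    duration_s: float
    max_depth_m: float
    mean_depth_m: float
    bottom_s: float


# ---------------------------------------------------------------------------
# random fields


def gaussian_random_field(rng: np.random.Generator, shape: tuple, range_cells: float) -> np.ndarray:
    """Stationary Gaussian field with ~unit variance.

    White noise smoothed with a Gaussian kernel (SD ``range_cells`` in cell
    units, reflective boundaries), then rescaled to unit sample variance.
    """
    z = rng.standard_normal(shape)
    if range_cells > 0:
        z = ndimage.gaussian_filter(z, sigma=range_cells, mode="reflect")
    sd = z.std()
    return z / sd if sd > 0 else z


def semivariogram(values: np.ndarray, max_lag: int) -> tuple:
    """Brute-force isotropic empirical semivariogram of a 2-D field.

    Returns (lags, semivariance) for integer cell lags 1..max_lag, averaging
    squared differences over row and column shifts.
    """
    lags = np.arange(1, max_lag + 1)
    sv = np.empty(len(lags))
    for n, h in enumerate(lags):
        dr = values[h:, :] - values[:-h, :]
        dc = values[:, h:] - values[:, :-h]
        sv[n] = 0.5 * np.mean(np.concatenate([dr.ravel() ** 2, dc.ravel() ** 2]))
    return lags, sv


def variogram_range(values: np.ndarray, max_lag: int, frac: float = 0.95) -> int:
    """First lag at which the semivariogram reaches ``frac`` of the field variance."""
    lags, sv = semivariogram(values, max_lag)
    sill = values.var()
    hit = np.nonzero(sv >= frac * sill)[0]
    return int(lags[hit[0]]) if hit.size else int(lags[-1])


# ---------------------------------------------------------------------------
# grid generation


def gen_grids(config: SimConfig) -> tuple:
    """Generate (PreyGrid, EnvGrid, IceSeries) for the configured domain.

    Biomass fields are exponentiated Gaussian random fields (so strictly
    positive, right-skewed, spatially autocorrelated) with per-species mean
    preserved exactly: B = mean * exp(s*Z - s^2/2) with Z ~ unit-variance.
    Bathymetry is a smooth strictly negative surface; SST is a seasonal
    cycle plus a smooth spatial anomaly; ice follows a melt-freeze cycle
    crossing 50% downward in early summer and upward in late autumn.
    """
    config.validate()
    rng = config.rng("grids")

    west, east = config.lon_extent
    south, north = config.lat_extent

    # prey (0.5 deg, yearly)
    nlon = int(round((east - west) / config.prey_res))
    nlat = int(round((north - south) / config.prey_res))
    range_cells = config.prey_range_deg / config.prey_res
    s = config.biomass_log_sd
    biomass = np.empty((1, len(SPECIES), nlat, nlon))
    for k, mean in enumerate(config.biomass_mean):
        z = gaussian_random_field(rng, (nlat, nlon), range_cells)
        biomass[0, k] = mean * (np.exp(s * z - 0.5 * s * s) if s > 0 else np.ones_like(z))
    prey = PreyGrid(
        species=SPECIES, west=west, south=south, res=config.prey_res,
        years=(config.year,), biomass=biomass,
    )

    # environment (0.01 deg)
    nlon_e = int(round((east - west) / config.env_res))
    nlat_e = int(round((north - south) / config.env_res))
    cells = config.bathy_range_deg / config.env_res
    zb = gaussian_random_field(rng, (nlat_e, nlon_e), cells)
    dmin, dmax = config.bathy_depth_range
    depth = dmin + (dmax - dmin) * stats.norm.cdf(zb)  # smooth, in (dmin, dmax)
    za = gaussian_random_field(rng, (nlat_e, nlon_e), cells)
    seasonal = {}
    for month in range(1, 13):
        # annual cycle peaking in August, typical of subarctic open water
        seasonal[(config.year, month)] = 3.0 + 8.0 * np.cos(2 * np.pi * (month - 8) / 12.0)
    env = EnvGrid(
        west=west, south=south, res=config.env_res,
        bathymetry=-depth, sst_anom=config.sst_anom_sd * za, sst_seasonal=seasonal,
    )

    # weekly ice: logistic melt around day 170, freeze around day 330
    week_start = pd.date_range(f"{config.year}-01-01", periods=52, freq="7D")
    doy = (week_start - pd.Timestamp(f"{config.year}-01-01")).days.to_numpy()
    melt = 1.0 / (1.0 + np.exp((doy - 170) / 9.0))
    freeze = 1.0 / (1.0 + np.exp(-(doy - 330) / 6.0))
    conc = np.clip(95.0 * np.clip(melt + freeze, 0, 1) + rng.normal(0, 1.5, len(doy)), 0, 100)
    ice = IceSeries(week_start=week_start, concentration=conc)

    return prey, env, ice


# ---------------------------------------------------------------------------
# covariate fields along tracks


def _diversity_field(prey: PreyGrid, year: int) -> np.ndarray:
    y = prey.years.index(year)
    b = prey.biomass[y]  # (species, nlat, nlon)
    tot = b.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.sum((b / tot) ** 2, axis=0)
    return d


class CovariateFields:
    """Standardized covariate lookup used by both simulator and pipeline.

    Supported names: ``diversity``, ``bathy``, ``sst``, ``biomass_all`` and
    ``biomass_<species>``.  Standardization uses the mean/SD of the field
    over its own grid cells (SST: anomaly SD around the monthly mean), so
    simulated coefficients are per field-SD.
    """

    def __init__(self, prey: PreyGrid, env: EnvGrid, year: int):
        self.prey, self.env, self.year = prey, env, year
        self._stats = {}
        self._stats["diversity"] = _moments(_diversity_field(prey, year))
        self._stats["bathy"] = _moments(env.bathymetry)
        self._stats["sst"] = (0.0, max(env.sst_anom.std(), 1e-12))
        y = prey.years.index(year)
        self._stats["biomass_all"] = _moments(prey.biomass[y].sum(axis=0))
        for k, sp in enumerate(prey.species):
            self._stats[f"biomass_{sp}"] = _moments(prey.biomass[y, k])
        self._div = _diversity_field(prey, year)

    def raw(self, name: str, lon, lat, month: int | None = None):
        if name == "bathy":
            return self.env.bathymetry_at(lon, lat)
        if name == "sst":
            m = 8 if month is None else month
            return self.env.sst_at(lon, lat, self.year, m)
        i, j = self.prey.cell_index(lon, lat)
        if name == "diversity":
            return self._div[i, j]
        y = self.prey.years.index(self.year)
        if name == "biomass_all":
            return self.prey.biomass[y].sum(axis=0)[i, j]
        if name.startswith("biomass_"):
            k = self.prey.species.index(name[len("biomass_"):])
            return self.prey.biomass[y, k][i, j]
        raise KeyError(name)

    def standardized(self, name: str, lon, lat, month: int | None = None):
        if name == "sst":
            m = 8 if month is None else month
            anom = self.raw(name, lon, lat, m) - self.env.sst_seasonal[(self.year, m)]
            return anom / self._stats["sst"][1]
        mu, sd = self._stats[name]
        return (self.raw(name, lon, lat, month) - mu) / sd


def _moments(a: np.ndarray) -> tuple:
    return float(a.mean()), float(max(a.std(), 1e-12))


# ---------------------------------------------------------------------------
# movement


def simulate_movement(config: SimConfig, grids: tuple) -> tuple:
    """Simulate truth tracks and Argos-like raw observations.

    Returns (list[TruthTrack], list[RawTrack]).  Tracks that would leave the
    domain are reflected at the boundary (with a debug log) so covariates
    stay defined everywhere.
    """
    config.validate()
    prey, env, _ = grids
    rng = config.rng("movement")
    plane = config.plane()
    fields = CovariateFields(prey, env, config.year)

    xlo, xhi = plane.to_km(np.array(config.lon_extent), np.array([config.lat_extent[0]] * 2))[0]
    ylo, yhi = plane.to_km(np.array([config.lon_extent[0]] * 2), np.array(config.lat_extent))[1]
    # stay one env cell inside the edge so containment never fails
    pad = config.env_res * 120.0
    xlo, xhi, ylo, yhi = xlo + pad, xhi - pad, ylo + pad, yhi - pad

    beta = np.asarray(config.true_beta, dtype=float)
    Sd = np.asarray(config.disp_cov, dtype=float)
    chol = np.linalg.cholesky(Sd)
    T = config.steps_per_track
    start0 = pd.Timestamp(config.start_date)

    truths, raws = [], []
    n_reflect = 0
    for k in range(config.n_individuals):
        ind = f"ind{k:03d}"
        b0 = rng.normal(0.0, config.sigma_b)
        t0 = start0 + pd.Timedelta(hours=float(np.round(rng.uniform(0, config.start_spread_days * 24))))
        times = pd.date_range(t0, periods=T, freq=pd.Timedelta(hours=config.step_hours))

        x = np.empty(T)
        y = np.empty(T)
        gamma = np.full(T, np.nan)
        covs = {name: np.full(T, np.nan) for name in config.covariate_names}
        x[0] = rng.uniform(xlo + 0.3 * (xhi - xlo), xhi - 0.3 * (xhi - xlo))
        y[0] = rng.uniform(ylo + 0.3 * (yhi - ylo), yhi - 0.3 * (yhi - ylo))
        d_prev = chol @ rng.standard_normal(2)
        x[1], y[1] = x[0] + d_prev[0], y[0] + d_prev[1]
        x[1], y[1], d_prev, nr = _reflect(x[1], y[1], x[0], y[0], xlo, xhi, ylo, yhi)
        n_reflect += nr

        for i in range(1, T - 1):
            lon_i, lat_i = plane.to_lonlat(x[i], y[i])
            month = times[i].month
            z = beta[0] + b0
            for j, name in enumerate(config.covariate_names):
                v = float(fields.standardized(name, lon_i, lat_i, month))
                covs[name][i] = v
                z += beta[j + 1] * v
            z += rng.normal(0.0, config.sigma_gamma)
            g = 1.0 / (1.0 + np.exp(-z))
            gamma[i] = g
            d = g * d_prev + chol @ rng.standard_normal(2)
            x[i + 1], y[i + 1] = x[i] + d[0], y[i] + d[1]
            x[i + 1], y[i + 1], d, nr = _reflect(x[i + 1], y[i + 1], x[i], y[i], xlo, xhi, ylo, yhi)
            n_reflect += nr
            d_prev = d

        lon, lat = plane.to_lonlat(x, y)
        truths.append(TruthTrack(ind, times, lon, lat, x, y, gamma, b0, covs))
        raws.append(_observe(config, rng, plane, ind, times, x, y))

    if n_reflect:
        logger.warning("reflected %d boundary exits back into the domain", n_reflect)
    return truths, raws


def _reflect(xn, yn, xp, yp, xlo, xhi, ylo, yhi):
    """Reflect a proposed position into the domain; return corrected displacement."""
    n = 0
    for _ in range(100):
        if xlo <= xn <= xhi and ylo <= yn <= yhi:
            break
        if xn < xlo:
            xn = 2 * xlo - xn
        elif xn > xhi:
            xn = 2 * xhi - xn
        if yn < ylo:
            yn = 2 * ylo - yn
        elif yn > yhi:
            yn = 2 * yhi - yn
        n = 1
    xn = float(np.clip(xn, xlo, xhi))
    yn = float(np.clip(yn, ylo, yhi))
    return xn, yn, np.array([xn - xp, yn - yp]), n


def _observe(config, rng, plane, ind, times, x, y) -> RawTrack:
    """Thin the truth to irregular fix times and add class-specific error."""
    t_end_h = (times[-1] - times[0]).total_seconds() / 3600.0
    if config.mean_fix_interval_h is None:
        obs_h = np.arange(len(times)) * config.step_hours
    else:
        obs_h = []
        t = 0.0
        while t <= t_end_h:
            obs_h.append(t)
            dt = rng.exponential(config.mean_fix_interval_h)
            if config.gap_rate > 0 and rng.uniform() < config.gap_rate:
                dt += rng.uniform(*config.gap_length_h)
            t += max(dt, 1.0 / 60.0)
        obs_h = np.asarray(obs_h)

    truth_h = np.arange(len(times)) * config.step_hours
    ox = np.interp(obs_h, truth_h, x)
    oy = np.interp(obs_h, truth_h, y)

    classes = list(config.class_freq)
    p = np.array([config.class_freq[c] for c in classes], dtype=float)
    lc = rng.choice(classes, size=len(obs_h), p=p / p.sum())
    sd = np.array([config.obs_error_sd_by_class[c] for c in lc])
    ox = ox + rng.normal(0, 1, len(obs_h)) * sd
    oy = oy + rng.normal(0, 1, len(obs_h)) * sd
    lon, lat = plane.to_lonlat(ox, oy)
    obs_times = times[0] + pd.to_timedelta(np.round(obs_h * 3600.0), unit="s")
    return RawTrack(ind, pd.DatetimeIndex(obs_times), lon, lat, np.asarray(lc, dtype=object))


# ---------------------------------------------------------------------------
# dives


def simulate_dives(config: SimConfig, truths: list, grids: tuple) -> list:
    """Simulate time-depth dive records coupled to move persistence.

    Per lattice step the number of dives is Poisson with
    log(rate) = log(dive_rate) + dive_coupling * (gamma_t - 1/2), so
    negative coupling concentrates dives in low-persistence (ARS-like)
    steps.  Dive depths respect the water column: max depth is a Beta(2,2)
    fraction of the local charted depth.
    """
    config.validate()
    _, env, _ = grids
    rng = config.rng("dives")
    dives = []
    for tr in truths:
        g = np.where(np.isfinite(tr.gamma), tr.gamma, 0.5)
        lam = config.dive_rate * np.exp(config.dive_coupling * (g - 0.5))
        counts = rng.poisson(lam[:-1])  # one window per step interval
        for i, n in enumerate(counts):
            if n == 0:
                continue
            depth_col = float(abs(env.bathymetry_at(tr.lon[i], tr.lat[i])))
            offs = np.sort(rng.uniform(0, config.step_hours * 3600.0, n))
            maxd = np.maximum(depth_col * rng.beta(2.0, 2.0, n), 1.0)
            maxd = np.minimum(maxd, depth_col)
            meand = maxd * rng.uniform(0.4, 0.9, n)
            dur = rng.uniform(120.0, 600.0, n)
            bott = dur * rng.uniform(0.1, 0.5, n)
            for m in range(n):
                dives.append(DiveRecord(
                    tr.individual,
                    tr.times[i] + pd.Timedelta(seconds=float(offs[m])),
                    float(dur[m]), float(maxd[m]), float(meand[m]), float(bott[m]),
                ))
    return dives


# ---------------------------------------------------------------------------
# CSV I/O


def tracks_to_frame(raws: list) -> pd.DataFrame:
    rows = [
        pd.DataFrame({"id": r.individual, "date": r.times, "lc": r.quality,
                      "lon": r.lon, "lat": r.lat})
        for r in raws
    ]
    return pd.concat(rows, ignore_index=True)


def truth_to_frame(truths: list) -> pd.DataFrame:
    rows = []
    for t in truths:
        df = pd.DataFrame({"id": t.individual, "date": t.times, "lon": t.lon,
                           "lat": t.lat, "x_km": t.x_km, "y_km": t.y_km,
                           "gamma": t.gamma, "b0": t.b0})
        for name, v in t.covariates.items():
            df[name] = v
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def dives_to_frame(dives: list) -> pd.DataFrame:
    return pd.DataFrame({
        "id": [d.individual for d in dives],
        "start": [d.start for d in dives],
        "dur_s": [d.duration_s for d in dives],
        "max_dep_m": [d.max_depth_m for d in dives],
        "mean_dep_m": [d.mean_depth_m for d in dives],
        "bottom_s": [d.bottom_s for d in dives],
    })


def prey_to_frame(prey: PreyGrid) -> pd.DataFrame:
    recs = []
    ny, ns, nlat, nlon = prey.biomass.shape
    lon = prey.west + (np.arange(nlon) + 0.5) * prey.res
    lat = prey.south + (np.arange(nlat) + 0.5) * prey.res
    for yi, year in enumerate(prey.years):
        for si, sp in enumerate(prey.species):
            gl, gt = np.meshgrid(lon, lat)
            recs.append(pd.DataFrame({
                "lon": gl.ravel(), "lat": gt.ravel(), "year": year,
                "species": sp, "value": prey.biomass[yi, si].ravel(),
            }))
    return pd.concat(recs, ignore_index=True)


def ice_to_frame(ice: IceSeries) -> pd.DataFrame:
    return pd.DataFrame({"week_start": ice.week_start, "conc_pct": ice.concentration})


def frame_to_prey(df: pd.DataFrame) -> PreyGrid:
    """Rebuild a PreyGrid from its long-format CSV (lon/lat are centres)."""
    species = tuple(sorted(df["species"].unique(), key=list(SPECIES).index))
    years = tuple(sorted(int(y) for y in df["year"].unique()))
    lons = np.sort(df["lon"].unique())
    lats = np.sort(df["lat"].unique())
    res = float(np.round(lons[1] - lons[0], 6)) if len(lons) > 1 else 0.5
    west = float(lons[0] - res / 2.0)
    south = float(lats[0] - res / 2.0)
    biomass = np.zeros((len(years), len(species), len(lats), len(lons)))
    li = {v: i for i, v in enumerate(lats)}
    lj = {v: j for j, v in enumerate(lons)}
    yi = {v: i for i, v in enumerate(years)}
    si = {v: i for i, v in enumerate(species)}
    for row in df.itertuples(index=False):
        biomass[yi[int(row.year)], si[row.species], li[row.lat], lj[row.lon]] = row.value
    return PreyGrid(species, west, south, res, years, biomass)


def env_to_frames(env: EnvGrid) -> tuple:
    """(cells_df, seasonal_df): bathymetry + SST anomaly per cell, and the
    per-(year, month) SST seasonal means."""
    nlat, nlon = env.bathymetry.shape
    lon = env.west + (np.arange(nlon) + 0.5) * env.res
    lat = env.south + (np.arange(nlat) + 0.5) * env.res
    gl, gt = np.meshgrid(lon, lat)
    cells = pd.DataFrame({"lon": gl.ravel(), "lat": gt.ravel(),
                          "bathy_m": env.bathymetry.ravel(),
                          "sst_anom": env.sst_anom.ravel()})
    seasonal = pd.DataFrame(
        [{"year": y, "month": m, "sst_mean": v}
         for (y, m), v in sorted(env.sst_seasonal.items())])
    return cells, seasonal


def frames_to_env(cells: pd.DataFrame, seasonal: pd.DataFrame) -> EnvGrid:
    lons = np.sort(cells["lon"].unique())
    lats = np.sort(cells["lat"].unique())
    res = float(np.round(lons[1] - lons[0], 6))
    nlat, nlon = len(lats), len(lons)
    tab = cells.sort_values(["lat", "lon"])
    bathy = tab["bathy_m"].to_numpy().reshape(nlat, nlon)
    anom = tab["sst_anom"].to_numpy().reshape(nlat, nlon)
    sst = {(int(r.year), int(r.month)): float(r.sst_mean)
           for r in seasonal.itertuples(index=False)}
    return EnvGrid(float(lons[0] - res / 2.0), float(lats[0] - res / 2.0), res,
                   bathy, anom, sst)


def frame_to_raws(df: pd.DataFrame) -> list:
    out = []
    for ind, g in df.groupby("id", sort=True):
        g = g.sort_values("date")
        out.append(RawTrack(str(ind), pd.DatetimeIndex(pd.to_datetime(g["date"])),
                            g["lon"].to_numpy(), g["lat"].to_numpy(),
                            g["lc"].to_numpy(dtype=object)))
    return out


def frame_to_ice(df: pd.DataFrame) -> IceSeries:
    return IceSeries(pd.DatetimeIndex(pd.to_datetime(df["week_start"])),
                     df["conc_pct"].to_numpy(dtype=float))


def simulate_all(config: SimConfig):
    """Convenience wrapper: grids, movement, and dives in one call."""
    grids = gen_grids(config)
    truths, raws = simulate_movement(config, grids)
    dives = simulate_dives(config, truths, grids)
    return grids, truths, raws, dives


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    return replace(config, seed=int(seed))
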