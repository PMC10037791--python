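"""Track preparation: season windowing, segmentation, speed filter, SSM.

The chain mirrors standard Argos-telemetry practice: restrict to the
open-water season delimited by the 50% sea-ice concentration crossings,
split tracks at transmission gaps > 12 h, drop segments with < 50 fixes,
remove fixes implying speeds above a biological maximum (30 km/h), and
regularize each segment onto an exact 4-h lattice with a continuous-time
correlated random walk (CTCRW) state-space model: Ornstein-Uhlenbeck
velocity, integrated position, class-specific Gaussian observation error,
maximum-likelihood parameters, Rauch-Tung-Striebel smoothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .geo import TangentPlane
from .simdata import DEFAULT_OBS_SD, IceSeries, RawTrack

logger = logging.getLogger(__name__)

ICE_THRESHOLD = 50.0


class NoSeasonError(ValueError):
    """The ice series never crosses 50% in the required direction."""


class UnsortedFixesError(ValueError):
    """Fix timestamps are not strictly increasing."""


class SsmConvergenceError(RuntimeError):
    """The CTCRW likelihood optimization failed to converge."""


@dataclass(frozen=True)
class Season:
    """Open-water season: break-up to freeze-up, fractional dates."""

    year: int
    breakup: pd.Timestamp
    freezeup: pd.Timestamp

    @property
    def breakup_doy(self) -> float:
        """Fractional day of year of break-up (Jan 1 00:00 = day 0)."""
        return _doy(self.breakup, self.year)

    @property
    def freezeup_doy(self) -> float:
        return _doy(self.freezeup, self.year)


def _doy(ts: pd.Timestamp, year: int) -> float:
    return (ts - pd.Timestamp(f"{year}-01-01")).total_seconds() / 86400.0


@dataclass
class Segment:
    """A contiguous run of fixes from one individual."""

    seg_id: str
    individual: str
    times: pd.DatetimeIndex
    lon: np.ndarray
    lat: np.ndarray
    quality: np.ndarray

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class RegularTrack:
    """SSM-estimated positions on an exact step lattice, with SDs."""

    seg_id: str
    individual: str
    times: pd.DatetimeIndex
    lon: np.ndarray
    lat: np.ndarray
    x_km: np.ndarray
    y_km: np.ndarray
    sd_km: np.ndarray


# ---------------------------------------------------------------------------
# season from ice


def season_bounds(ice: IceSeries, threshold: float = ICE_THRESHOLD) -> Season:
    """Break-up and freeze-up dates from a weekly ice series.

    Break-up is the linearly interpolated instant of the last downward
    crossing of the threshold after which concentration stays below it
    until the freeze-up ascent; freeze-up is the symmetric upward crossing
    after which concentration stays above the threshold to the end of the
    series.  A sample exactly at the threshold counts as the crossing
    point.
    """
    c = np.asarray(ice.concentration, dtype=float)
    t = ice.week_start
    if len(c) < 2:
        raise NoSeasonError("ice series too short")

    # freeze-up: c[j] < thr <= c[j+1] with everything after j staying >= thr
    freeze_j = None
    for j in range(len(c) - 2, -1, -1):
        if c[j] < threshold <= c[j + 1]:
            if np.all(c[j + 1:] >= threshold):
                freeze_j = j
            break
    if freeze_j is None:
        raise NoSeasonError("no sustained upward crossing (freeze-up) found")

    # break-up: c[i] >= thr > c[i+1] with everything in (i, freeze_j] below thr
    break_i = None
    for i in range(freeze_j - 1, -1, -1):
        if c[i] >= threshold > c[i + 1]:
            if np.all(c[i + 1:freeze_j + 1] < threshold):
                break_i = i
            break
    if break_i is None:
        raise NoSeasonError("no sustained downward crossing (break-up) found")

    breakup = _interp_crossing(t[break_i], t[break_i + 1], c[break_i], c[break_i + 1], threshold)
    freezeup = _interp_crossing(t[freeze_j], t[freeze_j + 1], c[freeze_j], c[freeze_j + 1], threshold)
    return Season(year=int(t[0].year), breakup=breakup, freezeup=freezeup)


def _interp_crossing(t0, t1, c0, c1, thr) -> pd.Timestamp:
    frac = 0.0 if c0 == c1 else (c0 - thr) / (c0 - c1)
    return t0 + frac * (t1 - t0)


def window_to_season(raw: RawTrack, season: Season) -> RawTrack:
    """Keep only fixes within [break-up, freeze-up]."""
    keep = (raw.times >= season.breakup) & (raw.times <= season.freezeup)
    return RawTrack(raw.individual, raw.times[keep], raw.lon[keep], raw.lat[keep],
                    raw.quality[keep])


# ---------------------------------------------------------------------------
# segmentation and speed filter


def split_and_filter(raw: RawTrack, gap_h: float = 12.0, min_fixes: int = 50) -> list:
    """Split at transmission gaps strictly greater than ``gap_h`` hours and
    drop segments with fewer than ``min_fixes`` fixes."""
    dt = np.diff(raw.times.asi8) / 3.6e12  # hours
    if np.any(dt <= 0):
        raise UnsortedFixesError(f"{raw.individual}: timestamps not strictly increasing")
    cuts = np.nonzero(dt > gap_h)[0] + 1
    bounds = np.concatenate([[0], cuts, [len(raw.times)]])
    segments = []
    n_seg = 0
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < min_fixes:
            continue
        seg = Segment(f"{raw.individual}_s{n_seg:02d}", raw.individual,
                      raw.times[a:b], raw.lon[a:b], raw.lat[a:b], raw.quality[a:b])
        segments.append(seg)
        n_seg += 1
    return segments


def speed_filter(seg: Segment, vmax_kmh: float = 30.0) -> Segment:
    """Drop fixes whose speed from the previous retained fix exceeds vmax.

    Greedy forward pass; the first fix is always retained, so every
    consecutive pair of retained fixes obeys the limit by construction
    (hence idempotence).
    """
    plane = TangentPlane(float(np.mean(seg.lon)), float(np.mean(seg.lat)))
    x, y = plane.to_km(seg.lon, seg.lat)
    th = seg.times.asi8 / 3.6e12
    keep = [0]
    last = 0
    for i in range(1, len(seg)):
        dist = float(np.hypot(x[i] - x[last], y[i] - y[last]))
        dt = th[i] - th[last]
        if dt <= 0 or dist / dt <= vmax_kmh:
            keep.append(i)
            last = i
    keep = np.asarray(keep)
    return Segment(seg.seg_id, seg.individual, seg.times[keep], seg.lon[keep],
                   seg.lat[keep], seg.quality[keep])


# ---------------------------------------------------------------------------
# CTCRW state-space regularization


def _ctcrw_mats(beta: float, sigma2: float, dt: np.ndarray):
    """Exact discretization of the OU-velocity CRW over steps dt (hours).

    State per coordinate is (position, velocity); returns stacked 2x2
    transition matrices F and innovation covariances Q for each interval.
    """
    e = np.exp(-beta * dt)
    e2 = np.exp(-2.0 * beta * dt)
    F = np.zeros((len(dt), 2, 2))
    F[:, 0, 0] = 1.0
    F[:, 0, 1] = (1.0 - e) / beta
    F[:, 1, 1] = e
    Q = np.zeros((len(dt), 2, 2))
    Q[:, 1, 1] = sigma2 / (2.0 * beta) * (1.0 - e2)
    Q[:, 0, 1] = Q[:, 1, 0] = sigma2 / (2.0 * beta**2) * (1.0 - 2.0 * e + e2)
    Q[:, 0, 0] = sigma2 / beta**2 * (dt - 2.0 * (1.0 - e) / beta + (1.0 - e2) / (2.0 * beta))
    return F, Q


def _kalman(times_h, obs_x, obs_y, obs_var, beta, sigma2, want_smooth=False):
    """Kalman filter (and optional RTS smoother) for the 2-coordinate CTCRW.

    The two coordinates share the (position, velocity) covariance recursion
    because their process and observation variances are identical; means
    are carried as columns of a (2, 2) matrix [state x coordinate].
    ``obs_var`` is NaN at prediction-only time points.
    """
    n = len(times_h)
    dt = np.diff(times_h)
    F, Q = _ctcrw_mats(beta, sigma2, np.maximum(dt, 1e-9))

    m = np.zeros((2, 2))
    first = int(np.nonzero(np.isfinite(obs_var))[0][0])
    m[0, 0], m[0, 1] = obs_x[first], obs_y[first]
    P = np.diag([50.0**2, max(sigma2 / (2.0 * beta), 1e-6)])

    H = np.array([[1.0, 0.0]])
    ll = 0.0
    mf = np.zeros((n, 2, 2))
    Pf = np.zeros((n, 2, 2))
    mp = np.zeros((n, 2, 2))
    Pp = np.zeros((n, 2, 2))
    for i in range(n):
        if i > 0:
            m = F[i - 1] @ m
            P = F[i - 1] @ P @ F[i - 1].T + Q[i - 1]
        mp[i], Pp[i] = m, P
        if np.isfinite(obs_var[i]):
            S = P[0, 0] + obs_var[i]
            innov = np.array([obs_x[i] - m[0, 0], obs_y[i] - m[0, 1]])
            ll += -0.5 * (2.0 * np.log(2.0 * np.pi * S) + (innov @ innov) / S)
            K = P[:, 0] / S  # gain column (2,)
            m = m + np.outer(K, innov)
            P = P - np.outer(K, P[0, :])
            P = 0.5 * (P + P.T)
        mf[i], Pf[i] = m, P
    if not want_smooth:
        return ll
    # RTS backward pass
    ms = mf.copy()
    Ps = Pf.copy()
    for i in range(n - 2, -1, -1):
        G = Pf[i] @ F[i].T @ np.linalg.inv(Pp[i + 1])
        ms[i] = mf[i] + G @ (ms[i + 1] - mp[i + 1])
        Ps[i] = Pf[i] + G @ (Ps[i + 1] - Pp[i + 1]) @ G.T
    return ll, ms, Ps


def regularize_ssm(
    seg: Segment,
    step_h: float = 4.0,
    plane: TangentPlane | None = None,
    obs_sd_by_class: dict | None = None,
    fixed_obs_sd: float | None = None,
    estimate_scale: bool = True,
) -> RegularTrack:
    """Fit the CTCRW by ML and return smoothed positions on the step lattice.

    The lattice starts at the first fix time rounded up to the next whole
    hour and ends at the last fix.  Per-class observation-error SD ratios
    are fixed (defaults as in the simulator); a single overall error scale
    is estimated jointly with the OU parameters unless ``fixed_obs_sd``
    pins the SD for every fix.

    Raises :class:`SsmConvergenceError` when the likelihood optimization
    fails; callers processing many segments should catch it, log, and drop
    the segment.
    """
    if len(seg) < 4:
        raise SsmConvergenceError(f"{seg.seg_id}: too few fixes for the SSM")
    if plane is None:
        plane = TangentPlane(float(np.mean(seg.lon)), float(np.mean(seg.lat)))
    sds = dict(DEFAULT_OBS_SD if obs_sd_by_class is None else obs_sd_by_class)
    x, y = plane.to_km(seg.lon, seg.lat)
    t0 = seg.times[0].ceil("h")
    n_lat = int(np.floor((seg.times[-1] - t0).total_seconds() / 3600.0 / step_h)) + 1
    if n_lat < 3:
        raise SsmConvergenceError(f"{seg.seg_id}: segment shorter than the lattice step")
    lattice = t0 + pd.to_timedelta(np.arange(n_lat) * step_h, unit="h")

    # merged time base: observations plus prediction-only lattice points
    obs_h = (seg.times - t0).total_seconds().to_numpy() / 3600.0
    lat_h = np.arange(n_lat) * step_h
    all_h = np.concatenate([obs_h, lat_h])
    kind = np.concatenate([np.arange(len(obs_h)), np.full(n_lat, -1)])
    order = np.argsort(all_h, kind="stable")
    all_h = all_h[order]
    kind = kind[order]

    ox = np.full(len(all_h), np.nan)
    oy = np.full(len(all_h), np.nan)
    base_var = np.full(len(all_h), np.nan)
    is_obs = kind >= 0
    ox[is_obs] = x[kind[is_obs]]
    oy[is_obs] = y[kind[is_obs]]
    if fixed_obs_sd is not None:
        base_var[is_obs] = float(fixed_obs_sd) ** 2
    else:
        cls_sd = np.array([sds.get(str(c), max(sds.values())) for c in seg.quality])
        base_var[is_obs] = cls_sd[kind[is_obs]] ** 2

    est_scale = estimate_scale and fixed_obs_sd is None

    def nll(theta):
        beta = np.exp(theta[0])
        sigma2 = np.exp(theta[1])
        scale2 = np.exp(theta[2]) if est_scale else 1.0
        ll = _kalman(all_h, ox, oy, base_var * scale2, beta, sigma2)
        return -ll if np.isfinite(ll) else 1e12

    x0 = [np.log(0.5), np.log(1.0)] + ([0.0] if est_scale else [])
    res = minimize(nll, x0, method="L-BFGS-B",
                   bounds=[(-6, 4), (-8, 8)] + ([(-4, 4)] if est_scale else []))
    if not np.all(np.isfinite(res.x)) or not np.isfinite(res.fun):
        raise SsmConvergenceError(f"{seg.seg_id}: CTCRW likelihood optimization failed")
    beta = np.exp(res.x[0])
    sigma2 = np.exp(res.x[1])
    scale2 = np.exp(res.x[2]) if est_scale else 1.0

    _, ms, Ps = _kalman(all_h, ox, oy, base_var * scale2, beta, sigma2, want_smooth=True)
    # pick the lattice entries (prediction points come after coincident obs
    # in the stable sort, so their filtered state includes that fix)
    sel = np.nonzero(kind == -1)[0]
    xs = ms[sel, 0, 0]
    ys = ms[sel, 0, 1]
    sd = np.sqrt(np.maximum(Ps[sel, 0, 0], 0.0))
    lon, lat = plane.to_lonlat(xs, ys)
    return RegularTrack(seg.seg_id, seg.individual, pd.DatetimeIndex(lattice),
                        lon, lat, xs, ys, sd)


def regularize_many(segments: list, step_h: float = 4.0,
                    plane: TangentPlane | None = None, **kwargs) -> list:
    """Regularize a batch of segments, dropping (and logging) failures."""
    out = []
    for seg in segments:
        try:
            out.append(regularize_ssm(seg, step_h=step_h, plane=plane, **kwargs))
        except SsmConvergenceError as exc:
            logger.warning("dropping segment: %s", exc)
    return out


def regular_to_frame(tracks: list) -> pd.DataFrame:
    rows = [
        pd.DataFrame({"seg_id": t.seg_id, "id": t.individual, "date": t.times,
                      "lon": t.lon, "lat": t.lat, "x_km": t.x_km, "y_km": t.y_km,
                      "sd_km": t.sd_km})
        for t in tracks
    ]
    return pd.concat(rows, ignore_index=True)
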