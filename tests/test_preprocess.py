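"""Season bounds, segmentation, speed filter, and SSM regularization."""

import numpy as np
import pandas as pd
import pytest

from conftest import weekly_ice
from persistforage import preprocess, simdata
from persistforage.preprocess import (
    NoSeasonError,
    Segment,
    UnsortedFixesError,
    season_bounds,
    speed_filter,
    split_and_filter,
)


def make_raw(times, lon=None, lat=None, ind="a"):
    times = pd.DatetimeIndex(times)
    n = len(times)
    lon = np.full(n, -80.0) if lon is None else np.asarray(lon, float)
    lat = np.full(n, 57.0) if lat is None else np.asarray(lat, float)
    return simdata.RawTrack(ind, times, lon, lat, np.array(["3"] * n, dtype=object))


# ---------------------------------------------------------------------------
# season


def test_breakup_interpolates_linearly_between_weeks():
    # 80% then 30%: crossing of 50% at (80-50)/(80-30) of the 7-day gap = 4.2 d
    ice = weekly_ice([80, 30, 20, 10, 10, 20, 40, 60, 70, 80])
    season = season_bounds(ice)
    expected = ice.week_start[0] + pd.Timedelta(days=4.2)
    assert abs((season.breakup - expected).total_seconds()) < 1.0


def test_freezeup_interpolates_symmetrically():
    ice = weekly_ice([80, 30, 20, 10, 10, 20, 30, 80, 80, 80])
    season = season_bounds(ice)
    # ascent 30 -> 80 over week 6..7: 50% reached at (50-30)/(80-30)*7 = 2.8 d
    expected = ice.week_start[6] + pd.Timedelta(days=2.8)
    assert abs((season.freezeup - expected).total_seconds()) < 1.0
    assert season.breakup < season.freezeup


def test_sample_exactly_at_threshold_is_the_crossing():
    ice = weekly_ice([80, 50, 20, 10, 10, 60, 80, 80])
    season = season_bounds(ice)
    assert season.breakup == ice.week_start[1]


def test_blip_uses_last_qualifying_downward_crossing():
    # mid-season refreeze above 50%: break-up must be the later crossing
    ice = weekly_ice([80, 30, 60, 20, 10, 10, 60, 80, 80])
    season = season_bounds(ice)
    assert season.breakup > ice.week_start[2]


def test_no_crossing_raises():
    with pytest.raises(NoSeasonError):
        season_bounds(weekly_ice([80, 80, 80, 80]))
    with pytest.raises(NoSeasonError):
        season_bounds(weekly_ice([80, 30, 20, 10, 10]))  # never refreezes


# ---------------------------------------------------------------------------
# segmentation


def test_split_at_gaps_and_drop_short_segments():
    # 200 hourly fixes; 13-h gap after fix 60 and 14-h gap after fix 140
    t0 = pd.Timestamp("2009-08-01")
    times = [t0 + pd.Timedelta(hours=i) for i in range(60)]
    t1 = times[-1] + pd.Timedelta(hours=13)
    times += [t1 + pd.Timedelta(hours=i) for i in range(80)]
    t2 = times[-1] + pd.Timedelta(hours=14)
    times += [t2 + pd.Timedelta(hours=i) for i in range(60)]
    segs = split_and_filter(make_raw(times), gap_h=12, min_fixes=50)
    assert [len(s) for s in segs] == [60, 80, 60]
    assert len({s.seg_id for s in segs}) == 3
    # partition: every fix in exactly one segment
    assert sum(len(s) for s in segs) == 200


def test_gap_of_exactly_twelve_hours_does_not_split():
    t0 = pd.Timestamp("2009-08-01")
    times = [t0 + pd.Timedelta(hours=i) for i in range(60)]
    start2 = times[-1] + pd.Timedelta(hours=12.0)
    times += [start2 + pd.Timedelta(hours=i) for i in range(60)]
    segs = split_and_filter(make_raw(times), gap_h=12, min_fixes=50)
    assert [len(s) for s in segs] == [120]


def test_short_segment_dropped():
    t0 = pd.Timestamp("2009-08-01")
    times = [t0 + pd.Timedelta(hours=i) for i in range(49)]
    assert split_and_filter(make_raw(times), gap_h=12, min_fixes=50) == []


def test_unsorted_input_rejected_not_resorted():
    t0 = pd.Timestamp("2009-08-01")
    times = [t0, t0 + pd.Timedelta(hours=2), t0 + pd.Timedelta(hours=1)]
    with pytest.raises(UnsortedFixesError):
        split_and_filter(make_raw(times), gap_h=12, min_fixes=1)


def test_season_windowing_keeps_only_open_water_fixes():
    ice = weekly_ice([80, 30, 20, 10, 10, 20, 30, 80, 80, 80])
    season = season_bounds(ice)
    t = pd.DatetimeIndex([season.breakup - pd.Timedelta(days=2),
                          season.breakup + pd.Timedelta(days=2),
                          season.freezeup + pd.Timedelta(days=2)])
    win = preprocess.window_to_season(make_raw(t), season)
    assert len(win.times) == 1


# ---------------------------------------------------------------------------
# speed filter


def hourly_track(xy_km):
    plane = simdata.SimConfig().plane()
    lon, lat = plane.to_lonlat(np.array([p[0] for p in xy_km]),
                               np.array([p[1] for p in xy_km]))
    t0 = pd.Timestamp("2009-08-01")
    times = pd.DatetimeIndex([t0 + pd.Timedelta(hours=i) for i in range(len(xy_km))])
    return Segment("a_s00", "a", times, lon, lat, np.array(["3"] * len(xy_km), dtype=object))


def test_speed_filter_noop_when_all_speeds_legal():
    seg = hourly_track([(0, 0), (5, 0), (10, 0), (15, 0)])
    out = speed_filter(seg, vmax_kmh=30)
    assert len(out) == len(seg)
    assert np.array_equal(out.lon, seg.lon)


def test_speed_filter_removes_single_outlier():
    seg = hourly_track([(0, 0), (5, 0), (105, 0), (10, 0), (15, 0)])
    out = speed_filter(seg, vmax_kmh=30)
    assert len(out) == 4
    assert 105.0 not in np.round(simdata.SimConfig().plane().to_km(out.lon, out.lat)[0], 6)


def test_speed_filter_idempotent_and_bounded():
    rng = np.random.default_rng(2)
    pts = np.cumsum(rng.normal(0, 20, (50, 2)), axis=0)
    seg = hourly_track([tuple(p) for p in pts])
    once = speed_filter(seg, vmax_kmh=30)
    twice = speed_filter(once, vmax_kmh=30)
    assert np.array_equal(once.lon, twice.lon)
    plane = simdata.SimConfig().plane()
    x, y = plane.to_km(once.lon, once.lat)
    th = once.times.asi8 / 3.6e12
    speeds = np.hypot(np.diff(x), np.diff(y)) / np.diff(th)
    assert np.all(speeds <= 30 + 1e-9)


def test_infinite_vmax_is_identity():
    seg = hourly_track([(0, 0), (500, 0), (0, 0)])
    out = speed_filter(seg, vmax_kmh=np.inf)
    assert len(out) == 3


# ---------------------------------------------------------------------------
# SSM regularization


def test_lattice_is_exact_and_anchored_at_next_whole_hour():
    cfg = simdata.SimConfig(n_individuals=1, steps_per_track=60, seed=3)
    grids = simdata.gen_grids(cfg)
    _, raws = simdata.simulate_movement(cfg, grids)
    seg = split_and_filter(raws[0], min_fixes=30)[0]
    reg = preprocess.regularize_ssm(speed_filter(seg), step_h=4.0, plane=cfg.plane())
    dt = np.diff(reg.times.asi8) / 3.6e12
    assert np.allclose(dt, 4.0)
    assert reg.times[0] == seg.times[0].ceil("h")
    assert np.all(np.isfinite(reg.x_km)) and np.all(np.isfinite(reg.sd_km))


def test_noiseless_lattice_observations_reproduced_to_micrometres():
    cfg = simdata.SimConfig(
        n_individuals=1, steps_per_track=60, seed=3, mean_fix_interval_h=None,
        gap_rate=0.0, obs_error_sd_by_class={c: 0.0 for c in simdata.ARGOS_CLASSES})
    grids = simdata.gen_grids(cfg)
    truths, raws = simdata.simulate_movement(cfg, grids)
    seg = split_and_filter(raws[0], min_fixes=30)[0]
    reg = preprocess.regularize_ssm(seg, step_h=4.0, plane=cfg.plane(),
                                    fixed_obs_sd=1e-6)
    x, y = cfg.plane().to_km(raws[0].lon, raws[0].lat)
    err = np.hypot(reg.x_km - x[: len(reg.x_km)], reg.y_km - y[: len(reg.y_km)])
    assert np.max(err) < 1e-6


def test_smoother_beats_raw_observations():
    cfg = simdata.SimConfig(
        n_individuals=3, steps_per_track=80, seed=7,
        obs_error_sd_by_class={c: 1.0 for c in simdata.ARGOS_CLASSES})
    grids = simdata.gen_grids(cfg)
    truths, raws = simdata.simulate_movement(cfg, grids)
    plane = cfg.plane()
    wins = total = 0
    for tr, raw in zip(truths, raws):
        for seg in split_and_filter(raw, 12, 50):
            seg = speed_filter(seg)
            reg = preprocess.regularize_ssm(seg, 4.0, plane=plane,
                                            obs_sd_by_class=cfg.obs_error_sd_by_class)
            tt = tr.times.asi8 / 3.6e12
            lt = reg.times.asi8 / 3.6e12
            tx = np.interp(lt, tt, tr.x_km)
            ty = np.interp(lt, tt, tr.y_km)
            oh = raw.times.asi8 / 3.6e12
            ox, oy = plane.to_km(raw.lon, raw.lat)
            rmse_s = np.sqrt(np.mean((reg.x_km - tx) ** 2 + (reg.y_km - ty) ** 2))
            rmse_r = np.sqrt(np.mean((np.interp(lt, oh, ox) - tx) ** 2
                                     + (np.interp(lt, oh, oy) - ty) ** 2))
            wins += rmse_s < rmse_r
            total += 1
    assert total >= 3 and wins == total
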