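"""Dive detection, phases, fluking/buoyancy, breaths, diel, hourly rates."""

from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd
import pytest

import whalekin as wk
from whalekin import dive_phases as dph
from whalekin.tag_io import CalibrationError, Channel, Deployment


def _channel(z, rate=10.0):
    return Channel(np.asarray(z, dtype=float), rate, "m")


def _trapezoid_dive(depth=50.0, rate=10.0, t_desc=30.0, t_bot=40.0,
                    t_asc=30.0, pad=20.0):
    segs = [np.zeros(int(pad * rate)),
            np.linspace(0, depth, int(t_desc * rate)),
            np.full(int(t_bot * rate), depth),
            np.linspace(depth, 0, int(t_asc * rate)),
            np.zeros(int(pad * rate))]
    return _channel(np.concatenate(segs), rate)


class TestDetectDives:
    def test_below_threshold_ignored(self):
        assert dph.detect_dives(_trapezoid_dive(depth=9.5)) == []

    def test_single_dive_found(self):
        dives = dph.detect_dives(_trapezoid_dive(depth=12.0))
        assert len(dives) == 1
        assert dives[0].max_depth == pytest.approx(12.0, abs=0.1)

    def test_simulator_dives_found_with_tight_boundaries(self, demo_sim):
        sensors, truth = demo_sim
        cfg = truth.config
        depth_true = Channel(truth.depth, truth.rate, "m")
        dives = dph.detect_dives(depth_true)
        tt = truth.dive_table()
        assert len(dives) == len(tt)
        # boundary = first/last crossing of the 2 m surface threshold
        for d in dives:
            i0 = int(round(d.t_start * truth.rate))
            assert abs(truth.depth[i0] - 2.0) < 1.0

    def test_dives_disjoint_and_inside_record(self, demo_result):
        dives = sorted(demo_result.dives, key=lambda d: d.t_start)
        dur = demo_result.depth.data.size / demo_result.rate
        for a, b in zip(dives[:-1], dives[1:]):
            assert a.t_end < b.t_start
        assert dives[0].t_start >= 0
        assert dives[-1].t_end <= dur


class TestSegmentPhases:
    def test_trapezoid_corners_recovered(self):
        ch = _trapezoid_dive(depth=100.0)
        dive = dph.detect_dives(ch)[0]
        de, asc = dph.segment_phases(dive, ch)
        # corners at 20+30 = 50 s and 20+30+40 = 90 s; band entry at 85 m
        assert de == pytest.approx(50.0, abs=5.0)
        assert asc == pytest.approx(90.0, abs=5.0)
        assert de < asc

    def test_v_dive_zero_bottom(self):
        ch = _trapezoid_dive(depth=60.0, t_bot=0.1)
        dive = dph.detect_dives(ch)[0]
        de, asc = dph.segment_phases(dive, ch, tol_band=0.0)
        assert asc - de <= 0.2 + 1e-9

    def test_simulator_boundaries_within_five_seconds(self, demo_sim):
        # rendered dives have sharp corners, so a tight bottom band matches
        # the true leveling points; the 15 % default suits gradual field dives
        _, truth = demo_sim
        depth = Channel(truth.depth, truth.rate, "m")
        dives = dph.detect_dives(depth)
        ev = truth.events
        true_de = ev.loc[ev.event_type == "descent_end", "t_start"].to_numpy()
        true_as = ev.loc[ev.event_type == "ascent_start", "t_start"].to_numpy()
        for d in dives:
            de, asc = dph.segment_phases(d, depth, tol_band=0.02)
            assert np.min(np.abs(true_de - de)) < 5.0
            assert np.min(np.abs(true_as - asc)) < 5.0


class TestFlukingAndBuoyancy:
    def test_constructed_stroke_switch_point(self):
        rate = 10.0
        t = np.arange(int(200 * rate)) / rate
        z = np.concatenate([np.linspace(2, 100, 1000),
                            np.full(1000, 100.0)])[:t.size]
        depth = _channel(z, rate)
        stroke = np.where(t < 60.0, 0.05 * np.sin(2 * np.pi * 0.5 * t), 0.0)
        dyn = np.column_stack([stroke, np.zeros_like(t), np.zeros_like(t)])
        dive = dph.DiveRecord(0, 0.0, t[-1], 100.0,
                              descent_end_t=100.0, ascent_start_t=t[-1])
        mask, onsets = dph.detect_fluking(dyn, rate, [dive], depth,
                                          window_s=2.0)
        switch = np.flatnonzero(mask)[-1] / rate
        assert switch == pytest.approx(60.0, abs=1.0)

    def test_all_glide_dive_excluded(self, caplog):
        rate = 10.0
        z = np.concatenate([np.linspace(2, 60, 300), np.linspace(60, 2, 300)])
        depth = _channel(z, rate)
        dive = dph.DiveRecord(0, 0.0, 59.9, 60.0, descent_end_t=30.0,
                              ascent_start_t=30.0)
        dyn = np.zeros((z.size, 3))
        _, onsets = dph.detect_fluking(dyn, rate, [dive], depth)
        assert len(onsets) == 0

    def test_simulator_onset_depth_recovered(self, demo_result):
        med_d = np.nanmedian(demo_result.onsets["descent_onset_depth"])
        med_a = np.nanmedian(demo_result.onsets["ascent_onset_depth"])
        assert abs(med_d - 26.0) <= 3.0
        assert abs(med_a - 26.0) <= 3.0

    def test_neutral_depth_trivial_cases(self):
        same = pd.DataFrame({"dive_id": range(4),
                             "descent_onset_depth": [30.0] * 4,
                             "ascent_onset_depth": [30.0] * 4})
        assert dph.estimate_neutral_buoyancy(same).neutral_depth == 30.0
        split = pd.DataFrame({"dive_id": range(4),
                              "descent_onset_depth": [20.0] * 4,
                              "ascent_onset_depth": [40.0] * 4})
        assert dph.estimate_neutral_buoyancy(split).neutral_depth == 30.0

    def test_neutral_depth_needs_three_dives(self):
        few = pd.DataFrame({"dive_id": [0, 1],
                            "descent_onset_depth": [20.0, 22.0],
                            "ascent_onset_depth": [30.0, 28.0]})
        with pytest.raises(CalibrationError):
            dph.estimate_neutral_buoyancy(few)

    def test_neutral_depth_within_contributing_range(self, demo_result):
        b = demo_result.buoyancy
        lo = min(b.descent_cessation_depths.min(),
                 b.ascent_cessation_depths.min())
        hi = max(b.descent_cessation_depths.max(),
                 b.ascent_cessation_depths.max())
        assert lo <= b.neutral_depth <= hi

    def test_asymmetric_onsets_recovered(self, asym_result):
        res = asym_result
        assert abs(np.nanmedian(res.onsets["descent_onset_depth"]) - 24) <= 3
        assert abs(np.nanmedian(res.onsets["ascent_onset_depth"]) - 38) <= 3
        assert abs(res.buoyancy.neutral_depth - 31.0) <= 3.0


class TestBreaths:
    def test_flat_surface_trace_with_pulses(self):
        rate = 10.0
        depth = _channel(np.zeros(600), rate)
        env = np.zeros(600)
        for t in (10.0, 25.0, 50.0):
            env[int(t * rate)] = 1.0
        breaths = dph.detect_breaths(depth, Channel(env, rate, "au"))
        assert breaths.size == 3
        np.testing.assert_allclose(sorted(breaths), [10.0, 25.0, 50.0],
                                   atol=0.5)

    def test_deep_segment_has_no_breaths(self):
        depth = _channel(np.full(600, 100.0))
        assert dph.detect_breaths(depth).size == 0
        env = np.zeros(600)
        env[100] = 1.0
        assert dph.detect_breaths(depth, Channel(env, 10.0, "au")).size == 0

    def test_simulator_recall_precision(self, demo_sim, demo_result):
        from conftest import match_events
        _, truth = demo_sim
        tb = truth.events.loc[truth.events.event_type == "breath",
                              "t_start"].to_numpy()
        r, p = match_events(tb, demo_result.breath_times, tol=1.5)
        assert r >= 0.95 and p >= 0.95


class TestDiel:
    def _dep(self):
        tz = timezone(timedelta(hours=-5))
        return Deployment("w", datetime(2018, 7, 3, 8, 0, tzinfo=tz),
                          datetime(2018, 7, 4, 8, 0, tzinfo=tz),
                          28.757, -85.705, 9.2, -5.0)

    def test_table_override(self):
        table = pd.DataFrame({"sunrise_twilight": [6 * 3600.0],
                              "sunset_twilight": [20 * 3600.0]})
        labels = dph.assign_diel(np.array([21 * 3600.0]), None, table)
        assert labels[0] == "night"
        assert dph.assign_diel(np.array([12 * 3600.0]), None, table)[0] == "day"

    def test_boundary_elevation_counts_as_day(self):
        dep = self._dep()
        elev = dph.solar_elevation_deg(
            dep.tag_on.astimezone(timezone.utc), dep.latitude, dep.longitude)
        # threshold set exactly at the current elevation: not "< threshold"
        labels = dph.assign_diel(np.array([0.0]), dep, threshold_deg=elev)
        assert labels[0] == "day"

    def test_equator_equinox_noon_is_high_day(self):
        when = datetime(2021, 3, 20, 12, 0, tzinfo=timezone.utc)
        elev = dph.solar_elevation_deg(when, 0.0, 0.0)
        assert elev > 80.0

    def test_midnight_is_night(self):
        dep = self._dep()
        labels = dph.assign_diel(np.array([17 * 3600.0]), dep)  # 01:00 local
        assert labels[0] == "night"

    def test_missing_inputs_raise(self):
        with pytest.raises(dph.ParameterError):
            dph.assign_diel(np.array([0.0]))


class TestHourlyRates:
    def _dep(self, hours=10.5):
        tz = timezone.utc
        t0 = datetime(2018, 7, 3, 6, 0, tzinfo=tz)
        return Deployment("w", t0, t0 + timedelta(hours=hours), 28.0, -85.0,
                          9.2, 0.0)

    def _day_table(self):
        return pd.DataFrame({"sunrise_twilight": [-1e7],
                             "sunset_twilight": [1e9]})

    def test_uniform_events_median_one(self):
        dep = self._dep(10.0)
        events = np.arange(10) * 3600.0 + 1800.0
        out = dph.hourly_rates(events, dep, self._day_table())
        row = out[out.diel == "day"].iloc[0]
        assert row["median"] == 1.0 and row["min"] == 1 and row["max"] == 1

    def test_partial_hour_events_discarded(self):
        tz = timezone.utc
        t0 = datetime(2018, 7, 3, 6, 30, tzinfo=tz)
        dep = Deployment("w", t0, t0 + timedelta(hours=10), 28.0, -85.0,
                         9.2, 0.0)
        # one event in the discarded first half hour, none later
        out = dph.hourly_rates(np.array([600.0]), dep, self._day_table())
        assert out["median"].max() == 0.0

    def test_matches_brute_force_buckets(self):
        rng = np.random.default_rng(3)
        dep = self._dep(12.0)
        events = np.sort(rng.uniform(0, dep.duration_s, 200))
        out = dph.hourly_rates(events, dep, self._day_table())
        # brute force: 12 full clock hours (deployment starts on the hour)
        counts = [((events >= a) & (events < a + 3600)).sum()
                  for a in np.arange(0, 12) * 3600.0]
        assert out["n_hours"].sum() == len(counts)
        assert out[out.diel == "day"].iloc[0]["median"] == np.median(counts)
        # conservation: per-hour counts sum to all events in complete hours
        assert sum(counts) == ((events >= 0) & (events < 12 * 3600)).sum()
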