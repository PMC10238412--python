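"""Circling, lunges, circle-lunge linking, context, event profiles."""

import numpy as np
import pytest

from conftest import (match_events, oracle_circles, oracle_link,
                      random_heading_track)
from whalekin import foraging_events as fev


RATE = 10.0


def _ramp(rot_deg, dur_s, rate=RATE):
    return np.deg2rad(np.linspace(0.0, rot_deg, int(dur_s * rate)))


class TestDetectCircling:
    def test_smooth_200_degree_ramp(self):
        heading = np.mod(np.concatenate([np.zeros(100), _ramp(200, 30),
                                         np.full(100, np.deg2rad(200))]),
                         2 * np.pi)
        pitch = np.zeros_like(heading)
        out = fev.detect_circling(heading, pitch, RATE, pause_rate=0)
        assert len(out) == 1
        assert out[0].total_rotation == pytest.approx(200.0, abs=1.0)
        assert out[0].duration == pytest.approx(30.0, abs=1.0)

    def test_90_degree_ramp_is_no_circle(self):
        heading = np.mod(_ramp(90, 30), 2 * np.pi)
        out = fev.detect_circling(heading, np.zeros_like(heading), RATE,
                                  pause_rate=0)
        assert out == []

    def test_steep_pitch_blocks_circles(self):
        heading = np.mod(_ramp(220, 30), 2 * np.pi)
        pitch = np.full_like(heading, np.deg2rad(88.0))
        out = fev.detect_circling(heading, pitch, RATE, pause_rate=0)
        assert out == []

    def test_invariant_to_full_turn_offsets(self):
        rng = np.random.default_rng(0)
        h = random_heading_track(rng)
        p = np.zeros_like(h)
        base = fev.detect_circling(h, p, RATE, pause_rate=0)
        shifted = fev.detect_circling(h + 6 * 2 * np.pi, p, RATE, pause_rate=0)
        assert [(c.t_start, c.t_end, round(c.total_rotation, 9))
                for c in base] == \
               [(c.t_start, c.t_end, round(c.total_rotation, 9))
                for c in shifted]

    def test_mirrored_heading_negates_rotation(self):
        rng = np.random.default_rng(1)
        h = random_heading_track(rng)
        p = np.zeros_like(h)
        fwd = fev.detect_circling(h, p, RATE, pause_rate=0)
        rev = fev.detect_circling(np.mod(-h, 2 * np.pi), p, RATE, pause_rate=0)
        assert [(c.t_start, c.t_end) for c in fwd] == \
               [(c.t_start, c.t_end) for c in rev]
        for a, b in zip(fwd, rev):
            assert a.total_rotation == pytest.approx(-b.total_rotation,
                                                     abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            h = random_heading_track(rng, n=300)
            pitch = rng.uniform(-0.4, 0.4, h.size)
            pitch[rng.random(h.size) < 0.05] = np.deg2rad(87.0)  # mask holes
            got = fev.detect_circling(h, pitch, RATE, pause_rate=0)
            want = oracle_circles(h, pitch, RATE)
            got_t = [(round(c.t_start * RATE), round(c.t_end * RATE),
                      round(c.total_rotation, 6)) for c in got]
            want_t = [(a, b, round(r, 6)) for a, b, r in want]
            assert got_t == want_t

    def test_pause_splitting_blocks_accumulation(self):
        # two 120 deg same-direction turns separated by a 60 s standstill
        h = np.concatenate([_ramp(120, 20),
                            np.full(600, np.deg2rad(120)),
                            np.deg2rad(120) + _ramp(120, 20)])
        h = np.mod(h, 2 * np.pi)
        p = np.zeros_like(h)
        assert fev.detect_circling(h, p, RATE, pause_rate=0) != []   # merged
        assert fev.detect_circling(h, p, RATE) == []                  # split


class TestDetectLunges:
    def _pulse_speed(self, base=1.5, peak=5.6, rate=RATE):
        v = np.full(int(120 * rate), base)
        t = np.arange(v.size) / rate
        up = (t >= 60) & (t < 66)
        down = (t >= 66) & (t < 72)
        v[up] = np.interp(t[up], [60, 66], [base, peak])
        v[down] = np.interp(t[down], [66, 72], [peak, 0.8 * base])
        return v

    def test_constructed_pulse_detected(self):
        v = self._pulse_speed()
        out = fev.detect_lunges(v, RATE, abs_threshold=3.0)
        assert len(out) == 1
        assert out[0].peak_speed == pytest.approx(5.6, abs=0.05)
        assert out[0].t_peak == pytest.approx(66.0, abs=0.5)
        assert out[0].decel > 0
        assert out[0].peak_speed > out[0].pre_speed

    def test_constant_speed_has_no_lunges(self):
        out = fev.detect_lunges(np.full(1200, 2.0), RATE)
        assert out == []

    def test_simulator_recall_precision(self, demo_sim, demo_result):
        _, truth = demo_sim
        tl = truth.events.loc[truth.events.event_type == "lunge",
                              "t_start"].to_numpy()
        dl = [lg.t_peak for lg in demo_result.lunges]
        r, p = match_events(tl, dl, tol=5.0)
        assert r >= 0.95 and p >= 0.95


class TestLinkAttempts:
    def test_single_gap_linked(self):
        c = fev.CircleEvent(t_start=0.0, t_end=20.0, total_rotation=220.0)
        lg = fev.LungeEvent(t_peak=25.0, depth_at_peak=100.0, peak_speed=5.0,
                            pre_speed=2.0, decel=0.5)
        table, failed = fev.link_attempts([c], [lg], max_gap=30.0)
        assert c.followed_by_lunge and lg.preceded_by_circle
        assert failed == 0.0

    def test_failed_fraction_fifth(self):
        circles = [fev.CircleEvent(t_start=100.0 * k, t_end=100.0 * k + 20,
                                   total_rotation=200.0) for k in range(10)]
        lunges = [fev.LungeEvent(t_peak=100.0 * k + 30, depth_at_peak=100.0,
                                 peak_speed=5.0, pre_speed=2.0, decel=0.5)
                  for k in range(8)]
        _, failed = fev.link_attempts(circles, lunges)
        assert failed == pytest.approx(0.20)

    def test_links_injective_and_causal(self, demo_result):
        linked = demo_result.attempts.dropna(subset=["lunge_t_peak"])
        assert linked["lunge_t_peak"].is_unique
        assert (linked["lunge_t_peak"]
                >= linked["circle_t_end"] - 15.0).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_linker(self, seed):
        rng = np.random.default_rng(100 + seed)
        circles = []
        t = 0.0
        for _ in range(20):
            t += rng.uniform(10, 120)
            circles.append(fev.CircleEvent(t_start=t, t_end=t + rng.uniform(5, 40),
                                           total_rotation=200.0))
            t = circles[-1].t_end
        lunges = [fev.LungeEvent(t_peak=float(rng.uniform(0, t)),
                                 depth_at_peak=100.0, peak_speed=5.0,
                                 pre_speed=2.0, decel=0.5)
                  for _ in range(15)]
        table, _ = fev.link_attempts(circles, lunges)
        want = oracle_link([(c.t_start, c.t_end) for c in circles],
                           [lg.t_peak for lg in lunges])
        got = [None if not row.linked else row.lunge_t_peak
               for row in table.itertuples()]
        assert got == want

    def test_failed_fraction_matches_truth(self, demo_sim, demo_result):
        _, truth = demo_sim
        circ = truth.events[truth.events.event_type == "circle"]
        true_failed = 1.0 - np.mean(
            [a["followed_by_lunge"] for a in circ["attributes"]])
        assert demo_result.failed_attempt_fraction == pytest.approx(
            true_failed, abs=0.1)


class TestLungeContext:
    def test_depth_classification(self):
        dives = [__import__("whalekin").DiveRecord(0, 100.0, 400.0, 200.0)]
        lunges = [
            fev.LungeEvent(t_peak=200.0, depth_at_peak=197.0, peak_speed=5.0,
                           pre_speed=2.0, decel=0.5),
            fev.LungeEvent(t_peak=50.0, depth_at_peak=3.0, peak_speed=5.0,
                           pre_speed=2.0, decel=0.5),
        ]
        out = fev.classify_lunge_context(lunges, dives)
        assert list(out["context"]) == ["deep", "surface"]  # input order
        assert not out["integrity_warning"].any()
        assert dives[0].n_lunges == 1

    def test_simulator_per_dive_counts_exact(self, demo_sim, demo_result):
        _, truth = demo_sim
        tt = truth.dive_table().sort_values("t_start").reset_index(drop=True)
        det = sorted(demo_result.dives, key=lambda d: d.t_start)
        assert len(det) == len(tt)
        assert [d.n_lunges for d in det] == list(tt["n_lunges"])


class TestAverageEventProfile:
    def test_identical_pulses_mean_with_zero_band(self):
        rate = 10.0
        x = np.zeros(2000)
        pulse = np.exp(-0.5 * ((np.arange(-50, 51)) / 10.0) ** 2)
        for c in (500, 1500):
            x[c - 50:c + 51] += pulse
        out = fev.average_event_profile({"speed": x}, np.array([50.0, 150.0]),
                                        rate, window=8.0)
        prof = out["speed"]
        assert out["n_events"] == 2
        np.testing.assert_allclose(prof["p95"] - prof["p05"], 0.0, atol=1e-12)
        assert prof["mean"].max() == pytest.approx(1.0, abs=1e-6)

    def test_edge_events_excluded(self):
        x = np.zeros(300)
        out = fev.average_event_profile({"x": x},
                                        np.array([0.5, 10.0, 20.0, 29.5]),
                                        10.0, window=10.0)
        assert out["n_events"] == 2  # the two edge events are dropped

    def test_too_few_complete_windows_raise(self):
        with pytest.raises(fev.ParameterError):
            fev.average_event_profile({"x": np.zeros(100)}, np.array([5.0]),
                                      10.0, window=4.0)

    def test_simulated_lunge_profile_peaks_at_configured_speed(self, demo_sim):
        _, truth = demo_sim
        tl = truth.events.loc[truth.events.event_type == "lunge",
                              "t_start"].to_numpy()
        out = fev.average_event_profile({"speed": truth.speed}, tl,
                                        truth.rate, window=30.0)
        peak = out["speed"]["mean"].max()
        assert peak == pytest.approx(truth.config.lunge_peak_speed, rel=0.05)
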