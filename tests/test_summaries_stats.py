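"""Summary tables, time-at-depth, rank-sum test, model fits."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import whalekin as wk
from whalekin import summaries_stats as sst


def _dives(depths, n_lunges=1):
    out = []
    for k, z in enumerate(depths):
        d = wk.DiveRecord(k, 600.0 * k, 600.0 * k + 300.0, float(z))
        d.descent_end_t = 600.0 * k + 100.0
        d.ascent_start_t = 600.0 * k + 200.0
        d.descent_rate = d.ascent_rate = 1.0
        d.descent_speed = d.ascent_speed = 2.0
        d.n_lunges = n_lunges
        out.append(d)
    return out


class TestDiveSummary:
    def test_identical_depths_zero_se(self):
        out = sst.dive_summary(_dives([100.0, 100.0, 100.0]))
        row = out[out.field == "dive_depth_m"].iloc[0]
        assert row["mean"] == 100.0 and row["se"] == 0.0

    def test_single_dive_se_absent(self):
        out = sst.dive_summary(_dives([100.0]))
        row = out[out.field == "dive_depth_m"].iloc[0]
        assert np.isnan(row["se"])

    def test_no_foraging_dives_empty_marker(self):
        out = sst.dive_summary(_dives([100.0], n_lunges=0))
        assert out.iloc[0]["field"] == "n_foraging_dives"
        assert out.iloc[0]["mean"] == 0.0

    def test_breathing_rate_uses_post_dive_interval(self):
        dives = _dives([100.0, 120.0])
        # 6 breaths in the 300 s (5 min) surfacing after dive 0
        breaths = 310.0 + np.arange(6) * 40.0
        out = sst.dive_summary(dives, breath_times=breaths)
        row = out[out.field == "breathing_rate_per_min"].iloc[0]
        assert row["mean"] == pytest.approx((6 / 5.0 + 0.0) / 2.0)

    def test_simulator_means_track_truth(self, demo_sim, demo_result):
        _, truth = demo_sim
        tt = truth.dive_table()
        out = demo_result.summary
        mean_depth = out.loc[out.field == "dive_depth_m", "mean"].iloc[0]
        se = out.loc[out.field == "dive_depth_m", "se"].iloc[0]
        true_mean = tt.loc[tt.n_lunges >= 1, "max_depth"].mean()
        assert abs(mean_depth - true_mean) < 2 * se + 1.0


class TestTimeAtDepth:
    def test_all_shallow_night(self):
        depth = np.full(1000, 1.0)
        diel = np.full(1000, "night")
        out = sst.time_at_depth(depth, diel, bins=[0, 2, 15, 100])
        row = out[(out.diel == "night") & (out.bin_lo == 0)].iloc[0]
        assert row["fraction"] == 1.0

    def test_fractions_sum_to_one_and_cumulative_monotone(self, demo_result):
        out = sst.time_at_depth(demo_result.depth.data, demo_result.diel,
                                bins=[0, 2, 15, 50, 100, 300])
        for _, g in out.groupby("diel"):
            assert g["fraction"].sum() == pytest.approx(1.0)
            assert (np.diff(g["cumulative"]) >= -1e-12).all()
            assert g["cumulative"].iloc[-1] == pytest.approx(1.0)

    def test_night_surface_fraction_recovered(self):
        cfg = wk.demo_config(seed=6, duration_h=1.5, day_window=(0.0, 0.0),
                             start_local_h=23.0,
                             n_dives_per_hour_night=0.25,
                             night_shallow_frac=0.5)
        sensors, truth = wk.simulate_deployment(cfg)
        res = wk.run_pipeline(sensors)
        night = res.diel == "night"
        assert night.mean() > 0.9
        frac = (res.depth.data[night] <= 2.0).mean()
        assert frac == pytest.approx(0.50, abs=0.02)


class TestRankSum:
    def test_exact_small_sample(self):
        out = sst.rank_sum_test([1.0, 2.0], [3.0, 4.0])
        assert out["W"] == 3.0
        assert out["p"] == pytest.approx(1.0 / 3.0)
        assert out["method"] == "exact"

    def test_tied_singletons_midranks(self):
        out = sst.rank_sum_test([5.0], [5.0])
        assert out["W"] == 1.5

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=8), rng.normal(0.5, 1.0, size=8)
        exact = sst.rank_sum_test(x, y, exact_max_n=16)
        approx = sst.rank_sum_test(x, y, exact_max_n=0)
        assert exact["method"] == "exact" and approx["method"] == "normal"
        assert abs(exact["p"] - approx["p"]) < 0.02

    @pytest.mark.parametrize("nx,ny", [(1, 2), (2, 2), (3, 4), (4, 5), (5, 5)])
    def test_matches_independent_enumeration(self, nx, ny):
        rng = np.random.default_rng(nx * 10 + ny)
        x = rng.integers(0, 6, nx).astype(float)   # ties likely
        y = rng.integers(0, 6, ny).astype(float)
        out = sst.rank_sum_test(x, y)
        # independent oracle: recompute midranks via scipy, enumerate subsets
        ranks = stats.rankdata(np.concatenate([x, y]))
        w_obs = ranks[:nx].sum()
        mean_w = nx * (nx + ny + 1) / 2.0
        hits = sum(1 for idx in combinations(range(nx + ny), nx)
                   if abs(ranks[list(idx)].sum() - mean_w)
                   >= abs(w_obs - mean_w) - 1e-12)
        assert out["W"] == pytest.approx(w_obs)
        assert out["p"] == pytest.approx(hits / comb(nx + ny, nx))

    def test_agrees_with_scipy_mannwhitney(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=6), rng.normal(size=5)
        out = sst.rank_sum_test(x, y)
        u = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        # rank-sum W relates to the Mann-Whitney U by W = U + nx(nx+1)/2
        assert out["W"] == pytest.approx(u.statistic + 6 * (6 + 1) / 2.0)
        assert out["p"] == pytest.approx(u.pvalue, abs=1e-9)

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=4), rng.normal(size=5)
        a = sst.rank_sum_test(x, y)
        b = sst.rank_sum_test(y, x)
        n = 9
        assert b["W"] == pytest.approx(n * (n + 1) / 2.0 - a["W"])
        assert a["p"] == pytest.approx(b["p"])

    def test_empty_group_rejected(self):
        with pytest.raises(sst.ParameterError):
            sst.rank_sum_test([], [1.0])

    @given(st.lists(st.integers(0, 9), min_size=1, max_size=6),
           st.lists(st.integers(0, 9), min_size=1, max_size=6))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_swap_symmetry_and_bounds_property(self, xs, ys):
        """p in (0, 1]; swapping groups reflects W and preserves p."""
        x = np.asarray(xs, dtype=float)
        y = np.asarray(ys, dtype=float)
        a = sst.rank_sum_test(x, y)
        b = sst.rank_sum_test(y, x)
        n = x.size + y.size
        assert 0.0 < a["p"] <= 1.0
        assert a["W"] + b["W"] == pytest.approx(n * (n + 1) / 2.0)
        assert a["p"] == pytest.approx(b["p"])


class TestFitModel:
    def test_gamma_log_link_recovers_noiseless_coefficients(self):
        x = np.linspace(0.0, 2.0, 60)
        y = np.exp(2.0 + 3.0 * x)
        out = sst.fit_model(y, x, "gamma-log-link")
        assert out["coefficients"]["intercept"] == pytest.approx(2.0, abs=1e-6)
        assert out["coefficients"]["x0"] == pytest.approx(3.0, abs=1e-6)

    def test_quasipoisson_intercept_only_closed_form(self):
        out = sst.fit_model(np.array([2.0, 2.0, 2.0]), np.zeros((3, 0)),
                            "quasipoisson-log-link")
        assert out["coefficients"]["intercept"] == pytest.approx(np.log(2.0),
                                                                 abs=1e-8)

    def test_gaussian_log_response_is_ols_on_log(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, 80)
        y = np.exp(1.0 + 2.0 * x + rng.normal(0, 0.1, 80))
        out = sst.fit_model(y, x, "gaussian-log-response")
        beta = np.polyfit(x, np.log(y), 1)
        assert out["coefficients"]["x0"] == pytest.approx(beta[0], abs=1e-9)
        assert out["coefficients"]["intercept"] == pytest.approx(beta[1],
                                                                 abs=1e-9)

    def test_positive_breath_energy_slope_power(self):
        # counts with log-rate linear in work: slope sign recovered >= 95 %
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(100):
            work = rng.uniform(0.0, 2.0, 40)
            lam = np.exp(0.5 + 0.8 * work)
            counts = rng.poisson(lam).astype(float)
            out = sst.fit_model(counts, work, "quasipoisson-log-link")
            hits += out["coefficients"]["x0"] > 0
        assert hits >= 95

    def test_quasipoisson_dispersion_reported(self):
        rng = np.random.default_rng(8)
        lam = 5.0
        counts = rng.negative_binomial(5, 5 / (5 + lam), 200).astype(float)
        out = sst.fit_model(counts, np.zeros((200, 0)),
                            "quasipoisson-log-link")
        assert out["dispersion"] > 1.2     # overdispersed by construction

    def test_nonpositive_response_rejected_for_log_families(self):
        with pytest.raises(sst.ParameterError):
            sst.fit_model(np.array([1.0, 0.0, 2.0]), np.arange(3.0),
                          "gamma-log-link")
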