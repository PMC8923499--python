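"""Weighted summaries, bootstrap CIs, stride sensitivity, paired comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from conftest import make_uniform_field
from swimtel.behaviorstats import (
    bl_normalize,
    classify_behavior,
    export_gam_table,
    ground_vs_river,
    rheotaxis_fraction,
    segment_weights,
    stride_speeds,
    weighted_kde,
    weighted_median,
    weighted_median_ci,
)
from swimtel.hydrofield import RiverReach
from swimtel.swimvec import make_segments, swim_records


def _records(tags_and_counts, vranges=("full",)):
    rows = []
    for tag, n in tags_and_counts:
        for vr in vranges:
            for k in range(n):
                rows.append(
                    {"tag_id": tag, "vrange": vr, "t0": 5.0 * k,
                     "u_long": -0.1, "v_lat": 0.0}
                )
    return pd.DataFrame(rows)


class TestSegmentWeights:
    def test_single_tag_equal_split(self):
        rec = segment_weights(_records([("a", 4)]))
        assert np.allclose(rec["weight"], 0.25)

    def test_unequal_tags_get_equal_total_weight(self):
        rec = segment_weights(_records([("a", 2), ("b", 8)]))
        totals = rec.groupby("tag_id")["weight"].sum()
        assert np.allclose(totals, 1.0)

    def test_pooled_vranges_keep_per_tag_total_one(self):
        rec = segment_weights(
            _records([("a", 4), ("b", 6)], vranges=("top1m", "top2m", "full")),
            pool_vranges=True,
        )
        totals = rec.groupby("tag_id")["weight"].sum()
        assert np.allclose(totals, 1.0)


class TestWeightedMedian:
    def test_equal_weights_simple(self):
        assert weighted_median([1, 2, 3], [1, 1, 1]) == 2

    def test_cumulative_weight_definition(self):
        assert weighted_median([0.0, 10.0], [0.75, 0.25]) == 0.0

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=41))
    def test_equal_weights_reduce_to_ordinary_median_odd_n(self, vals):
        if len(vals) % 2 == 0:
            vals = vals + [0.0]
        w = np.ones(len(vals))
        assert weighted_median(vals, w) == pytest.approx(np.median(vals))

    def test_ci_brackets_median_and_zero_width_for_constant(self):
        med, (lo, hi) = weighted_median_ci(
            np.full(50, 3.3), np.ones(50), n_boot=200, seed=1)
        assert med == lo == hi == 3.3

    def test_bootstrap_ci_coverage(self):
        # CI of the median covers the true median in >= 85% of replicates
        rng = np.random.default_rng(99)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            x = rng.normal(0.0, 1.0, 500)
            _, (lo, hi) = weighted_median_ci(
                x, np.ones(500), n_boot=200, seed=int(rng.integers(2**31)))
            hits += lo <= 0.0 <= hi
        assert hits / n_rep >= 0.85


class TestWeightedKDE:
    def test_single_value_with_fixed_bandwidth_is_the_kernel(self):
        grid, dens = weighted_kde(np.full(5, 2.0), np.ones(5), bandwidth=0.3)
        expected = stats.norm.pdf(grid, loc=2.0, scale=0.3)
        assert np.allclose(dens, expected, atol=1e-12)

    def test_rule_based_bandwidth_needs_two_distinct_values(self):
        with pytest.raises(ValueError):
            weighted_kde(np.full(5, 2.0), np.ones(5))

    def test_symmetric_data_give_symmetric_density(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0])
        grid, dens = weighted_kde(x, np.ones(4), bandwidth=0.5, n_grid=401)
        assert np.allclose(dens, dens[::-1], atol=1e-6)

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=200)
        w = rng.uniform(0.5, 2.0, 200)
        grid, dens = weighted_kde(x, w)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)
        assert (dens >= 0).all()

    def test_mixture_mode_matches_dense_grid_brute_force(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(-1, 0.1, 150), rng.normal(1.5, 0.3, 50)])
        w = np.ones(x.size)
        bw = 0.15
        grid, dens = weighted_kde(x, w, bandwidth=bw, n_grid=2001)
        fine = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, 20001)
        brute = np.zeros_like(fine)
        for xi in x:
            brute += stats.norm.pdf(fine, xi, bw) / x.size
        assert grid[np.argmax(dens)] == pytest.approx(
            fine[np.argmax(brute)], abs=0.01)

    def test_equal_weights_match_unweighted_evaluation(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=100)
        g1, d1 = weighted_kde(x, np.ones(100), bandwidth=0.4)
        g2, d2 = weighted_kde(x, np.full(100, 7.7), bandwidth=0.4)
        assert np.allclose(d1, d2)


class TestRheotaxisFraction:
    def _rec(self, u_long, w):
        return pd.DataFrame({"u_long": u_long, "weight": w})

    def test_all_upstream(self):
        assert rheotaxis_fraction(self._rec([-0.1, -0.2], [1, 1])) == 1.0

    def test_weighted_fraction(self):
        assert rheotaxis_fraction(
            self._rec([-0.1, 0.1], [0.75, 0.25])) == pytest.approx(0.75)

    def test_random_table_matches_rowwise_oracle(self):
        rng = np.random.default_rng(8)
        u = rng.normal(0, 0.1, 200)
        w = rng.uniform(0.1, 2, 200)
        expected = w[u < 0].sum() / w.sum()
        assert rheotaxis_fraction(self._rec(u, w)) == pytest.approx(expected)


class TestStrideSpeeds:
    def _noisy_track(self, noise_sd, n=120, rng=None):
        rng = np.random.default_rng(0) if rng is None else rng
        t = np.arange(n) * 5.0
        x = 100.0 + 0.5 * t + rng.normal(0, noise_sd, n)
        y = 25.0 + rng.normal(0, noise_sd, n)
        return pd.DataFrame({"tag_id": "a", "t": t, "x": x, "y": y})

    def test_stride_one_matches_segment_pipeline(self, uniform_field):
        tr = self._noisy_track(0.0, n=20)
        s1 = stride_speeds(tr, uniform_field, "full", stride=1)
        seg = make_segments(tr, max_gap=np.inf)
        rec = swim_records(seg, uniform_field, vranges=("full",))
        assert np.allclose(np.sort(s1),
                           np.sort(np.hypot(rec["us_u"], rec["us_v"])))

    def test_noiseless_constant_velocity_speed_independent_of_stride(
            self, uniform_field):
        tr = self._noisy_track(0.0)
        for k in (1, 2, 8):
            s = stride_speeds(tr, uniform_field, "full", stride=k)
            assert np.allclose(s, 0.0, atol=1e-9)

    def test_position_noise_bias_shrinks_with_stride(self, uniform_field):
        # 1.4 m iid noise at 5 s PRI inflates speeds; stride 8 (40 s) less so
        rng = np.random.default_rng(42)
        m1, m8 = [], []
        for _ in range(10):
            tr = self._noisy_track(1.4, n=200, rng=rng)
            m1.append(np.median(stride_speeds(tr, uniform_field, "full", 1)))
            m8.append(np.median(stride_speeds(tr, uniform_field, "full", 8)))
        assert np.median(m8) < np.median(m1)

    def test_speed_bias_monotone_in_noise(self, uniform_field):
        rng = np.random.default_rng(43)
        meds = []
        for sd in (0.0, 0.7, 1.4, 2.8):
            tr = self._noisy_track(sd, n=300, rng=np.random.default_rng(7))
            meds.append(np.median(stride_speeds(tr, uniform_field, "full", 1)))
        assert all(b >= a - 1e-12 for a, b in zip(meds, meds[1:]))

    def test_short_track_empty(self, uniform_field):
        tr = self._noisy_track(0.0, n=3)
        assert stride_speeds(tr, uniform_field, "full", stride=5).size == 0


class TestGroundVsRiver:
    def _reach(self, u=0.5):
        t = np.linspace(0, 7200, 100)
        V = 46800.0
        return RiverReach(times=t, discharge=np.full(100, u * V / 234.0),
                          stage=np.zeros(100),
                          volume_stages=np.array([-1, 1.0]),
                          volume_values=np.array([V, V]))

    def _segments(self, tag, uog, n=10):
        t0 = np.arange(n) * 5.0
        return pd.DataFrame(
            {"tag_id": tag, "t0": t0, "t1": t0 + 5.0,
             "uog_u": np.full(n, uog), "uog_v": 0.0}
        )

    def test_fish_moving_at_river_speed_zero_difference(self):
        segs = pd.concat([self._segments("a", 0.5), self._segments("b", 0.5)])
        res = ground_vs_river(segs, self._reach(0.5))
        assert res.mean_difference == pytest.approx(0.0, abs=1e-12)
        assert res.degenerate

    def test_t_statistic_closed_form_oracle(self):
        # per-fish differences {1, 2, 3} → t = 3.464, df 2, p ≈ 0.074
        segs = pd.concat(
            [self._segments("a", 1.5), self._segments("b", 2.5),
             self._segments("c", 3.5)]
        )
        res = ground_vs_river(segs, self._reach(0.5))
        assert res.mean_difference == pytest.approx(2.0)
        assert res.t_statistic == pytest.approx(2.0 / (1.0 / np.sqrt(3)), abs=1e-3)
        assert res.p_value == pytest.approx(0.0742, abs=0.002)

    def test_prescribed_rheotaxis_recovered_in_uniform_flow(self):
        rng = np.random.default_rng(3)
        segs = pd.concat(
            [self._segments(f"f{i}", 0.45 + rng.normal(0, 0.002))
             for i in range(20)]
        )
        res = ground_vs_river(segs, self._reach(0.5))
        assert res.mean_difference == pytest.approx(-0.05, abs=0.01)
        assert res.ci_90[0] < -0.04 and res.ci_90[1] < 0.0


class TestClassifyBehavior:
    def _rec(self, u_long, v_lat, n=8):
        return pd.DataFrame({"u_long": np.full(n, u_long),
                             "v_lat": np.full(n, v_lat)})

    def test_positive_rheotaxis(self):
        assert classify_behavior(self._rec(-0.1, 0.0)) == "positive_rheotaxis"

    def test_negative_rheotaxis(self):
        assert classify_behavior(self._rec(0.1, 0.0)) == "negative_rheotaxis"

    def test_lateral(self):
        assert classify_behavior(self._rec(0.0, 0.1)) == "lateral"

    def test_passive(self):
        assert classify_behavior(self._rec(0.0, 0.0)) == "passive"

    def test_too_few_records_unlabeled(self):
        assert classify_behavior(self._rec(-0.2, 0.0, n=3)) is None


class TestBLNormalize:
    def test_mode_of_swim_speed_distribution(self):
        # 0.15 m/s at the 76.6 mm mean fork length ≈ 2.0 BL/s
        assert bl_normalize(0.15, 76.6) == pytest.approx(1.96, abs=0.005)
        assert round(bl_normalize(0.15, 76.6), 1) == 2.0

    def test_zero_speed(self):
        assert bl_normalize(0.0, 76.6) == 0.0

    def test_arithmetic_oracle(self):
        assert bl_normalize(0.51, 85.0) == pytest.approx(6.0, abs=1e-12)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            bl_normalize(0.1, 0.0)


class TestGamTable:
    def _records(self):
        rows = []
        for tag in ("a", "b"):
            for vr in ("top1m", "top2m", "full"):
                for k in range(4):
                    rows.append(
                        {"tag_id": tag, "vrange": vr, "t0": 5.0 * k,
                         "mid_t": 5.0 * k + 2.5, "u_long": -0.1, "v_lat": 0.05,
                         "speed_hydro": 0.5, "vorticity": 0.0, "depth": 4.0,
                         "time_of_day_h": 12.0, "u_river": 0.5,
                         "turbidity": 10.0}
                    )
        return pd.DataFrame(rows)

    def test_row_count(self):
        tab = export_gam_table(self._records())
        assert len(tab) == 2 * 3 * 4

    def test_per_tag_weight_sums_to_one(self):
        tab = export_gam_table(self._records())
        assert np.allclose(tab.groupby("tag_id")["weight"].sum(), 1.0)

    def test_columns_match_recomputation(self):
        tab = export_gam_table(self._records())
        assert np.allclose(tab["abs_v_lat"], 0.05)
        assert np.allclose(tab["weight"], 1.0 / 12)

    def test_missing_covariates_rejected(self):
        rec = self._records().drop(columns=["turbidity"])
        with pytest.raises(ValueError):
            export_gam_table(rec)
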