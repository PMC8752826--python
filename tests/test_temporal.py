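"""Tidal/diel classification, cyclic mixed models, excursion detection and
the Monte-Carlo goodness-of-fit test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import shapely

import lagoonhab as lh
from lagoonhab.temporal import (
    DIEL_ORDER,
    bin_depth,
    classify_diel,
    classify_tide,
    detect_excursions,
    excursion_timing_test,
    fit_cycle_lmm,
)
from lagoonhab.synthetic import simulate_cycle_observations


class TestDiel:
    def test_phase_boundaries(self):
        ts = pd.to_datetime(
            ["2013-10-02 03:00", "2013-10-02 08:59", "2013-10-02 09:00",
             "2013-10-02 15:00", "2013-10-02 21:00", "2013-10-02 02:59"]
        )
        assert classify_diel(ts).tolist() == [
            "dawn", "dawn", "day", "dusk", "night", "night"
        ]

    def test_24_hourly_stamps_split_evenly(self):
        ts = pd.date_range("2013-10-02", periods=24, freq="h")
        counts = classify_diel(ts).value_counts()
        assert (counts == 6).all()

    def test_labels_depend_only_on_clock(self):
        t1 = pd.date_range("2013-10-02", periods=24, freq="h")
        t2 = pd.date_range("2019-03-17", periods=24, freq="h")
        assert classify_diel(t1).tolist() == classify_diel(t2).tolist()


class TestTide:
    def test_crest_is_high_and_late_is_neither(self):
        t = lh.generate_tide_series(
            "2013-10-01", "2013-10-08", noise_sd=0.0, modulation=0.0
        )
        rec = t.records
        crest = rec.loc[rec["height_m"].idxmax(), "time"]
        lab = classify_tide(t, [crest, crest + pd.Timedelta(minutes=61)])
        assert lab["tidal"].tolist() == ["high", "neither"]

    def test_window_fraction_matches_analytic(self):
        t = lh.generate_tide_series(
            "2013-10-01", "2013-10-15", noise_sd=0.0, modulation=0.0
        )
        q = pd.date_range("2013-10-02", "2013-10-13", freq="5min")
        lab = classify_tide(t, q)["tidal"]
        frac = 2.0 / 12.42
        assert abs((lab == "high").mean() - frac) < 0.02
        assert abs((lab == "low").mean() - frac) < 0.02

    def test_out_of_span_rejected(self):
        t = lh.generate_tide_series("2013-10-01", "2013-10-05")
        with pytest.raises(ValueError):
            classify_tide(t, [pd.Timestamp("2013-11-01")])

    def test_ebb_flood_alternate_with_windows(self):
        t = lh.generate_tide_series(
            "2013-10-01", "2013-10-05", noise_sd=0.0, modulation=0.0
        )
        rec = t.records
        crest = rec.loc[rec["height_m"].idxmax(), "time"]
        lab = classify_tide(
            t, [crest - pd.Timedelta(hours=2), crest + pd.Timedelta(hours=2)]
        )
        assert lab["ebb_flood"].tolist() == ["flood", "ebb"]


class TestDepthBins:
    def test_printed_interval_boundaries(self):
        assert bin_depth([2.0]).iloc[0] == "shallow"
        assert bin_depth([7.0]).iloc[0] == "medium"
        assert bin_depth([10.0]).iloc[0] == "medium"
        assert bin_depth([10.5]).iloc[0] == "deep"

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            bin_depth([-1.0])


class TestCycleLMM:
    def test_planted_interaction_detected(self):
        d = simulate_cycle_observations(interaction=1.0, seed=42)
        rep = fit_cycle_lmm(d, "response")
        assert rep["terms"]["tidal_x_diel"]["p"] < 0.05

    def test_conditional_r2_dominates_marginal(self):
        for s in range(5):
            d = simulate_cycle_observations(
                tidal_effect=0.3, diel_effects=(0.2, -0.1, 0.4), seed=s
            )
            rep = fit_cycle_lmm(d, "response")
            assert rep["conditional_r2"] >= rep["marginal_r2"] - 1e-12

    def test_sparse_individuals_removed_and_few_rejected(self):
        d = simulate_cycle_observations(n_individuals=2, n_loc_per_ind=5, seed=0)
        with pytest.raises(ValueError):
            fit_cycle_lmm(d, "response")

    def test_posthoc_table_covers_all_cell_pairs(self):
        d = simulate_cycle_observations(interaction=1.0, seed=1)
        rep = fit_cycle_lmm(d, "response")
        assert len(rep["posthoc"]) == math.comb(8, 2)
        assert rep["posthoc"]["p_tukey"].between(0, 1).all()


class TestExcursions:
    def _channel_world(self):
        lagoon = shapely.box(0, 0, 20_000, 5_000)
        barrier = shapely.box(0, 5_000, 20_000, 5_400)
        return lh.LagoonGeometry(
            coastline=shapely.box(0, -5_000, 20_000, 0),
            barrier_reef=[barrier],
            passes=[lh.Pass(10_000.0, 5_200.0, 1.0)],
            intermediate_reefs=[],
            islets=[],
            seagrass=[],
            lagoon=lagoon,
            domain=shapely.box(0, -5_000, 20_000, 9_000),
        )

    def test_inside_track_yields_no_excursion(self, tide):
        g = self._channel_world()
        tr = pd.DataFrame(
            {
                "timestamp": pd.date_range("2013-10-05", periods=12, freq="h"),
                "x": np.linspace(1000, 15_000, 12),
                "y": 2500.0,
                "rt": 1.0,
            }
        )
        assert detect_excursions({"a": tr}, g, tide) == []

    def test_hand_built_eight_hour_run(self, tide):
        g = self._channel_world()
        y = np.full(20, 2500.0)
        y[6:14] = 6_500.0  # 8 consecutive hourly locations seaward
        tr = pd.DataFrame(
            {
                "timestamp": pd.date_range("2013-10-05", periods=20, freq="h"),
                "x": 10_000.0,
                "y": y,
                "rt": 1.0,
            }
        )
        exc = detect_excursions({"a": tr}, g, tide)
        assert len(exc) == 1
        assert not exc[0].open_ended
        assert abs(exc[0].duration_h - 8.0) < 1.0
        assert exc[0].t_out < exc[0].t_in

    def test_track_ending_outside_flagged_open(self, tide):
        g = self._channel_world()
        y = np.full(10, 2500.0)
        y[6:] = 6_500.0
        tr = pd.DataFrame(
            {
                "timestamp": pd.date_range("2013-10-05", periods=10, freq="h"),
                "x": 10_000.0,
                "y": y,
                "rt": 1.0,
            }
        )
        exc = detect_excursions({"a": tr}, g, tide)
        assert len(exc) == 1 and exc[0].open_ended
        assert exc[0].duration_h is None


class TestTimingGOF:
    def _exact_tail_p(self, obs):
        """Exact multinomial tail probability for counts over 4 phases."""
        n = sum(obs)
        expected = n / 4.0
        chi2_obs = sum((o - expected) ** 2 / expected for o in obs)
        p = 0.0
        for c in itertools.product(range(n + 1), repeat=3):
            rest = n - sum(c)
            if rest < 0:
                continue
            counts = (*c, rest)
            chi2 = sum((o - expected) ** 2 / expected for o in counts)
            if chi2 >= chi2_obs - 1e-12:
                logp = (
                    math.lgamma(n + 1)
                    - sum(math.lgamma(o + 1) for o in counts)
                    + n * math.log(0.25)
                )
                p += math.exp(logp)
        return p

    def test_simulated_p_matches_enumeration(self):
        labels = ["dawn"] * 6 + ["day"] + ["dusk"] + ["night"] * 2
        rep = excursion_timing_test(labels, n_replicates=2000, seed=0)
        exact = self._exact_tail_p([6, 1, 1, 2])
        mc_se = math.sqrt(exact * (1 - exact) / 2000)
        assert abs(rep["p"] - exact) < 4 * mc_se + 1e-3

    def test_uniform_counts_give_p_near_one(self):
        labels = [c for c in DIEL_ORDER for _ in range(5)]
        rep = excursion_timing_test(labels, seed=1)
        assert rep["p"] > 0.9

    def test_all_in_one_phase_extreme(self):
        rep = excursion_timing_test(["dawn"] * 10, seed=2)
        assert rep["p"] <= 0.01

    def test_no_excursions_refused(self):
        with pytest.raises(ValueError):
            excursion_timing_test([])
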