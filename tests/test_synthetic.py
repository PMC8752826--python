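"""Generator self-consistency: planted geometry contrasts, tide envelope,
behavioural switching, injected degradations, density surface."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import find_peaks
from scipy.stats import chi2_contingency

import lagoonhab as lh
from lagoonhab.synthetic import (
    DEFAULT_REGIONS,
    RegionSpec,
    _diel_code,
    ars_bout_durations,
    generate_density_surface,
)


class TestLagoon:
    def test_planted_region_contrasts_recovered_in_raster(self, lagoon):
        """Per-region depth summaries reproduce the deep/wide vs shallow/narrow
        vs shallow/medium ordering of the planted configuration."""
        geometry, bathy = lagoon
        X, Y = bathy.cell_centers()
        xt = X - np.clip(Y, 0, None)
        xb = geometry.region_truth["boundaries_m"]
        means = []
        for i in range(3):
            mask = (xt >= xb[i]) & (xt < xb[i + 1]) & ~np.isnan(bathy.data)
            # lagoon cells only: inside the barrier
            mask &= geometry.zones.data == 1
            means.append(np.nanmean(bathy.data[mask]))
        assert means[0] > 2 * means[1]  # deep region vs shallow
        assert abs(means[1] - 6.5) < 2.5 and abs(means[2] - 7.0) < 2.5
        # region 2 has no intermediate reefs planted
        r2 = [
            g
            for g in geometry.intermediate_reefs
            if xb[1] < g.centroid.x - max(g.centroid.y, 0) < xb[2]
        ]
        assert len(r2) == 0

    def test_single_uniform_region_gives_flat_bathymetry(self):
        regions = (RegionSpec(30.0, 6.0, 10.0, 0.0, 0.0, (), uniform_depth=True),)
        geometry, bathy = lh.generate_lagoon(regions, seed=0)
        lag = bathy.data[geometry.zones.data == 1]
        assert np.allclose(lag, 10.0)
        assert geometry.intermediate_reefs == []

    def test_fixed_seed_reproducible(self):
        g1, b1 = lh.generate_lagoon(seed=7)
        g2, b2 = lh.generate_lagoon(seed=7)
        assert np.array_equal(b1.data, b2.data, equal_nan=True)
        assert g1.lagoon.equals_exact(g2.lagoon, 0)
        assert [p.x_mid for p in g1.passes] == [p.x_mid for p in g2.passes]

    @pytest.mark.parametrize(
        "bad",
        [
            (RegionSpec(0.0, 5.0, 10.0, 1.0, 0.0, ()),),
            (RegionSpec(50.0, 0.0, 10.0, 1.0, 0.0, ()),),
            (RegionSpec(50.0, 5.0, -2.0, 1.0, 0.0, ()),),
        ],
    )
    def test_degenerate_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            lh.generate_lagoon(bad, seed=0)

    def test_land_and_water_disjoint(self, lagoon):
        """Depth is NaN exactly on land cells of the zone raster."""
        geometry, bathy = lagoon
        land = geometry.zones.data == 0
        assert np.isnan(bathy.data[land]).all()
        assert np.isfinite(bathy.data[~land]).all()

    def test_seagrass_lies_in_shallow_water(self, lagoon):
        geometry, bathy = lagoon
        for poly, _density in geometry.seagrass:
            c = poly.representative_point()
            d = bathy.sample(c.x, c.y)[0]
            if np.isfinite(d):
                assert d < 5.0


class TestTides:
    def test_peak_envelope_matches_study_regime(self):
        t = lh.generate_tide_series("2013-10-01", "2013-10-31", seed=3)
        h = t.records["height_m"].to_numpy()
        hi, _ = find_peaks(h, prominence=0.3)
        lo, _ = find_peaks(-h, prominence=0.3)
        assert ((h[hi] >= 1.80) & (h[hi] <= 1.91)).all()
        assert ((h[lo] >= 1.10) & (h[lo] <= 1.28)).all()

    def test_noiseless_harmonic_peaks_and_spacing(self):
        t = lh.generate_tide_series(
            "2013-10-01", "2013-10-11", noise_sd=0.0, modulation=0.0, seed=0
        )
        h = t.records["height_m"].to_numpy()
        hi, _ = find_peaks(h)
        assert np.allclose(h[hi], 1.505 + 0.345, atol=2e-3)
        spacing_h = np.diff(hi) * 20 / 60.0
        assert np.allclose(spacing_h, 12.42, atol=0.35)

    def test_empty_window(self):
        t = lh.generate_tide_series("2013-10-01", "2013-10-01")
        assert len(t.records) == 0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            lh.generate_tide_series(amplitude=-1.0)
        with pytest.raises(ValueError):
            lh.generate_tide_series(period_h=0.0)


class TestTracks:
    def test_zero_excursion_rate_keeps_animals_inside(self, lagoon, tide):
        geometry, bathy = lagoon
        cfg = lh.SimulationConfig(
            n_individuals=3, track_durations_days=(6,) * 3, excursion_rate=0.0, seed=9
        )
        sim = lh.simulate_tracks(geometry, bathy, tide, cfg)
        sea = geometry.is_seaward(sim.truth["x"].to_numpy(), sim.truth["y"].to_numpy())
        assert not sea.any()
        assert len(sim.excursions) == 0

    def test_null_effects_make_shallow_use_phase_independent(self, lagoon, tide):
        """With tidal/diel effects off, shallow-water occupancy is independent
        of diel phase (chi-square on thinned locations, 18 of 20 seeds)."""
        geometry, bathy = lagoon
        ok = 0
        for s in range(20):
            cfg = lh.SimulationConfig(
                n_individuals=3,
                track_durations_days=(10,) * 3,
                tidal_depth_effect=0.0,
                diel_depth_effect=0.0,
                excursion_rate=0.0,
                seed=s,
            )
            sim = lh.simulate_tracks(geometry, bathy, tide, cfg)
            thin = sim.truth.iloc[::26]  # 13 h apart: decorrelate, rotate phase
            d = bathy.sample(thin["x"].to_numpy(), thin["y"].to_numpy())
            shallow = d <= 2.0
            dusk_night = np.isin(
                _diel_code(pd.DatetimeIndex(thin["timestamp"]).hour), [2, 3]
            )
            ct = pd.crosstab(shallow, dusk_night)
            p = chi2_contingency(ct)[1] if ct.shape == (2, 2) else 1.0
            ok += p >= 0.05
        assert ok >= 18

    def test_ars_dwell_parameter_scales_bout_duration(self, lagoon, tide):
        """Halving the ARS exit rate doubles mean ground-truth bout length
        within 15%."""
        geometry, bathy = lagoon
        means = []
        for rate in (0.2, 0.1):
            cfg = lh.SimulationConfig(
                n_individuals=10,
                track_durations_days=(10,) * 10,
                switch_rate_to_transit_per_h=rate,
                tidal_depth_effect=0.0,
                diel_depth_effect=0.0,
                excursion_rate=0.0,
                seed=21,
            )
            sim = lh.simulate_tracks(geometry, bathy, tide, cfg)
            means.append(ars_bout_durations(sim.truth).mean())
        assert abs(means[1] / means[0] - 2.0) < 0.3

    def test_ground_truth_speeds_bounded(self, simulated):
        for _, g in simulated.truth.groupby("id"):
            step_km = np.hypot(np.diff(g["x"]), np.diff(g["y"])) / 1000.0
            dt_h = np.diff(pd.DatetimeIndex(g["timestamp"]).asi8) / 3.6e12
            assert (step_km / dt_h <= 10.0).all()

    def test_injected_degradations_present(self, simulated):
        assert (simulated.fixes["quality"] != "valid").any()
        gaps = (
            simulated.fixes.groupby("id")["timestamp"]
            .apply(lambda s: np.diff(pd.DatetimeIndex(s).asi8).max() / 3.6e12)
        )
        assert (gaps > 10.0).any()

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            lh.SimulationConfig(gap_rate=-0.1)
        with pytest.raises(ValueError):
            lh.SimulationConfig(fix_interval_min=7)

    def test_fixed_seed_reproducible(self, lagoon, tide):
        geometry, bathy = lagoon
        cfg = lh.SimulationConfig(n_individuals=2, track_durations_days=(4, 5), seed=5)
        a = lh.simulate_tracks(geometry, bathy, tide, cfg)
        b = lh.simulate_tracks(geometry, bathy, tide, cfg)
        pd.testing.assert_frame_equal(a.fixes, b.fixes)
        pd.testing.assert_frame_equal(a.truth, b.truth)


class TestDensitySurface:
    def _true_use(self, n=4500, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "x": rng.uniform(0, 48000, n),
                "y": rng.uniform(0, 24000, n),
                "intensity": rng.gamma(0.5, 20, n),
                "night_fraction": rng.uniform(0, 1, n),
            }
        )

    def test_unbiased_density_tracks_true_use(self):
        df = self._true_use()
        agg = generate_density_surface(df, daytime_bias=0.0, seed=1)
        assert len(agg) >= 400
        r = np.corrcoef(agg["density"], agg["true_mean"])[0, 1]
        assert r >= 0.95

    def test_total_bias_blanks_night_only_cells(self):
        df = self._true_use()
        df["night_fraction"] = 1.0
        agg = generate_density_surface(df, daytime_bias=1.0, seed=1)
        assert (agg["density"] == 0).all()

    def test_reproducible_and_validated(self):
        df = self._true_use()
        a = generate_density_surface(df, 0.5, seed=2)
        b = generate_density_surface(df, 0.5, seed=2)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError):
            generate_density_surface(df.drop(columns=["night_fraction"]), 0.5)
        with pytest.raises(ValueError):
            generate_density_surface(df, daytime_bias=1.5)
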