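import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from estuaryuse._geodesy import LocalProjection, great_circle_km
from estuaryuse.geospatial import PORT_NELSON, geodesic_km
from estuaryuse.hydrology import classify_series
from estuaryuse.survey import coverage_fraction, default_design
from estuaryuse.synthetic_data import (
    DensitySurface,
    SimConfig,
    make_shoreline_fixture,
    simulate_discharge,
    simulate_survey,
    simulate_tides,
    simulate_track,
    simulate_tracks,
)


class TestTrackGenerator:
    def test_zero_noise_residency_pins_to_center(self, noise_free_config):
        track = simulate_track(noise_free_config, 0)
        pre = track[track.timestamp < pd.Timestamp("2003-08-09")]
        d = great_circle_km(
            pre.lon, pre.lat, *noise_free_config.residency_center
        )
        assert np.max(d) < 1e-6

    def test_zero_noise_migration_drift_rate(self, noise_free_config):
        track = simulate_track(noise_free_config, 0)
        post = track[track.timestamp >= pd.Timestamp("2003-08-09")].copy()
        days_after = (
            post.timestamp - pd.Timestamp("2003-08-09")
        ) / pd.Timedelta(days=1)
        d = great_circle_km(post.lon, post.lat, *noise_free_config.residency_center)
        expected = noise_free_config.migration_speed_km_day * days_after
        mask = days_after > 0.5  # avoid relative error blowup near the switch
        np.testing.assert_allclose(d[mask], expected[mask], rtol=0.01)

    def test_residency_spread_matches_configured_sd(self):
        cfg = SimConfig(
            residency_sd_km=5.0,
            tide_coupling_km_per_m=0.0,
            argos_error_sd_km={c: 0.0 for c in ("3", "2", "1", "0", "A", "B")},
            fixes_per_day=130.0,
            start_date="2003-06-01",
            end_date="2003-08-08",  # all pre-switch: > 8000 fixes
            seed=11,
        )
        track = simulate_track(cfg, 0)
        assert len(track) > 8000
        proj = LocalProjection(*cfg.residency_center)
        x, y = proj.forward(track.lon.to_numpy(), track.lat.to_numpy())
        # thin to roughly independent samples (OU tau = 0.5 d at ~130 fixes/d)
        assert np.std(x[::40], ddof=1) == pytest.approx(5.0, rel=0.12)
        assert np.std(y[::40], ddof=1) == pytest.approx(5.0, rel=0.12)
        # pooled across both axes the Monte-Carlo bound tightens
        sd_all = np.std(np.r_[x[::40], y[::40]], ddof=1)
        assert sd_all == pytest.approx(5.0, rel=0.05)

    def test_timestamps_strictly_increasing_and_sorted(self):
        cfg = SimConfig(seed=3)
        for w in (0, 5):
            track = simulate_track(cfg, w)
            dt = np.diff(track.timestamp.to_numpy())
            assert (dt > np.timedelta64(0)).all()

    def test_determinism_and_whale_independence(self):
        cfg = SimConfig(seed=42)
        a = simulate_track(cfg, 2)
        b = simulate_track(cfg, 2)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_track(cfg, 3)
        assert not a.drop(columns="whale_id").equals(c.drop(columns="whale_id"))

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(argos_class_probs={"3": 0.5, "2": 0.6})
        with pytest.raises(ValueError):
            simulate_track(SimConfig(fixes_per_day=0.0), 0)
        with pytest.raises(ValueError):
            simulate_track(SimConfig(), 99)


class TestDischarge:
    def test_zero_noise_is_constant_at_mean(self):
        series = simulate_discharge({2003: 3331.0}, noise_sd=0.0, seed=1)
        assert (series.discharge_m3s == 3331.0).all()

    def test_round_trip_through_wet_dry_classification(self):
        series = simulate_discharge({2004: 2831.0, 2005: 5163.0}, seed=5)
        classes = classify_series(series, [2004, 2005], [2004, 2005])
        labels = {c.year: c.label for c in classes}
        assert labels == {2004: "dry", 2005: "wet"}

    def test_seed_reproducibility_byte_identical(self, tmp_path):
        from estuaryuse.io import write_discharge

        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_discharge(simulate_discharge({2003: 3000.0}, seed=9), p1)
        write_discharge(simulate_discharge({2003: 3000.0}, seed=9), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_years_rejected(self):
        with pytest.raises(ValueError):
            simulate_discharge({}, seed=0)


class TestTides:
    def test_zero_amplitude_flat_no_highs(self):
        series, highs = simulate_tides(amplitude_m=0.0)
        assert (series.height_m == 0).all()
        assert len(highs) == 0

    def test_spring_maxima_spacing(self):
        from scipy.signal import find_peaks

        series, highs = simulate_tides(amplitude_m=2.0, seed=2, n_days=90)
        # spring maxima = local maxima of the high-tide height sequence;
        # ~29.5 semidiurnal highs per fortnight, so enforce wide separation
        idx, _ = find_peaks(highs.height_m.to_numpy(), distance=20)
        t = (
            highs.timestamp.iloc[idx].to_numpy() - series.timestamp.iloc[0].to_numpy()
        ) / np.timedelta64(1, "D")
        gaps = np.diff(t)
        assert len(gaps) >= 4
        assert np.all(np.abs(gaps - 14.765) < 0.6)

    def test_roughly_two_highs_per_day(self):
        _, highs = simulate_tides(amplitude_m=2.0, seed=2, n_days=30)
        per_day = highs.groupby(highs.timestamp.dt.normalize()).size()
        assert per_day.between(1, 3).all()
        assert abs(per_day.mean() - 2.0) < 0.3


class TestShorelineFixture:
    def test_apex_is_river_mouth(self, shoreline):
        assert shoreline.river_mouth in shoreline.vertices

    def test_offshore_extent_about_60_km(self, shoreline):
        ext = max(geodesic_km(v, shoreline.river_mouth) * np.cos(np.radians(37.0))
                  for v in shoreline.vertices)
        assert ext == pytest.approx(60.0, rel=0.02)

    def test_polyline_is_simple(self, shoreline):
        from shapely.geometry import LineString

        line = LineString([tuple(v) for v in shoreline.vertices])
        assert line.is_simple


class TestSurveySimulator:
    def test_all_whales_in_one_strip_counted_once(self):
        proj = LocalProjection(*PORT_NELSON)
        design = default_design(n_transects=1, transect_length_km=10.0)
        # a dense blob centred 3 km along the single transect, well inside
        # the 0.35 km strip
        u = np.array([np.sin(np.radians(35.0)), np.cos(np.radians(35.0))])
        cx, cy = 5.0 * u  # transect starts 2 km offshore, blob at along=3
        surface = DensitySurface.uniform(
            400.0, (cx - 0.1, cx + 0.1), (cy - 0.1, cy + 0.1), proj, cell_km=0.05
        )
        records = simulate_survey(design, surface, seed=8)
        # every simulated whale lies in the strip, so the summed counts must
        # equal the number of whales the same seeded stream generates
        positions = surface.sample_positions(np.random.default_rng([8, 4]))
        assert len(positions) > 0
        assert records["count"].sum() == len(positions)

    def test_uniform_density_expectation(self):
        proj = LocalProjection(*PORT_NELSON)
        design = default_design()
        lam = 0.5
        # surface generously covers every strip of the design
        surface = DensitySurface.uniform(lam, (-40, 40), (-15, 50), proj)
        strip_area = (
            len(design.transects) * 40.0 * 2 * design.strip_halfwidth_km
        )
        totals = [
            simulate_survey(design, surface, seed=s)["count"].sum()
            for s in range(200)
        ]
        expected = lam * strip_area
        se = np.sqrt(expected / 200)  # Poisson counts averaged over 200 reps
        assert np.mean(totals) == pytest.approx(expected, abs=3 * se)

    def test_zero_strip_width_warns_and_counts_zero(self):
        proj = LocalProjection(*PORT_NELSON)
        design = replace(default_design(), strip_halfwidth_km=0.0)
        surface = DensitySurface.uniform(1.0, (-10, 10), (0, 20), proj)
        with pytest.warns(UserWarning):
            records = simulate_survey(design, surface, seed=1)
        assert records["count"].sum() == 0

    def test_no_double_counting_across_transects(self):
        proj = LocalProjection(*PORT_NELSON)
        # overlapping strips: spacing < 2*halfwidth forces shared territory
        from estuaryuse.survey import SurveyDesign

        base = default_design(n_transects=2)
        design = SurveyDesign(
            transects=base.transects, spacing_km=3.7, strip_halfwidth_km=5.0
        )
        surface = DensitySurface.uniform(2.0, (-8, 8), (0, 30), proj)
        records = simulate_survey(design, surface, seed=3)
        positions = surface.sample_positions(np.random.default_rng([3, 4]))
        assert records["count"].sum() <= len(positions)
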