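"""Propagation laws, effect ranges, geodesics and GPS leg speeds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ahdtag.acoustics import PingDetection
from ahdtag.tag_io import GpsFix, ValidationError
from ahdtag.tracking import (
    PropagationModel,
    enu_offset_to_latlon,
    geodesic_distance,
    impact_area_ratio,
    leg_speeds,
    predicted_response_threshold,
    range_to_source,
    received_level,
    rl_vs_range_profile,
    solve_effect_range,
    transmission_loss,
)

SPH = PropagationModel("spherical", 1.5)
SPH0 = PropagationModel("spherical", 0.0)
CYL0 = PropagationModel("cylindrical", 0.0)


class TestTransmissionLoss:
    def test_spherical_with_absorption_at_1km(self):
        assert transmission_loss(1000.0, SPH) == pytest.approx(61.5)
        assert round(transmission_loss(1000.0, SPH)) == 62

    def test_cylindrical_at_1km(self):
        assert transmission_loss(1000.0, CYL0) == pytest.approx(30.0)

    def test_reference_range(self):
        # only the (negligible) 1-m absorption term remains at the reference
        assert transmission_loss(1.0, SPH) == pytest.approx(0.0, abs=2e-3)

    def test_below_reference_rejected(self):
        with pytest.raises(ValueError):
            transmission_loss(0.5, SPH)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(min_value=2.0, max_value=50_000.0),
           st.floats(min_value=1.01, max_value=1.5))
    def test_monotone_and_spherical_dominates(self, r, factor):
        assert transmission_loss(r * factor, SPH) > transmission_loss(r, SPH)
        assert transmission_loss(r, SPH0) >= transmission_loss(r, CYL0)


class TestReceivedLevel:
    def test_source_level_at_1m(self):
        assert received_level(189.0, 1.0, SPH) == pytest.approx(189.0, abs=2e-3)

    def test_reduced_source_at_1km(self):
        """SL 164 with TL rounded to 62 dB leaves ~102 dB re 1 uPa."""
        tl = round(transmission_loss(1000.0, SPH))
        assert 164.0 - tl == pytest.approx(102.0)

    def test_playback_design_level(self):
        assert received_level(158.0, 100.0, SPH0) == pytest.approx(118.0)


class TestEffectRange:
    def test_closed_form_no_absorption(self):
        r = solve_effect_range(190.0, 100.0, SPH0)
        assert r == pytest.approx(10 ** (90 / 20.0), rel=1e-4)  # 31.62 km

    @pytest.mark.parametrize("sl", [190.0, 164.0])
    def test_against_grid_scan_oracle(self, sl):
        """Brute-force 1-m grid scan agrees with the root-finder."""
        grid = np.arange(1.0, 100_000.0, 1.0)
        rl = received_level(sl, grid, SPH)
        oracle = grid[np.argmin(np.abs(rl - 100.0))]
        assert solve_effect_range(sl, 100.0, SPH) == pytest.approx(oracle, abs=2.0)

    def test_inverse_of_received_level(self):
        r = solve_effect_range(189.0, 110.0, SPH)
        assert received_level(189.0, r, SPH) == pytest.approx(110.0, abs=0.01)

    def test_threshold_above_source_rejected(self):
        with pytest.raises(ValueError):
            solve_effect_range(100.0, 120.0, SPH)


class TestImpactArea:
    def test_three_to_one_radius_is_factor_nine(self):
        assert impact_area_ratio(900.0, 300.0) == pytest.approx(9.0)

    def test_printed_radii_pair(self):
        assert impact_area_ratio(2200.0, 600.0) == pytest.approx(13.44, abs=0.01)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(min_value=1.0, max_value=1e5),
           st.floats(min_value=1.0, max_value=1e5))
    def test_reciprocal_product_is_one(self, r1, r2):
        assert impact_area_ratio(r1, r2) * impact_area_ratio(r2, r1) == pytest.approx(1.0)


def test_predicted_response_threshold():
    assert predicted_response_threshold() == pytest.approx(95.0)


class TestGeodesic:
    def test_meridian_arc(self):
        """0.009 deg of latitude is ~1000 m of meridian arc at mid-latitude."""
        assert geodesic_distance(45.0, 10.0, 45.009, 10.0) == pytest.approx(1000.0, abs=2.0)

    def test_symmetric_and_zero(self):
        assert geodesic_distance(55.0, 10.0, 55.0, 10.0) == 0.0
        d1 = geodesic_distance(55.0, 10.0, 55.01, 10.02)
        d2 = geodesic_distance(55.01, 10.02, 55.0, 10.0)
        assert d1 == pytest.approx(d2, rel=1e-9)

    def test_enu_round_trip(self):
        lat, lon = enu_offset_to_latlon(np.array([500.0]), np.array([-800.0]), 55.0, 10.0)
        d = geodesic_distance(55.0, 10.0, float(lat[0]), float(lon[0]))
        assert d == pytest.approx(np.hypot(500.0, 800.0), rel=1e-4)


class TestLegSpeeds:
    def test_simple_leg(self):
        lat2, lon2 = enu_offset_to_latlon(np.array([0.0]), np.array([300.0]), 55.0, 10.0)
        fixes = [GpsFix(0.0, 55.0, 10.0), GpsFix(200.0, float(lat2[0]), float(lon2[0]))]
        est = leg_speeds(fixes)
        assert est.speeds[0] == pytest.approx(1.5, rel=1e-3)

    def test_overspeed_fix_excluded(self):
        north = np.array([0.0, 300.0, 1800.0, 900.0])  # third fix implies 7.5 m/s
        times = [0.0, 200.0, 400.0, 600.0]
        fixes = []
        for t, n in zip(times, north):
            lat, lon = enu_offset_to_latlon(np.array([0.0]), np.array([n]), 55.0, 10.0)
            fixes.append(GpsFix(t, float(lat[0]), float(lon[0])))
        est = leg_speeds(fixes)
        assert est.excluded[2]
        assert not est.excluded[[0, 1, 3]].any()
        assert np.all(est.speeds <= 5.0)

    def test_duplicate_timestamps_rejected(self):
        fixes = [GpsFix(0.0, 55.0, 10.0), GpsFix(0.0, 55.001, 10.0)]
        with pytest.raises(ValidationError):
            leg_speeds(fixes)

    def test_straight_track_speed_recovered(self):
        rng = np.random.default_rng(0)
        fixes = []
        for k in range(12):
            t = 240.0 * k
            lat, lon = enu_offset_to_latlon(
                np.array([0.0]) + rng.normal(0, 5),
                np.array([1.8 * t]) + rng.normal(0, 5),
                55.0, 10.0,
            )
            fixes.append(GpsFix(t, float(lat[0]), float(lon[0])))
        est = leg_speeds(fixes)
        assert np.mean(est.speeds) == pytest.approx(1.8, abs=0.1)


class TestRlRangeProfile:
    def _track_and_pings(self, model, speed=1.2, r0=500.0, duration=300.0):
        times = np.arange(0.0, duration, 20.0)
        fixes = []
        for t in times:
            lat, lon = enu_offset_to_latlon(np.array([0.0]), np.array([r0 + speed * t]),
                                            55.0, 10.0)
            fixes.append(GpsFix(float(t), float(lat[0]), float(lon[0])))
        est = leg_speeds(fixes)
        pings = []
        for t in np.arange(0.0, duration, 2.0):
            r = r0 + speed * t
            rl = received_level(189.0, r, model)
            pings.append(PingDetection(float(t), rl, rl - 3.0, 30.0, True))
        return est, pings

    def test_constant_rl_constant_profile(self):
        est, _ = self._track_and_pings(SPH)
        pings = [PingDetection(float(t), 120.0, 117.0, 30.0, True)
                 for t in np.arange(0.0, 300.0, 2.0)]
        profile = rl_vs_range_profile(pings, est, 55.0, 10.0)
        assert profile["median_rl_db"].nunique() == 1

    def test_receding_profile_monotone_and_fits_model(self):
        est, pings = self._track_and_pings(SPH)
        profile = rl_vs_range_profile(pings, est, 55.0, 10.0)
        assert (np.diff(profile["median_rl_db"]) < 0).all()
        predicted = received_level(189.0, profile["range_m"].to_numpy(), SPH)
        rms = np.sqrt(np.mean((profile["median_rl_db"] - predicted) ** 2))
        assert rms < 1.5
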