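import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import circvar

import soarlift as sl
from conftest import make_fixes


class TestFilterFixes:
    def test_daylight_window_boundaries(self):
        fx = make_fixes(t0="2012-08-21 07:59:00", n=4, dt_s=60.0,
                        xs=np.arange(4.0))
        out = sl.filter_fixes(fx)
        # 07:59 dropped; 08:00, 08:01, 08:02 kept
        assert len(out) == 3
        assert out["t"].dt.strftime("%H:%M").tolist() == ["08:00", "08:01", "08:02"]

    def test_evening_cutoff_inclusive(self):
        fx = make_fixes(t0="2012-08-21 19:29:00", n=3, dt_s=60.0,
                        xs=np.arange(3.0))
        out = sl.filter_fixes(fx)
        assert out["t"].dt.strftime("%H:%M").tolist() == ["19:29", "19:30"]

    def test_consecutive_repeats_dropped(self):
        fx = make_fixes(n=4, xs=[0, 10, 10, 20], ys=[0, 5, 5, 9],
                        alts=[400, 401, 401, 402])
        out = sl.filter_fixes(fx)
        assert len(out) == 3
        assert out["x"].tolist() == [0, 10, 20]

    def test_missing_coordinates_dropped(self):
        fx = make_fixes(n=3, xs=[0, np.nan, 20])
        assert len(sl.filter_fixes(fx)) == 2

    def test_empty_input(self):
        fx = make_fixes(n=2, xs=[0, 1]).iloc[0:0]
        assert sl.filter_fixes(fx).empty

    def test_unsorted_times_rejected(self):
        fx = make_fixes(n=3, xs=np.arange(3.0))
        fx = fx.iloc[[0, 2, 1]]
        with pytest.raises(ValueError):
            sl.filter_fixes(fx)


class TestSegmentation:
    def test_window_arithmetic_41_fixes(self):
        # 41 fixes spanning 400 s: two 20-fix windows, 1-fix remainder dropped
        fx = make_fixes(n=41, xs=10.0 * np.arange(41))
        segs = sl.segment_track(fx)
        assert len(segs) == 2
        assert all(len(s) == 20 for s in segs)

    def test_minimum_fixes_boundary(self):
        # 10 fixes spanning 90 s: exactly the minimum, one segment
        fx = make_fixes(n=10, xs=10.0 * np.arange(10))
        assert len(sl.segment_track(fx)) == 1
        # 9 fixes: below the minimum, none
        fx = make_fixes(n=9, xs=10.0 * np.arange(9))
        assert len(sl.segment_track(fx)) == 0

    def test_partition_no_fix_in_two_segments(self):
        fx = make_fixes(n=100, xs=10.0 * np.arange(100))
        segs = sl.segment_track(fx)
        seen = pd.concat([s.fixes for s in segs])
        assert not seen.index.duplicated().any()
        for s in segs:
            span = (s.fixes["t"].iloc[-1] - s.fixes["t"].iloc[0]).total_seconds()
            assert span < 200.0 + 1e-9

    def test_gap_splits_sections(self):
        # 25 fixes, then a 100-s hole, then 25 fixes: windows re-anchor
        a = make_fixes(n=25, xs=10.0 * np.arange(25))
        b = make_fixes(t0="2012-08-21 09:05:40", n=25, xs=1000 + 10.0 * np.arange(25))
        segs = sl.segment_track(pd.concat([a, b], ignore_index=True))
        assert len(segs) == 2
        assert segs[1].fixes["x"].iloc[0] == 1000.0

    def test_sustained_slow_movement_splits(self):
        # 3 min of 10 m/s flight, 2 min stationary drift, 3 min flight
        speeds = [10.0] * 18 + [0.05] * 12 + [10.0] * 18
        xs = np.concatenate([[0.0], np.cumsum(np.array(speeds) * 10)])
        fx = make_fixes(n=len(xs), xs=xs)
        segs = sl.segment_track(fx, min_fixes=5)
        # the perched spell never lands inside a retained segment
        for s in segs:
            vv = sl.velocity_vectors(s.fixes)
            assert (vv["speed_ms"] > 1.0).mean() > 0.8


class TestVelocityAndCircular:
    def test_velocity_vector_definition(self):
        fx = make_fixes(n=2, xs=[0, 100], ys=[0, 0], alts=[400, 391.7])
        vv = sl.velocity_vectors(fx)
        assert vv["speed_ms"].iloc[0] == pytest.approx(10.0)
        assert vv["direction_deg"].iloc[0] == pytest.approx(90.0)
        assert vv["vertical_ms"].iloc[0] == pytest.approx(-0.83)

    def test_stationary_pair_undefined_direction(self):
        fx = make_fixes(n=2, xs=[5, 5], ys=[3, 3])
        vv = sl.velocity_vectors(fx)
        assert vv["speed_ms"].iloc[0] == 0.0
        assert np.isnan(vv["direction_deg"].iloc[0])

    @pytest.mark.parametrize("dirs,expected", [
        ([42.0] * 20, 0.0),
        (list(np.arange(0, 360, 18.0)), 1.0),
        ([0.0, 90.0], 1 - math.sqrt(2) / 2),
    ])
    def test_directional_variance_known_values(self, dirs, expected):
        assert sl.directional_variance(dirs) == pytest.approx(expected, abs=1e-12)

    def test_directional_variance_all_undefined_is_missing(self):
        assert np.isnan(sl.directional_variance([np.nan, np.nan]))

    def test_doubled_angular_variance_convention(self):
        dirs = [0.0, 90.0]
        assert sl.directional_variance(dirs, angular=True) == pytest.approx(
            2 * sl.directional_variance(dirs))

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 360, exclude_max=True), min_size=2, max_size=40))
    def test_directional_variance_matches_unit_vector_brute_force(self, dirs):
        sines = sum(math.sin(math.radians(d)) for d in dirs) / len(dirs)
        cosines = sum(math.cos(math.radians(d)) for d in dirs) / len(dirs)
        expected = 1 - math.hypot(sines, cosines)
        assert sl.directional_variance(dirs) == pytest.approx(expected, abs=1e-12)

    def test_directional_variance_agrees_with_scipy(self):
        rng = np.random.default_rng(3)
        dirs = rng.uniform(0, 360, 50)
        assert sl.directional_variance(dirs) == pytest.approx(
            circvar(np.radians(dirs)), abs=1e-12)


class TestTailwind:
    def test_downwind_headwind_and_oblique(self):
        west_wind = sl.WindScenario(270.0, 8.0)   # blows towards the east
        assert sl.tailwind_component(90.0, west_wind) == pytest.approx(1.0)
        east_wind = sl.WindScenario(90.0, 8.0)
        assert sl.tailwind_component(90.0, east_wind) == pytest.approx(-1.0)
        assert sl.tailwind_component(150.0, west_wind) == pytest.approx(0.5)

    def test_undefined_direction_is_missing(self):
        assert np.isnan(sl.tailwind_component(float("nan"), sl.WindScenario(0, 5)))


class TestHeave:
    def make_bursts(self, samples):
        cols = {f"s{i+1}": [v] for i, v in enumerate(samples)}
        return pd.DataFrame({"bird_id": ["b"], "day": ["d"],
                             "t_start": [pd.Timestamp("2012-08-21 09:00")], **cols})

    def test_constant_heave_zero_amplitude(self):
        assert sl.heave_amplitude(self.make_bursts([0.7] * 20)) == pytest.approx(0.0, abs=1e-12)

    def test_alternating_samples_amplitude_a(self):
        a = 0.25
        samples = [a, -a] * 10
        assert sl.heave_amplitude(self.make_bursts(samples)) == pytest.approx(a)

    def test_fewer_than_ten_readings_missing(self):
        assert np.isnan(sl.heave_amplitude(self.make_bursts([0.1] * 9)))
        assert not np.isnan(sl.heave_amplitude(self.make_bursts([0.1] * 10)))

    def test_no_bursts_missing(self):
        assert np.isnan(sl.heave_amplitude(None))


class TestFlightParameters:
    def test_straight_level_segment(self, flat_dem):
        fx = make_fixes(n=20, xs=2000 + 100.0 * np.arange(20),
                        ys=np.full(20, 2000.0), alts=np.full(20, 400.0))
        seg = sl.TrackSegment(fx, "b1", "2012-08-21")
        p = sl.flight_parameters(seg, flat_dem, sl.WindScenario(270.0, 8.0))
        assert p.ground_speed_ms == pytest.approx(10.0)
        assert p.vertical_speed_ms == pytest.approx(0.0)
        assert p.elevation_change_m == pytest.approx(0.0)
        assert p.directional_variance == pytest.approx(0.0, abs=1e-12)
        assert p.agl_m == pytest.approx(400.0)
        assert p.tailwind_component == pytest.approx(1.0)
        assert p.horizontal_displacement_m == pytest.approx(1900.0)

    def test_climbing_helix(self, flat_dem):
        # helix: radius 40 m, full turn per 80 s, climb 0.66 m/s
        t = 10.0 * np.arange(20)
        omega = 2 * math.pi / 80.0
        fx = make_fixes(n=20, xs=2000 + 40 * np.sin(omega * t),
                        ys=2000 + 40 * np.cos(omega * t),
                        alts=400 + 0.66 * t)
        seg = sl.TrackSegment(fx, "b1", "2012-08-21")
        p = sl.flight_parameters(seg, flat_dem)
        assert p.elevation_change_m == pytest.approx(0.66 * 190.0)
        assert p.vertical_speed_ms == pytest.approx(0.66)
        assert p.directional_variance > 0.85
        path_length = p.ground_speed_ms * 190.0
        assert p.horizontal_displacement_m < 0.2 * path_length

    def test_elevation_change_sign(self, flat_dem):
        alts = np.linspace(500.0, 334.0, 20)
        fx = make_fixes(n=20, xs=100.0 * np.arange(20) + 500, alts=alts)
        p = sl.flight_parameters(sl.TrackSegment(fx, "b", "d"), flat_dem)
        assert p.elevation_change_m == pytest.approx(-166.0)

    def test_rigid_translation_invariance(self, flat_dem):
        rng = np.random.default_rng(5)
        xs = 1500 + np.cumsum(rng.uniform(-60, 100, 20))
        ys = 1500 + np.cumsum(rng.uniform(-60, 100, 20))
        alts = 400 + np.cumsum(rng.uniform(-5, 5, 20))
        fx1 = make_fixes(n=20, xs=xs, ys=ys, alts=alts)
        fx2 = make_fixes(n=20, xs=xs + 777, ys=ys + 333, alts=alts)
        p1 = sl.flight_parameters(sl.TrackSegment(fx1, "b", "d"), flat_dem)
        p2 = sl.flight_parameters(sl.TrackSegment(fx2, "b", "d"), flat_dem)
        for attr in ("horizontal_displacement_m", "elevation_change_m",
                     "ground_speed_ms", "vertical_speed_ms", "directional_variance"):
            assert getattr(p2, attr) == pytest.approx(getattr(p1, attr), rel=1e-12)

    def test_displacement_bounded_by_path_length(self, flat_dem):
        rng = np.random.default_rng(9)
        for _ in range(5):
            xs = 2000 + np.cumsum(rng.uniform(-80, 80, 15))
            ys = 2000 + np.cumsum(rng.uniform(-80, 80, 15))
            fx = make_fixes(n=15, xs=xs, ys=ys)
            p = sl.flight_parameters(sl.TrackSegment(fx, "b", "d"), flat_dem)
            vv = sl.velocity_vectors(fx)
            assert p.horizontal_displacement_m <= (vv["speed_ms"] * 10.0).sum() + 1e-9
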