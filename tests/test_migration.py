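"""Departures, forays, straightness geometry, path and rate metrics."""

import math
from datetime import datetime, timedelta, timezone

import numpy as np
import pytest
from shapely.geometry import Point

from turtletrack.geo import haversine_km
from turtletrack.migration import (MigrationPath, day_night_rate_test,
                                   detect_departure, detect_forays, haversine,
                                   path_metrics, pelagic_mask,
                                   straightness_3pt)
from turtletrack.qc import flag_implausible, speed_filter
from turtletrack.synthetic import SimConfig, observe_fixes, simulate_track
from turtletrack.trackio import FixRecord
from .conftest import T0, make_fix

START = datetime(2016, 8, 15, tzinfo=timezone.utc)
KM_PER_DEG = 111.19


class TestHaversineOp:
    def test_identical(self):
        assert haversine((-64.8, 32.3), (-64.8, 32.3)) == 0.0

    def test_one_degree(self):
        assert haversine((0.0, 0.0), (0.0, 1.0)) == pytest.approx(111.19, abs=0.01)

    def test_symmetry(self):
        a, b = (-64.8, 32.3), (-79.2, 25.7)
        assert haversine(a, b) == pytest.approx(haversine(b, a), rel=1e-12)


class TestStraightness:
    def test_collinear_equally_spaced(self):
        fixes = [(i * 0.1, 0.0) for i in range(10)]  # due east
        assert straightness_3pt(fixes) == pytest.approx(1.0, abs=1e-9)

    def test_right_angle_equal_legs(self):
        # 10-km legs at a right angle: d(A,C) = sqrt(2) * leg
        leg_deg = 10.0 / KM_PER_DEG
        fixes = [(0.0, 0.0), (0.0, leg_deg), (leg_deg / math.cos(math.radians(leg_deg)), leg_deg)]
        s = straightness_3pt(fixes)
        assert s == pytest.approx(math.sqrt(2) / 2, abs=1e-3)

    def test_duplicates_dropped(self):
        fixes = [(0, 0), (0, 0), (0, 0.1), (0, 0.2), (0, 0.2)]
        assert straightness_3pt(fixes) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_distinct_errors(self):
        with pytest.raises(ValueError):
            straightness_3pt([(0, 0), (0, 0), (0, 1)])

    def test_bounded(self):
        rng = np.random.default_rng(0)
        pts = np.cumsum(rng.normal(0, 0.05, (50, 2)), axis=0)
        s = straightness_3pt([tuple(p) for p in pts])
        assert 0.0 < s <= 1.0


def platform(cfg):
    return Point(*cfg.centers["release"]).buffer(0.15)


class TestDepartureDetection:
    def test_resident_track_none(self):
        cfg = SimConfig(seed=0)
        fixes = observe_fixes(simulate_track(cfg, 20))
        assert detect_departure(fixes, platform(cfg)) is None

    def test_synthetic_departure_within_24h(self):
        cfg = SimConfig(seed=1, migration_start=START + timedelta(days=30))
        tr = simulate_track(cfg, 45)
        fixes, _ = flag_implausible(observe_fixes(tr))
        fixes = speed_filter(fixes)
        dep = detect_departure(fixes, platform(cfg))
        assert dep is not None
        err_h = abs((dep.departure_time
                     - tr.truth["departure_time"]).total_seconds()) / 3600
        assert err_h <= 24.0

    def test_brief_outside_loop_is_not_departure(self):
        cfg = SimConfig(seed=0)
        lon0, lat0 = cfg.centers["release"]
        fixes = []
        for h in range(0, 24 * 20, 2):
            if 24 * 5 <= h < 24 * 7:   # 2-day excursion 20 km out, then home
                lat = lat0 + 20.0 / KM_PER_DEG
            else:
                lat = lat0
            fixes.append(make_fix(hours=h, lon=lon0, lat=lat))
        assert detect_departure(fixes, platform(cfg)) is None


class TestForays:
    def _fixes_with_loop(self, cfg, loop_start_d, loop_days, dist_km=8.0):
        lon0, lat0 = cfg.centers["release"]
        fixes = []
        for h in range(0, 24 * 40, 2):
            d = h / 24.0
            if loop_start_d <= d < loop_start_d + loop_days:
                lat = lat0 + dist_km / KM_PER_DEG
            else:
                lat = lat0
            fixes.append(make_fix(hours=h, lon=lon0, lat=lat))
        return fixes

    def test_six_day_loop_found(self):
        cfg = SimConfig(seed=0)
        home = Point(*cfg.centers["release"]).buffer(0.02)
        fixes = self._fixes_with_loop(cfg, loop_start_d=20, loop_days=6)
        dep_time = T0 + timedelta(days=40)
        events = detect_forays(fixes, home, departure_time=dep_time)
        assert len(events) == 1
        assert events[0].returned
        assert 5.5 <= events[0].duration_days <= 6.5
        assert events[0].max_displacement_km == pytest.approx(8.0, abs=1.0)

    def test_no_excursion_no_foray(self):
        cfg = SimConfig(seed=0)
        home = Point(*cfg.centers["release"]).buffer(0.02)
        fixes = [make_fix(hours=h) for h in range(0, 24 * 35, 2)]
        assert detect_forays(fixes, home,
                             departure_time=T0 + timedelta(days=35)) == []

    def test_two_day_excursion_below_threshold(self):
        cfg = SimConfig(seed=0)
        home = Point(*cfg.centers["release"]).buffer(0.02)
        fixes = self._fixes_with_loop(cfg, loop_start_d=20, loop_days=2)
        assert detect_forays(fixes, home,
                             departure_time=T0 + timedelta(days=40)) == []


def constant_westward_path(rate_kmh=2.0, n=60, dt_h=2.0, lat=30.0):
    fixes = []
    lon = -60.0
    for i in range(n):
        fixes.append(FixRecord("m", START + timedelta(hours=i * dt_h),
                               lon, lat, 8, 5.0, depth_at_fix=1000.0,
                               current_u=0.3, current_v=0.4))
        lon -= rate_kmh * dt_h / (KM_PER_DEG * math.cos(math.radians(lat)))
    return fixes


class TestPathMetrics:
    def test_constant_westward(self):
        m = path_metrics(MigrationPath(constant_westward_path()))
        assert m.rate_mean_kmh == pytest.approx(2.0, abs=0.01)
        assert m.bearing_mean_deg == pytest.approx(270.0, abs=1.0)
        assert m.straightness > 0.999
        assert m.current_mean_ms == pytest.approx(0.5, abs=1e-9)

    def test_path_at_least_endpoint_distance(self):
        rng = np.random.default_rng(1)
        fixes = []
        lon, lat = -60.0, 30.0
        for i in range(50):
            lon += rng.normal(-0.05, 0.03)
            lat += rng.normal(-0.02, 0.03)
            fixes.append(FixRecord("m", START + timedelta(hours=2 * i),
                                   lon, lat, 8, 5.0))
        m = path_metrics(MigrationPath(fixes))
        endpoint = haversine_km(fixes[0].lon, fixes[0].lat,
                                fixes[-1].lon, fixes[-1].lat)
        assert m.total_path_km >= endpoint - 1e-9

    def test_long_gaps_excluded_from_rates(self):
        fixes = constant_westward_path(n=10)
        # insert a 3-day gap mid-path: the jump step must not enter rates
        late = [FixRecord("m", f.timestamp + timedelta(days=3), f.lon - 1.0,
                          f.lat, 8, 5.0) for f in constant_westward_path(n=10)]
        m = path_metrics(MigrationPath(fixes + late))
        assert m.rate_mean_kmh == pytest.approx(2.0, abs=0.05)

    def test_pelagic_mask_by_depth_and_polygon(self):
        shallow = make_fix(depth_at_fix=50.0)
        deep = make_fix(hours=2, depth_at_fix=900.0)
        nodepth_in = make_fix(hours=4)
        nodepth_out = make_fix(hours=6, lon=-60.0, lat=28.0)
        poly = Point(-64.8, 32.3).buffer(1.0)
        masked = pelagic_mask([shallow, deep, nodepth_in, nodepth_out], poly)
        assert masked == [deep, nodepth_out]


class TestDayNightRates:
    def _path(self, seed, day_speed=2.4, night_speed=2.0):
        from turtletrack.useareas import solar_elevation_deg

        rng = np.random.default_rng(seed)
        t, lon, lat = START, -65.0, 30.0
        fixes = [FixRecord("m", t, lon, lat, 8, 5.0)]
        for _ in range(200):
            day = solar_elevation_deg(lon, lat, t + timedelta(hours=1)) > 0
            sp = max(rng.normal(day_speed if day else night_speed, 0.3), 0.1)
            d = sp * 2.0 / KM_PER_DEG
            lat -= d / math.sqrt(2)
            lon -= d / math.sqrt(2) / math.cos(math.radians(lat))
            t += timedelta(hours=2)
            fixes.append(FixRecord("m", t, lon, lat, 8, 5.0))
        return MigrationPath(fixes)

    def test_day_faster_detected(self):
        wins = 0
        for seed in range(10):
            d, n, p = day_night_rate_test(self._path(seed))
            wins += (d > n and p < 0.05)
        assert wins >= 9

    def test_null_unbiased(self):
        diffs, sig = [], 0
        for seed in range(10):
            d, n, p = day_night_rate_test(self._path(seed, 2.2, 2.2))
            diffs.append(d - n)
            sig += p < 0.05
        assert abs(np.mean(diffs)) < 0.15
        assert sig <= 3

    def test_single_photoperiod_errors(self):
        # 5 fixes spanning 8 h of one night
        fixes = [FixRecord("m", START + timedelta(hours=2 + 2 * i),
                           -65.0, 30.0 - i * 0.05, 8, 5.0) for i in range(5)]
        with pytest.raises(ValueError):
            day_night_rate_test(MigrationPath(fixes))
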