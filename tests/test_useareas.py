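"""Fix labeling, use-area discovery/classification, occupancy, dive means."""

from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point

from turtletrack.geo import LocalProjection
from turtletrack.qc import flag_implausible, speed_filter
from turtletrack.synthetic import SimConfig, observe_fixes, simulate_track
from turtletrack.trackio import DiveHistogram, TemperatureSeries
from turtletrack.useareas import (area_center_distances,
                                  distance_temperature_correlation,
                                  find_use_areas, label_fixes,
                                  occupancy_histogram, season_of,
                                  seasonal_occupancy_shift,
                                  solar_elevation_deg, weighted_mean_bins)
from .conftest import T0, make_fix


class TestLabeling:
    def test_season_rule(self):
        assert season_of(datetime(2017, 1, 10)) == "cool"
        assert season_of(datetime(2017, 4, 30)) == "cool"
        assert season_of(datetime(2017, 5, 1)) == "warm"
        assert season_of(datetime(2017, 11, 30)) == "warm"
        assert season_of(datetime(2017, 12, 1)) == "cool"

    def test_local_noon_in_june_is_day(self):
        # Bermuda local noon = 16:00 UTC
        when = datetime(2017, 6, 21, 16, 0, tzinfo=timezone.utc)
        assert solar_elevation_deg(-64.8, 32.3, when) > 60

    def test_local_midnight_is_night(self):
        when = datetime(2017, 6, 21, 4, 0, tzinfo=timezone.utc)
        assert solar_elevation_deg(-64.8, 32.3, when) < -20

    def test_point_in_seagrass(self, seagrass_habitat):
        inside = make_fix(lon=-64.800, lat=32.300)
        outside = make_fix(lon=-64.70, lat=32.40)
        labeled = label_fixes([inside, outside], seagrass_habitat)
        assert labeled[0].in_seagrass and not labeled[1].in_seagrass

    def test_depth_from_bathymetry(self, seagrass_habitat, flat_bathymetry):
        lf = label_fixes([make_fix()], seagrass_habitat, flat_bathymetry)[0]
        assert lf.bathymetric_depth == pytest.approx(3.0)


def classify_truth(area, cfg):
    """Truth kind of a discovered area: nearest simulated center."""
    mapping = {"foraging": "foraging_f", "day_rest": "rest_day_r",
               "night_rest": "rest_night_r", "refuge": "cool_refuge_c"}
    best, best_d = None, np.inf
    for role in ("foraging", "day_rest", "night_rest", "refuge"):
        c = cfg.centers[role]
        d = Point(area.mean_center).distance(Point(c))
        if d < best_d:
            best, best_d = mapping[role], d
    return best


class TestFindUseAreas:
    def test_three_centers_recovered(self, seagrass_habitat, flat_bathymetry):
        cfg = SimConfig(seed=1, temp_amplitude=0.0, temp_mean=25.0)
        tr = simulate_track(cfg, 30)
        fixes, _ = flag_implausible(observe_fixes(tr))
        fixes = speed_filter(fixes)
        labeled = label_fixes(fixes, seagrass_habitat, flat_bathymetry)
        areas = find_use_areas(labeled)
        assert len(areas) == 3
        for a in areas:
            assert a.kind == classify_truth(a, cfg)
            assert a.size_km2 > 0

    def test_single_tight_cluster_is_foraging(self, seagrass_habitat):
        rng = np.random.default_rng(0)
        fixes = [make_fix(hours=24 * i / 50 + 14,  # mid-day local
                          lon=-64.8 + rng.normal(0, 3e-4),
                          lat=32.3 + rng.normal(0, 3e-4)) for i in range(50)]
        labeled = label_fixes(fixes, seagrass_habitat)
        areas = find_use_areas(labeled)
        assert len(areas) == 1 and areas[0].kind == "foraging_f"

    def test_cool_refuge_override(self, seagrass_habitat, flat_bathymetry):
        cfg = SimConfig(seed=5)
        tr = simulate_track(cfg, 150,
                            start=datetime(2016, 11, 1, tzinfo=timezone.utc))
        fixes, _ = flag_implausible(observe_fixes(tr))
        fixes = speed_filter(fixes)
        labeled = label_fixes(fixes, seagrass_habitat, flat_bathymetry)
        areas = find_use_areas(labeled)
        kinds = {a.kind for a in areas}
        assert "cool_refuge_c" in kinds
        refuge = next(a for a in areas if a.kind == "cool_refuge_c")
        assert refuge.usage_timing["cool"] >= 0.8
        assert refuge.mean_depth_m >= 1.5 * 3.0

    def test_order_independent(self, seagrass_habitat, flat_bathymetry):
        cfg = SimConfig(seed=2, temp_amplitude=0.0, temp_mean=25.0)
        tr = simulate_track(cfg, 20)
        fixes, _ = flag_implausible(observe_fixes(tr))
        labeled = label_fixes(fixes, seagrass_habitat, flat_bathymetry)
        fwd = find_use_areas(labeled)
        rev = find_use_areas(list(reversed(labeled)))
        assert sorted(a.kind for a in fwd) == sorted(a.kind for a in rev)
        assert sorted(round(a.size_km2, 9) for a in fwd) == \
               sorted(round(a.size_km2, 9) for a in rev)

    def test_members_disjoint(self, seagrass_habitat, flat_bathymetry):
        cfg = SimConfig(seed=3, temp_amplitude=0.0, temp_mean=25.0)
        tr = simulate_track(cfg, 20)
        fixes, _ = flag_implausible(observe_fixes(tr))
        labeled = label_fixes(fixes, seagrass_habitat, flat_bathymetry)
        areas = find_use_areas(labeled)
        seen = set()
        for a in areas:
            assert not (seen & set(a.member_indices.tolist()))
            seen |= set(a.member_indices.tolist())


class TestCenterDistances:
    def test_hundredth_degree_latitude(self, seagrass_habitat):
        class A:
            mean_center = (-64.8, 32.30)
        class B:
            mean_center = (-64.8, 32.31)
        d = area_center_distances([A(), B()])
        assert d[0, 1] == pytest.approx(1111.9, abs=0.5)
        assert d[0, 1] == d[1, 0]
        assert d[0, 0] == 0.0


class TestOccupancy:
    def test_all_in_seagrass_gives_ones(self, seagrass_habitat):
        fixes = [make_fix(hours=2 * h) for h in range(48)]
        labeled = label_fixes(fixes, seagrass_habitat)
        occ = occupancy_histogram(labeled, season="warm")
        assert all(p == 1.0 for p in occ.proportions if p is not None)

    def test_none_in_seagrass_gives_zeros(self, seagrass_habitat):
        fixes = [make_fix(hours=2 * h, lon=-64.7, lat=32.4) for h in range(48)]
        labeled = label_fixes(fixes, seagrass_habitat)
        occ = occupancy_histogram(labeled, season="warm")
        assert all(p == 0.0 for p in occ.proportions if p is not None)

    def test_bimodal_schedule_detected(self, seagrass_habitat, flat_bathymetry):
        cfg = SimConfig(seed=4, temp_amplitude=0.0, temp_mean=25.0)
        tr = simulate_track(cfg, 40)
        fixes, _ = flag_implausible(observe_fixes(tr))
        labeled = label_fixes(fixes, seagrass_habitat, flat_bathymetry)
        occ = occupancy_histogram(labeled, season="warm")
        assert occ.bimodality is not None and occ.bimodality > 1.0

    def test_proportions_bounded(self, seagrass_habitat, resident_fixes):
        labeled = label_fixes(resident_fixes, seagrass_habitat)
        occ = occupancy_histogram(labeled, season="warm")
        assert all(0.0 <= p <= 1.0 for p in occ.proportions if p is not None)


class TestWeightedMeanBins:
    def hist(self, edges, props):
        return DiveHistogram("t", T0, T0 + timedelta(days=1), "depth_m",
                             edges, props)

    def test_all_mass_one_bin(self):
        h = self.hist([1, 2, 3, 4, 5], [0, 0, 1.0, 0, 0, 0])
        assert weighted_mean_bins(h) == pytest.approx(2.5)

    def test_split_mass(self):
        h = self.hist([1, 2, 3, 4], [0, 0.5, 0, 0.5, 0])
        assert weighted_mean_bins(h) == pytest.approx((1.5 + 3.5) / 2)

    def test_open_bin_midpoint_rule(self):
        # edges ... 24, 29: open bin ">29" uses 29 + 5/2 = 31.5
        h = self.hist([24, 29], [0, 0, 1.0])
        assert weighted_mean_bins(h) == pytest.approx(31.5)


class TestTemperatureCorrelation:
    def _buoy(self, temps, start="2017-01-01"):
        ts = pd.date_range(start, periods=len(temps), freq="D", tz="UTC")
        return TemperatureSeries("b", ts, np.asarray(temps, float))

    def test_linear_negative_gives_minus_one(self):
        temps = np.linspace(18, 28, 30)
        fixes = [make_fix(hours=24 * i, lat=32.3 + (28 - temps[i]) * 0.01)
                 for i in range(30)]
        labeled = label_fixes(fixes, None)
        res = distance_temperature_correlation(
            labeled, (-64.8, 32.3),
            self._buoy(temps, start=fixes[0].timestamp.date().isoformat()))
        assert res.r == pytest.approx(-1.0, abs=1e-6)
        assert res.p_value < 1e-10

    def test_independent_has_small_r(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            temps = rng.uniform(18, 28, 200)
            fixes = [make_fix(hours=24 * i, lat=32.3 + abs(rng.normal(0, 0.01)))
                     for i in range(200)]
            labeled = label_fixes(fixes, None)
            res = distance_temperature_correlation(
                labeled, (-64.8, 32.3),
                self._buoy(temps, start=fixes[0].timestamp.date().isoformat()))
            hits += abs(res.r) < 0.2
        assert hits >= 19

    def test_constant_temperature_errors(self):
        fixes = [make_fix(hours=24 * i, lat=32.3 + i * 0.001) for i in range(10)]
        labeled = label_fixes(fixes, None)
        with pytest.raises(ValueError, match="constant"):
            distance_temperature_correlation(
                labeled, (-64.8, 32.3),
                self._buoy(np.full(10, 20.0),
                           start=fixes[0].timestamp.date().isoformat()))


class TestSeasonalShift:
    def test_refuge_routing_raises_cool_offmeadow_time(self, seagrass_habitat,
                                                       flat_bathymetry):
        cfg = SimConfig(seed=6)
        tr = simulate_track(cfg, 200,
                            start=datetime(2016, 10, 1, tzinfo=timezone.utc))
        fixes, _ = flag_implausible(observe_fixes(tr))
        labeled = label_fixes(fixes, seagrass_habitat, flat_bathymetry)
        tab = seasonal_occupancy_shift(labeled).set_index(["season", "photoperiod"])
        assert (tab.loc[("cool", "day"), "off_seagrass"] >
                tab.loc[("warm", "day"), "off_seagrass"])

    def test_proportions_bounded(self, seagrass_habitat, resident_fixes):
        labeled = label_fixes(resident_fixes, seagrass_habitat)
        with pytest.warns(UserWarning):   # 30-day track spans one season
            tab = seasonal_occupancy_shift(labeled)
        vals = tab["off_seagrass"].dropna()
        assert ((vals >= 0) & (vals <= 1)).all()
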