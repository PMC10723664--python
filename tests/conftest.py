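"""Shared fixtures: small synthetic tracks, habitat maps, fix factories."""

from datetime import datetime, timedelta, timezone

import numpy as np
import pytest
from shapely.geometry import Point

from turtletrack.synthetic import SimConfig, observe_fixes, simulate_track
from turtletrack.trackio import FixRecord, HabitatMap, HabitatPolygon

T0 = datetime(2016, 8, 15, 0, 0, tzinfo=timezone.utc)


def make_fix(hours=0.0, lon=-64.8, lat=32.3, nsat=8, residual=5.0,
             tag="t1", **kw) -> FixRecord:
    return FixRecord(tag_id=tag, timestamp=T0 + timedelta(hours=hours),
                     lon=lon, lat=lat, n_satellites=nsat, residual=residual, **kw)


@pytest.fixture(scope="session")
def resident_track():
    """A 30-day resident track with default study-condition parameters."""
    return simulate_track(SimConfig(seed=7), n_days=30)


@pytest.fixture(scope="session")
def resident_fixes(resident_track):
    return observe_fixes(resident_track)


@pytest.fixture(scope="session")
def seagrass_habitat():
    """One seagrass polygon centered on the default foraging center."""
    cfg = SimConfig()
    lon, lat = cfg.centers["foraging"]
    return HabitatMap([HabitatPolygon(Point(lon, lat).buffer(0.003),
                                      "seagrass", "meadow")])


@pytest.fixture(scope="session")
def flat_bathymetry():
    """Depth lookup: 3 m on the meadow, 8 m off it, 12 m near the refuge."""
    cfg = SimConfig()
    f = Point(cfg.centers["foraging"])
    r = Point(cfg.centers["refuge"])

    def depth(lon, lat):
        p = Point(lon, lat)
        if p.distance(f) < 0.003:
            return 3.0
        if p.distance(r) < 0.01:
            return 12.0
        return 8.0

    return depth
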