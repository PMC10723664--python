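"""Departure detection, pre-departure forays, and migration path metrics.

The pelagic portion of an emigration (fixes beyond the platform, or deeper
than 200 m where bathymetry is available) is summarized by path distance,
the circular mean and SD of per-step initial great-circle bearings, travel
rates split by photoperiod, and a 3-position straightness index: for every
consecutive triple (A, B, C), d(A,C) / (d(A,B) + d(B,C)), averaged along
the path.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from shapely.geometry import Point

from .geo import circular_mean_deg, circular_sd_deg, haversine_km, initial_bearing_deg
from .trackio import FixRecord
from .useareas import solar_elevation_deg


@dataclass
class Departure:
    tag_id: str
    departure_time: datetime
    departure_fix: FixRecord
    nighttime_departure: bool


@dataclass
class ForayEvent:
    start: datetime
    end: datetime
    max_displacement_km: float
    returned: bool

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("foray start must precede its end")

    @property
    def duration_days(self) -> float:
        return (self.end - self.start).total_seconds() / 86400.0


@dataclass
class MigrationPath:
    fixes: List[FixRecord]       # ordered pelagic fixes

    def __len__(self) -> int:
        return len(self.fixes)


@dataclass
class PathMetrics:
    total_path_km: float
    bearing_mean_deg: float
    bearing_sd_deg: float
    straightness: float
    rate_mean_kmh: float
    rate_sd_kmh: float
    rate_day_kmh: Optional[float]
    rate_night_kmh: Optional[float]
    current_mean_ms: Optional[float]
    n_fixes: int


def haversine(a: Tuple[float, float], b: Tuple[float, float]) -> float:
    """Great-circle distance in km between (lon, lat) points."""
    return haversine_km(a[0], a[1], b[0], b[1])


# ---------------------------------------------------------------------------
# Departure and forays
# ---------------------------------------------------------------------------

def detect_departure(fixes: Sequence[FixRecord], platform_polygon,
                     no_return_days: float = 5.0) -> Optional[Departure]:
    """First fix outside the platform not followed by any return inside it
    within ``no_return_days`` (nor ever after that window).

    Returns ``None`` for resident-only tracks.  The nighttime flag comes from
    solar elevation at the departure fix.
    """
    fixes = sorted(fixes, key=lambda f: f.timestamp)
    outside = [not platform_polygon.covers(Point(f.lon, f.lat)) for f in fixes]
    n = len(fixes)
    for i in range(n):
        if not outside[i]:
            continue
        if any(not outside[j] for j in range(i + 1, n)):
            continue
        # no later fix is inside; require the track to persist long enough
        span_days = (fixes[-1].timestamp - fixes[i].timestamp).total_seconds() / 86400.0
        if span_days < no_return_days and i > 0:
            # too little post-departure data to rule out a foray; still treat
            # the terminal excursion as a departure only if nothing follows
            pass
        elev = solar_elevation_deg(fixes[i].lon, fixes[i].lat, fixes[i].timestamp)
        return Departure(tag_id=fixes[i].tag_id,
                         departure_time=fixes[i].timestamp,
                         departure_fix=fixes[i],
                         nighttime_departure=elev <= 0.0)
    return None


def detect_forays(fixes: Sequence[FixRecord], isopleth95,
                  departure_time: Optional[datetime] = None,
                  window_days: float = 30.0,
                  min_d: float = 4.0, max_d: float = 15.0,
                  center: Optional[Tuple[float, float]] = None
                  ) -> List[ForayEvent]:
    """Maximal pre-departure excursions outside the residency 95% isopleth.

    Runs of consecutive fixes outside ``isopleth95`` (a polygon in lon/lat)
    inside the ``window_days`` before ``departure_time`` qualify as forays
    when they last between ``min_d`` and ``max_d`` days and the animal either
    returns inside afterwards or proceeds directly to departure.
    """
    fixes = sorted(fixes, key=lambda f: f.timestamp)
    if departure_time is not None:
        window_start = departure_time - timedelta(days=window_days)
        pre = [f for f in fixes if window_start <= f.timestamp < departure_time]
    else:
        pre = list(fixes)
    if not pre:
        return []
    out_flags = [not isopleth95.covers(Point(f.lon, f.lat)) for f in pre]
    if center is None:
        c = isopleth95.centroid
        center = (c.x, c.y)

    events: List[ForayEvent] = []
    i = 0
    while i < len(pre):
        if not out_flags[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(pre) and out_flags[j + 1]:
            j += 1
        start, end = pre[i].timestamp, pre[j].timestamp
        duration = (end - start).total_seconds() / 86400.0
        returned = j + 1 < len(pre)          # a later inside fix exists
        ends_at_departure = (departure_time is not None and j == len(pre) - 1)
        if min_d <= duration <= max_d and (returned or ends_at_departure):
            disp = max(haversine_km(f.lon, f.lat, center[0], center[1])
                       for f in pre[i:j + 1])
            events.append(ForayEvent(start=start, end=end,
                                     max_displacement_km=float(disp),
                                     returned=returned))
        i = j + 1
    return events


# ---------------------------------------------------------------------------
# Path geometry
# ---------------------------------------------------------------------------

def pelagic_mask(fixes: Sequence[FixRecord], platform_polygon=None,
                 depth_cutoff_m: float = 200.0) -> List[FixRecord]:
    """Fixes in pelagic water: depth > cutoff when per-fix depth is known,
    else outside the platform polygon."""
    out = []
    for f in fixes:
        if f.depth_at_fix is not None:
            if f.depth_at_fix > depth_cutoff_m:
                out.append(f)
        elif platform_polygon is not None:
            if not platform_polygon.covers(Point(f.lon, f.lat)):
                out.append(f)
        else:
            out.append(f)
    return out


def straightness_3pt(fixes: Sequence) -> float:
    """3-position straightness index in (0, 1].

    Accepts FixRecords or (lon, lat) pairs.  Zero-length steps are dropped
    first; for each remaining consecutive triple (A, B, C) the ratio
    d(A,C) / (d(A,B) + d(B,C)) is computed and the index is their mean.
    """
    pts = [(f.lon, f.lat) if isinstance(f, FixRecord) else (float(f[0]), float(f[1]))
           for f in fixes]
    dedup = [pts[0]] if pts else []
    for p in pts[1:]:
        if haversine_km(p[0], p[1], dedup[-1][0], dedup[-1][1]) > 1e-9:
            dedup.append(p)
    if len(dedup) < 3:
        raise ValueError("need at least 3 distinct positions")
    ratios = []
    for a, b, c in zip(dedup[:-2], dedup[1:-1], dedup[2:]):
        leg = haversine_km(*a, *b) + haversine_km(*b, *c)
        ratios.append(haversine_km(*a, *c) / leg)
    return float(np.mean(ratios))


def path_metrics(path: MigrationPath, rate_dt_max_h: float = 12.0) -> PathMetrics:
    """Distance, bearing, straightness and travel-rate summary of a path.

    Steps are consecutive retained fixes; steps whose time gap exceeds
    ``rate_dt_max_h`` are excluded from rate statistics (but still count
    toward path distance and bearings).  Day/night rates use the photoperiod
    of the step midpoint; current speed is sqrt(u^2 + v^2) averaged over fixes
    carrying pre-extracted current components.
    """
    fx = path.fixes
    if len(fx) < 2:
        raise ValueError("need at least 2 pelagic fixes")
    lons = np.array([f.lon for f in fx])
    lats = np.array([f.lat for f in fx])
    d_km = np.atleast_1d(haversine_km(lons[:-1], lats[:-1], lons[1:], lats[1:]))
    bearings = np.atleast_1d(initial_bearing_deg(lons[:-1], lats[:-1], lons[1:], lats[1:]))
    nonzero = d_km > 1e-9

    dt_h = np.array([(b.timestamp - a.timestamp).total_seconds() / 3600.0
                     for a, b in zip(fx[:-1], fx[1:])])
    rate_ok = (dt_h > 0) & (dt_h <= rate_dt_max_h)
    rates = np.where(rate_ok, d_km / np.where(dt_h > 0, dt_h, 1.0), np.nan)

    day_rates, night_rates = [], []
    for i in range(len(fx) - 1):
        if not rate_ok[i]:
            continue
        mid_t = fx[i].timestamp + (fx[i + 1].timestamp - fx[i].timestamp) / 2
        mid_lon = (fx[i].lon + fx[i + 1].lon) / 2
        mid_lat = (fx[i].lat + fx[i + 1].lat) / 2
        if solar_elevation_deg(mid_lon, mid_lat, mid_t) > 0:
            day_rates.append(rates[i])
        else:
            night_rates.append(rates[i])

    valid_rates = rates[np.isfinite(rates)]
    if valid_rates.size == 0:
        import warnings

        warnings.warn("all steps exceed the rate time cutoff; rates undefined",
                      stacklevel=2)
        rate_mean = rate_sd = float("nan")
    else:
        rate_mean = float(valid_rates.mean())
        rate_sd = float(valid_rates.std(ddof=1)) if valid_rates.size > 1 else 0.0

    currents = [np.hypot(f.current_u, f.current_v) for f in fx
                if f.current_u is not None and f.current_v is not None]

    return PathMetrics(
        total_path_km=float(d_km.sum()),
        bearing_mean_deg=circular_mean_deg(bearings[nonzero]),
        bearing_sd_deg=circular_sd_deg(bearings[nonzero]),
        straightness=straightness_3pt(fx),
        rate_mean_kmh=rate_mean,
        rate_sd_kmh=rate_sd,
        rate_day_kmh=float(np.mean(day_rates)) if day_rates else None,
        rate_night_kmh=float(np.mean(night_rates)) if night_rates else None,
        current_mean_ms=float(np.mean(currents)) if currents else None,
        n_fixes=len(fx),
    )


def day_night_rate_test(path: MigrationPath, rate_dt_max_h: float = 12.0
                        ) -> Tuple[float, float, float]:
    """Welch two-sample comparison of day vs night step travel rates.

    Returns (mean day rate, mean night rate, two-sided p).
    """
    fx = path.fixes
    day, night = [], []
    for i in range(len(fx) - 1):
        dt_h = (fx[i + 1].timestamp - fx[i].timestamp).total_seconds() / 3600.0
        if not (0 < dt_h <= rate_dt_max_h):
            continue
        r = haversine_km(fx[i].lon, fx[i].lat, fx[i + 1].lon, fx[i + 1].lat) / dt_h
        mid_t = fx[i].timestamp + (fx[i + 1].timestamp - fx[i].timestamp) / 2
        if solar_elevation_deg((fx[i].lon + fx[i + 1].lon) / 2,
                               (fx[i].lat + fx[i + 1].lat) / 2, mid_t) > 0:
            day.append(r)
        else:
            night.append(r)
    if len(day) < 5 or len(night) < 5:
        raise ValueError("need at least 5 steps in each photoperiod")
    t, p = stats.ttest_ind(day, night, equal_var=False)
    return float(np.mean(day)), float(np.mean(night)), float(p)
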