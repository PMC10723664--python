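"""Labeling of fixes (photoperiod, season, habitat) and discovery of
distinct use areas.

A use area is a density-connected cluster of fixes classified by when and
where it is occupied: daytime clusters on seagrass are foraging (f, not
separable from on-meadow resting), off-seagrass clusters are day or night
resting areas (r), and clusters occupied almost exclusively in the cool
season at markedly greater depth are cool-weather refugia (c).  Photoperiod
comes from solar elevation at the fix position and time; season follows the
month rule (warm May-Nov, cool Dec-Apr); habitat membership is
point-in-polygon against the habitat map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import MultiPoint, Point

from .geo import LocalProjection, haversine_km
from .trackio import DiveHistogram, FixRecord, HabitatMap, TemperatureSeries

WARM_MONTHS = {5, 6, 7, 8, 9, 10, 11}   # May-Nov; Dec-Apr is the cool season
LOCAL_UTC_OFFSET_H = -4                  # Atlantic Standard Time


@dataclass
class LabeledFix:
    fix: FixRecord
    photoperiod: str          # day | night
    season: str               # warm | cool
    in_seagrass: bool
    bathymetric_depth: Optional[float]   # m, None when outside bathymetry

    @property
    def local_hour(self) -> int:
        return (self.fix.timestamp.hour + LOCAL_UTC_OFFSET_H) % 24


@dataclass
class UseArea:
    kind: str                 # foraging_f | rest_day_r | rest_night_r | cool_refuge_c
    polygon: object           # shapely polygon, projected meters
    size_km2: float
    mean_depth_m: Optional[float]
    mean_center: Tuple[float, float]     # (lon, lat)
    usage_timing: dict        # proportions by photoperiod and season
    member_indices: np.ndarray


@dataclass
class OccupancyHistogram:
    hours: List[int]          # even local hours (AST)
    proportions: List[Optional[float]]   # fraction of that hour's fixes in seagrass
    season: str
    bimodality: Optional[float]          # mean occ at {6,8,18,20} / mean at {10,12,14}


@dataclass
class CorrelationResult:
    variable_pair: Tuple[str, str]
    r: float
    n: int
    p_value: float


# ---------------------------------------------------------------------------
# Solar position (standard approximate algorithm; accuracy ~ minutes)
# ---------------------------------------------------------------------------

def solar_elevation_deg(lon: float, lat: float, when: datetime) -> float:
    """Elevation of the sun's center above the horizon, degrees."""
    t = when.astimezone(timezone.utc) if when.tzinfo else when.replace(tzinfo=timezone.utc)
    doy = t.timetuple().tm_yday
    frac_hour = t.hour + t.minute / 60.0 + t.second / 3600.0
    g = 2.0 * np.pi / 365.0 * (doy - 1 + (frac_hour - 12.0) / 24.0)
    eqtime = 229.18 * (0.000075 + 0.001868 * np.cos(g) - 0.032077 * np.sin(g)
                       - 0.014615 * np.cos(2 * g) - 0.040849 * np.sin(2 * g))
    decl = (0.006918 - 0.399912 * np.cos(g) + 0.070257 * np.sin(g)
            - 0.006758 * np.cos(2 * g) + 0.000907 * np.sin(2 * g)
            - 0.002697 * np.cos(3 * g) + 0.00148 * np.sin(3 * g))
    tst = frac_hour * 60.0 + eqtime + 4.0 * lon   # true solar time, minutes
    ha = np.radians(tst / 4.0 - 180.0)
    lat_r = np.radians(lat)
    cos_zen = (np.sin(lat_r) * np.sin(decl)
               + np.cos(lat_r) * np.cos(decl) * np.cos(ha))
    return float(90.0 - np.degrees(np.arccos(np.clip(cos_zen, -1.0, 1.0))))


def season_of(when: datetime) -> str:
    return "warm" if when.month in WARM_MONTHS else "cool"


# ---------------------------------------------------------------------------
# Labeling
# ---------------------------------------------------------------------------

def label_fixes(fixes: Sequence[FixRecord], habitat: Optional[HabitatMap] = None,
                bathymetry=None) -> List[LabeledFix]:
    """Attach photoperiod, season, seagrass membership and depth to fixes.

    ``bathymetry`` is any callable ``(lon, lat) -> depth_m or None``; fixes
    outside its extent get ``bathymetric_depth=None`` (flagged missing).
    """
    seagrass = habitat.union_of("seagrass") if habitat is not None else None
    out: List[LabeledFix] = []
    for f in fixes:
        elev = solar_elevation_deg(f.lon, f.lat, f.timestamp)
        in_sg = bool(seagrass is not None and seagrass.covers(Point(f.lon, f.lat)))
        depth = None
        if bathymetry is not None:
            depth = bathymetry(f.lon, f.lat)
        elif f.depth_at_fix is not None:
            depth = f.depth_at_fix
        out.append(LabeledFix(
            fix=f,
            photoperiod="day" if elev > 0.0 else "night",
            season=season_of(f.timestamp),
            in_seagrass=in_sg,
            bathymetric_depth=depth,
        ))
    return out


# ---------------------------------------------------------------------------
# Use-area discovery and classification
# ---------------------------------------------------------------------------

def find_use_areas(labeled: Sequence[LabeledFix], eps_m: float = 100.0,
                   min_count: int = 15,
                   cool_fraction: float = 0.8,
                   refuge_depth_ratio: float = 1.5,
                   projection: Optional[LocalProjection] = None) -> List[UseArea]:
    """Density-connected clustering of fixes into classified use areas.

    Clusters (DBSCAN, radius ``eps_m``, ``min_count`` neighbors, projected
    meters) become use areas whose polygon is the convex hull buffered by
    ``eps_m / 2``.  Classification: seagrass-majority & day-majority ->
    foraging_f; off-seagrass & day-majority -> rest_day_r; off-seagrass &
    night-majority -> rest_night_r.  A cluster with >= ``cool_fraction`` of
    fixes in the cool season whose mean depth is >= ``refuge_depth_ratio``
    times the animal's foraging-area depth overrides to cool_refuge_c.
    """
    from sklearn.cluster import DBSCAN

    if len(labeled) < min_count:
        warnings.warn("too few fixes for clustering; no use areas", stacklevel=2)
        return []
    lons = np.array([lf.fix.lon for lf in labeled])
    lats = np.array([lf.fix.lat for lf in labeled])
    if projection is None:
        projection = LocalProjection.for_points(lons, lats)
    x, y = projection.forward(lons, lats)
    xy = np.column_stack([x, y])
    labels = DBSCAN(eps=eps_m, min_samples=min_count).fit_predict(xy)
    if (labels >= 0).sum() == 0:
        warnings.warn("no density-connected clusters found", stacklevel=2)
        return []

    areas: List[UseArea] = []
    for cl in sorted(set(labels) - {-1}):
        idx = np.nonzero(labels == cl)[0]
        members = [labeled[i] for i in idx]
        day_frac = np.mean([m.photoperiod == "day" for m in members])
        sg_frac = np.mean([m.in_seagrass for m in members])
        cool_frac = np.mean([m.season == "cool" for m in members])
        depths = [m.bathymetric_depth for m in members if m.bathymetric_depth is not None]
        mean_depth = float(np.mean(depths)) if depths else None

        # on-meadow clusters are foraging/resting combined (f/r): the data
        # cannot separate on-meadow resting from foraging, so seagrass
        # membership dominates the photoperiod split
        if sg_frac > 0.5:
            kind = "foraging_f"
        elif day_frac > 0.5:
            kind = "rest_day_r"
        else:
            kind = "rest_night_r"

        hull = MultiPoint(xy[idx]).convex_hull.buffer(eps_m / 2.0)
        clon = float(np.mean(lons[idx]))
        clat = float(np.mean(lats[idx]))
        timing = {
            "day": float(day_frac), "night": float(1 - day_frac),
            "warm": float(1 - cool_frac), "cool": float(cool_frac),
        }
        areas.append(UseArea(kind=kind, polygon=hull,
                             size_km2=hull.area / 1e6,
                             mean_depth_m=mean_depth,
                             mean_center=(clon, clat),
                             usage_timing=timing,
                             member_indices=idx))

    # refuge override needs the foraging depth as a baseline; when no
    # on-meadow cluster was found, the shallowest cluster stands in
    f_depths = [a.mean_depth_m for a in areas
                if a.kind == "foraging_f" and a.mean_depth_m is not None]
    if not f_depths:
        f_depths = [a.mean_depth_m for a in areas if a.mean_depth_m is not None]
        f_depths = [min(f_depths)] if f_depths else []
    baseline = float(np.mean(f_depths)) if f_depths else None
    for a in areas:
        if (baseline is not None and a.mean_depth_m is not None
                and a.usage_timing["cool"] >= cool_fraction
                and a.mean_depth_m >= refuge_depth_ratio * baseline):
            a.kind = "cool_refuge_c"
    return areas


def area_center_distances(use_areas: Sequence[UseArea]) -> np.ndarray:
    """Pairwise great-circle distances (m) between use-area mean centers."""
    if len(use_areas) < 2:
        raise ValueError("need at least 2 use areas")
    n = len(use_areas)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            km = haversine_km(*use_areas[i].mean_center, *use_areas[j].mean_center)
            d[i, j] = d[j, i] = km * 1000.0
    return d


# ---------------------------------------------------------------------------
# Occupancy and dive summaries
# ---------------------------------------------------------------------------

def occupancy_histogram(labeled: Sequence[LabeledFix], season: str = "warm"
                        ) -> OccupancyHistogram:
    """Fraction of fixes in seagrass per even local hour (AST).

    The bimodality statistic is the ratio of mean occupancy during morning and
    evening foraging hours {06, 08, 18, 20} to mid-day hours {10, 12, 14}.
    """
    sub = [lf for lf in labeled if lf.season == season]
    hours = list(range(0, 24, 2))
    props: List[Optional[float]] = []
    for h in hours:
        bin_fixes = [lf for lf in sub if lf.local_hour == h]
        if not bin_fixes:
            props.append(None)
        else:
            props.append(float(np.mean([lf.in_seagrass for lf in bin_fixes])))
    def _mean_over(hs):
        vals = [p for h, p in zip(hours, props) if h in hs and p is not None]
        return float(np.mean(vals)) if vals else None
    peak = _mean_over({6, 8, 18, 20})
    trough = _mean_over({10, 12, 14})
    bim = None
    if peak is not None and trough is not None and trough > 0:
        bim = peak / trough
    return OccupancyHistogram(hours=hours, proportions=props, season=season,
                              bimodality=bim)


def weighted_mean_bins(hist: DiveHistogram) -> float:
    """Mean of a binned variable, weighted by time-in-bin proportions.

    Interior bins use their midpoint; the bottom bin uses half its upper
    edge (lower bound 0); the open top bin uses its lower edge plus half the
    width of the preceding bin.
    """
    edges = np.asarray(hist.bin_edges, dtype=float)
    p = np.asarray(hist.proportions, dtype=float)
    if edges.size >= 2 and np.any(np.diff(edges) == 0):
        raise ValueError("zero-width bin")
    mids = np.empty(edges.size + 1)
    mids[0] = edges[0] / 2.0
    mids[1:-1] = (edges[:-1] + edges[1:]) / 2.0
    last_width = edges[-1] - edges[-2] if edges.size >= 2 else edges[-1]
    mids[-1] = edges[-1] + last_width / 2.0
    return float(np.sum(mids * p))


def distance_temperature_correlation(labeled: Sequence[LabeledFix],
                                     ud25_center: Tuple[float, float],
                                     buoy: TemperatureSeries,
                                     max_match_h: float = 24.0
                                     ) -> CorrelationResult:
    """Pearson correlation of daily distance-from-core against water
    temperature.

    Each fix is matched to the buoy record nearest in time (within
    ``max_match_h``); pairs are averaged to one (distance, temperature) pair
    per calendar day before the correlation is computed.
    """
    if len(buoy) == 0:
        raise ValueError("empty temperature series")
    rows = []
    for lf in labeled:
        d_km = haversine_km(lf.fix.lon, lf.fix.lat, ud25_center[0], ud25_center[1])
        rows.append({"timestamp": pd.Timestamp(lf.fix.timestamp), "distance_km": d_km})
    fixes_df = pd.DataFrame(rows).sort_values("timestamp")
    buoy_df = buoy.to_frame().rename(columns={"temperature_c": "temp"}).sort_values("timestamp")
    merged = pd.merge_asof(fixes_df, buoy_df, on="timestamp",
                           direction="nearest",
                           tolerance=pd.Timedelta(hours=max_match_h)).dropna()
    if merged.empty:
        raise ValueError("no fix matched a buoy record within the tolerance")
    daily = merged.groupby(merged["timestamp"].dt.date).agg(
        distance_km=("distance_km", "mean"), temp=("temp", "mean"))
    if len(daily) < 3:
        raise ValueError("need at least 3 daily pairs for a correlation")
    if daily["temp"].std() == 0 or daily["distance_km"].std() == 0:
        raise ValueError("constant variable: correlation undefined")
    r, p = stats.pearsonr(daily["distance_km"], daily["temp"])
    return CorrelationResult(("distance_from_ud25_center", "water_temperature"),
                             float(r), int(len(daily)), float(p))


def seasonal_occupancy_shift(labeled: Sequence[LabeledFix]) -> pd.DataFrame:
    """Proportion of fixes off seagrass by photoperiod x season."""
    rows = []
    seasons_present = {lf.season for lf in labeled}
    if seasons_present != {"warm", "cool"}:
        warnings.warn("fixes do not span both seasons; partial table",
                      stacklevel=2)
    for season in ("warm", "cool"):
        for photoperiod in ("day", "night"):
            sub = [lf for lf in labeled
                   if lf.season == season and lf.photoperiod == photoperiod]
            rows.append({
                "season": season,
                "photoperiod": photoperiod,
                "n": len(sub),
                "off_seagrass": (float(np.mean([not lf.in_seagrass for lf in sub]))
                                 if sub else np.nan),
            })
    return pd.DataFrame(rows)
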