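"""Readers and writers for every external format the pipeline touches.

Fix tables, capture/set logs and binned histograms are delimited text with
named columns; buoy temperature series are NDBC-style whitespace-delimited
text; habitat polygons and spatial products are GeoJSON.  All timestamps are
stored UTC internally; a single fixed display offset (UTC-4, Atlantic
Standard Time) is applied only in diel computations elsewhere.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger(__name__)

#: Default mapping from semantic field -> column name in delimited fix tables.
DEFAULT_FIX_COLUMNS = {
    "tag_id": "tag_id",
    "timestamp": "timestamp",
    "lon": "lon",
    "lat": "lat",
    "n_satellites": "n_satellites",
    "residual": "residual",
    "source": "source",
    "depth_at_fix": "depth_at_fix",
    "current_u": "current_u",
    "current_v": "current_v",
}

MANDATORY_FIX_FIELDS = ("tag_id", "timestamp", "lon", "lat", "n_satellites", "residual")


class FormatError(ValueError):
    """A file does not conform to the expected schema."""


@dataclass
class FixRecord:
    """One satellite-derived position with quality metadata."""

    tag_id: str
    timestamp: datetime
    lon: float
    lat: float
    n_satellites: int
    residual: float
    source: str = "fastloc"
    depth_at_fix: Optional[float] = None
    current_u: Optional[float] = None
    current_v: Optional[float] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"lon out of range: {self.lon}")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"lat out of range: {self.lat}")
        if self.n_satellites < 0:
            raise ValueError("n_satellites must be >= 0")
        if self.residual < 0:
            raise ValueError("residual must be >= 0")
        if self.timestamp.tzinfo is None:
            self.timestamp = self.timestamp.replace(tzinfo=timezone.utc)


@dataclass
class DiveHistogram:
    """Proportion of time per depth/duration/temperature bin over one period.

    ``bin_edges`` are the interior edges; with n edges there are n + 1 bins:
    (-inf, e0], (e0, e1], ..., (e_{n-1}, inf) — the top bin is open.
    """

    tag_id: str
    period_start: datetime
    period_end: datetime
    variable: str  # depth_m | duration_min | temperature_C
    bin_edges: Sequence[float]
    proportions: Sequence[float]

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        if edges.size and np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        p = np.asarray(self.proportions, dtype=float)
        if p.size != edges.size + 1:
            raise ValueError("need one proportion per bin (open top bin included)")
        if np.any(p < -1e-12):
            raise ValueError("proportions must be nonnegative")
        if abs(float(p.sum()) - 1.0) > 1e-6:
            raise ValueError(f"proportions must sum to 1, got {p.sum()}")


@dataclass
class TemperatureSeries:
    """Water temperature record for one station."""

    station_id: str
    timestamps: pd.DatetimeIndex
    temperatures_c: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.temperatures_c, dtype=float)
        if len(self.timestamps) != t.size:
            raise ValueError("timestamps and temperatures differ in length")
        if t.size and (t.min() <= -5.0 or t.max() >= 45.0):
            raise ValueError("temperature outside plausible water range (-5, 45) C")
        if len(self.timestamps) and not self.timestamps.is_monotonic_increasing:
            raise ValueError("timestamps must be non-decreasing")
        self.temperatures_c = t

    def __len__(self) -> int:
        return len(self.timestamps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.timestamps, "temperature_c": self.temperatures_c})


@dataclass
class HabitatPolygon:
    geometry: BaseGeometry
    habitat_class: str  # seagrass | reef | channel | platform_boundary
    name: str = ""


@dataclass
class HabitatMap:
    polygons: list

    def __post_init__(self):
        for p in self.polygons:
            if not p.geometry.is_valid:
                raise ValueError(f"invalid habitat geometry: {p.name!r}")

    def by_class(self, habitat_class: str) -> list:
        return [p for p in self.polygons if p.habitat_class == habitat_class]

    def union_of(self, habitat_class: str):
        from shapely.ops import unary_union

        geoms = [p.geometry for p in self.by_class(habitat_class)]
        if not geoms:
            return None
        return unary_union(geoms)


@dataclass
class NetCaptureRecord:
    turtle_id: str
    date: datetime
    site: str
    lon: float
    lat: float
    scl_min_cm: float

    def __post_init__(self):
        if not (20.0 < self.scl_min_cm < 120.0):
            raise ValueError(f"scl_min_cm out of plausible range: {self.scl_min_cm}")


@dataclass
class NetSetRecord:
    date: datetime
    site: str
    lon: float
    lat: float


# ---------------------------------------------------------------------------
# Fix tables
# ---------------------------------------------------------------------------

def read_fix_table(path, columns: Optional[dict] = None, sep: str = ",") -> list:
    """Read a delimited fix table into sorted, de-duplicated :class:`FixRecord` s.

    ``columns`` maps semantic names (see :data:`DEFAULT_FIX_COLUMNS`) to the
    file's column names.  Records are sorted by (tag_id, timestamp); duplicate
    (tag_id, timestamp) rows collapse to the one with more satellites (ties
    keep the first).  Unparseable rows are logged and skipped.
    """
    colmap = dict(DEFAULT_FIX_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep=sep)
    for semantic in MANDATORY_FIX_FIELDS:
        if colmap[semantic] not in df.columns:
            raise FormatError(f"missing mandatory column {colmap[semantic]!r} (for {semantic})")
    known = {v: k for k, v in colmap.items() if v in df.columns}
    extra_cols = [c for c in df.columns if c not in known]

    records, skipped = [], 0
    for _, row in df.iterrows():
        try:
            ts = pd.Timestamp(row[colmap["timestamp"]])
            if ts.tzinfo is None:
                ts = ts.tz_localize("UTC")
            kwargs = dict(
                tag_id=str(row[colmap["tag_id"]]),
                timestamp=ts.to_pydatetime(),
                lon=float(row[colmap["lon"]]),
                lat=float(row[colmap["lat"]]),
                n_satellites=int(row[colmap["n_satellites"]]),
                residual=float(row[colmap["residual"]]),
            )
            for opt in ("source",):
                if colmap[opt] in df.columns and not pd.isna(row[colmap[opt]]):
                    kwargs[opt] = str(row[colmap[opt]])
            for opt in ("depth_at_fix", "current_u", "current_v"):
                if colmap[opt] in df.columns and not pd.isna(row[colmap[opt]]):
                    kwargs[opt] = float(row[colmap[opt]])
            kwargs["extra"] = {c: row[c] for c in extra_cols}
            records.append(FixRecord(**kwargs))
        except (ValueError, TypeError) as exc:
            skipped += 1
            logger.warning("skipping unparseable fix row: %s", exc)
    if skipped:
        logger.warning("read_fix_table: skipped %d unparseable rows", skipped)

    records.sort(key=lambda r: (r.tag_id, r.timestamp, -r.n_satellites))
    deduped, seen = [], set()
    for r in records:
        key = (r.tag_id, r.timestamp)
        if key in seen:
            continue
        seen.add(key)
        deduped.append(r)
    return deduped


def write_fix_table(fixes: Iterable[FixRecord], path, sep: str = ",") -> None:
    rows = []
    for f in fixes:
        row = {
            "tag_id": f.tag_id,
            "timestamp": f.timestamp.astimezone(timezone.utc).isoformat(),
            "lon": repr(f.lon),
            "lat": repr(f.lat),
            "n_satellites": f.n_satellites,
            "residual": f.residual,
            "source": f.source,
        }
        if f.depth_at_fix is not None:
            row["depth_at_fix"] = f.depth_at_fix
        if f.current_u is not None:
            row["current_u"] = f.current_u
        if f.current_v is not None:
            row["current_v"] = f.current_v
        row.update(f.extra)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def fixes_to_frame(fixes: Sequence[FixRecord]) -> pd.DataFrame:
    """Tabular view of fix records (timestamps as tz-aware pandas column)."""
    return pd.DataFrame(
        {
            "tag_id": [f.tag_id for f in fixes],
            "timestamp": pd.to_datetime([f.timestamp for f in fixes], utc=True),
            "lon": [f.lon for f in fixes],
            "lat": [f.lat for f in fixes],
            "n_satellites": [f.n_satellites for f in fixes],
            "residual": [f.residual for f in fixes],
        }
    )


# ---------------------------------------------------------------------------
# Buoy temperature series (NDBC-style text)
# ---------------------------------------------------------------------------

def read_buoy_series(path, station_id: str = "", missing_sentinel: float = 999.0) -> TemperatureSeries:
    """Read an NDBC-style whitespace-delimited water temperature file.

    Expects columns ``YY MM DD hh mm ... WTMP`` (header lines starting with
    ``#`` allowed; a units line is skipped automatically).  Values >=
    ``missing_sentinel`` are treated as missing and dropped.
    """
    df = pd.read_csv(path, sep=r"\s+", comment=None, header=0, dtype=str)
    # NDBC files begin the header with '#YY'; a second '#...' row carries
    # units.  Column case matters: 'MM' is month, 'mm' is minute.
    df.columns = [c.lstrip("#") for c in df.columns]
    df = df[~df.iloc[:, 0].astype(str).str.startswith("#")]
    year = next((c for c in ("YY", "YYYY") if c in df.columns), None)
    if year is None or "MM" not in df.columns or "DD" not in df.columns:
        raise FormatError("buoy file lacks year/month/day columns")
    if "WTMP" not in df.columns:
        raise FormatError("buoy file lacks WTMP column")

    years = df[year].astype(int)
    years = years.where(years > 100, years + 2000)
    ts = pd.to_datetime(
        {
            "year": years,
            "month": df["MM"].astype(int),
            "day": df["DD"].astype(int),
            "hour": df["hh"].astype(int) if "hh" in df.columns else 0,
            "minute": df["mm"].astype(int) if "mm" in df.columns else 0,
        },
        utc=True,
    )
    temp = pd.to_numeric(df["WTMP"], errors="coerce")
    keep = temp.notna() & (temp < missing_sentinel)
    if not keep.any():
        warnings.warn("buoy series: all values missing", stacklevel=2)
        return TemperatureSeries(station_id, pd.DatetimeIndex([], tz="UTC"), np.array([]))
    out = pd.DataFrame({"ts": ts[keep], "t": temp[keep]}).sort_values("ts")
    return TemperatureSeries(station_id, pd.DatetimeIndex(out["ts"]), out["t"].to_numpy())


def monthly_summary(series: TemperatureSeries) -> pd.DataFrame:
    """Per-calendar-month (mean, sd, n) pooled across years.

    Returns a frame indexed by month number 1-12 (months present only).
    """
    if len(series) == 0:
        raise ValueError("empty temperature series")
    df = series.to_frame()
    g = df.groupby(df["timestamp"].dt.month)["temperature_c"]
    out = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1), "n": g.size()})
    out.index.name = "month"
    return out


# ---------------------------------------------------------------------------
# GeoJSON
# ---------------------------------------------------------------------------

def write_geojson(features, path) -> None:
    """Write (geometry, properties) pairs as a GeoJSON FeatureCollection.

    ``features`` is an iterable of (shapely geometry, dict) pairs in WGS84.
    Invalid geometries raise before anything is written.
    """
    feats = []
    for geom, props in features:
        if not geom.is_valid:
            raise ValueError("invalid geometry; refusing to write")
        feats.append({"type": "Feature", "geometry": mapping(geom), "properties": dict(props)})
    payload = {"type": "FeatureCollection", "features": feats}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_geojson(path) -> list:
    """Read a GeoJSON FeatureCollection as (shapely geometry, properties) pairs."""
    payload = json.loads(Path(path).read_text())
    if payload.get("type") != "FeatureCollection":
        raise FormatError("expected a GeoJSON FeatureCollection")
    return [(shape(f["geometry"]), f.get("properties") or {}) for f in payload["features"]]


def read_habitat_map(path) -> HabitatMap:
    """Read habitat polygons from GeoJSON with a ``class`` property."""
    polys = []
    for geom, props in read_geojson(path):
        polys.append(HabitatPolygon(geom, props.get("class", "unknown"), props.get("name", "")))
    return HabitatMap(polys)


# ---------------------------------------------------------------------------
# Capture / set logs
# ---------------------------------------------------------------------------

def read_capture_log(path, sep: str = ",") -> list:
    df = pd.read_csv(path, sep=sep)
    out = []
    for _, r in df.iterrows():
        out.append(
            NetCaptureRecord(
                turtle_id=str(r["turtle_id"]),
                date=pd.Timestamp(r["date"]).to_pydatetime(),
                site=str(r["site"]),
                lon=float(r["lon"]),
                lat=float(r["lat"]),
                scl_min_cm=float(r["scl_min_cm"]),
            )
        )
    return out


def read_set_log(path, sep: str = ",") -> list:
    df = pd.read_csv(path, sep=sep)
    return [
        NetSetRecord(
            date=pd.Timestamp(r["date"]).to_pydatetime(),
            site=str(r["site"]),
            lon=float(r["lon"]),
            lat=float(r["lat"]),
        )
        for _, r in df.iterrows()
    ]
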