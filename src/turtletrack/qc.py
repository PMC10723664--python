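"""Plausibility screening of Fastloc-GPS fixes.

Four screens are applied, mirroring standard practice for snapshot-GPS
marine telemetry: (1) a solution-quality rule that discards fixes with few
satellites or a large solution residual, (2) an iterative data-driven speed
filter, (3) exclusion of the first 24 h after release (handling/transmitter
effects), and (4) splitting on transmission gaps longer than 3 days.

The solution-quality rule defaults to the disjunctive reading (either failing
clause removes the fix): retaining 5-satellite fixes would contradict the
<100 m accuracy such screening is meant to deliver.  Set ``QCConfig.rule`` to
``"and"`` for the conjunctive variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import timedelta
from typing import List, Sequence, Tuple

import numpy as np

from .geo import haversine_km
from .trackio import FixRecord


@dataclass
class QCConfig:
    min_satellites: int = 6
    max_residual: float = 30.0
    vmax_kmh: float = 10.0
    exclude_initial_h: float = 24.0
    max_gap_days: float = 3.0
    dup_tolerance_s: float = 0.0
    rule: str = "or"  # "or": either clause removes; "and": both must fail

    def __post_init__(self):
        if self.min_satellites <= 0 or self.max_residual <= 0 or self.vmax_kmh <= 0:
            raise ValueError("QC thresholds must be positive")
        if self.rule not in ("or", "and"):
            raise ValueError("rule must be 'or' or 'and'")


@dataclass
class QCReport:
    n_input: int = 0
    n_retained: int = 0
    removed_quality: int = 0
    removed_speed: int = 0
    removed_initial: int = 0
    removed_duplicate: int = 0
    per_tag: dict = field(default_factory=dict)

    def check(self) -> None:
        removed = (self.removed_quality + self.removed_speed +
                   self.removed_initial + self.removed_duplicate)
        if self.n_input != self.n_retained + removed:
            raise AssertionError("QC report does not account for every fix")

    def summary(self) -> str:
        self.check()
        lines = [
            f"input fixes:          {self.n_input}",
            f"removed (quality):    {self.removed_quality}",
            f"removed (speed):      {self.removed_speed}",
            f"removed (initial 24h):{self.removed_initial}",
            f"removed (duplicate):  {self.removed_duplicate}",
            f"retained:             {self.n_retained}",
        ]
        return "\n".join(lines)


def flag_implausible(fixes: Sequence[FixRecord], qc: QCConfig = QCConfig()
                     ) -> Tuple[List[FixRecord], QCReport]:
    """Apply the satellite-count / residual quality rule.

    A fix fails clause 1 when ``n_satellites < min_satellites`` (strictly
    fewer) and clause 2 when ``residual > max_residual`` (strictly exceeds);
    boundary values are retained.
    """
    report = QCReport(n_input=len(fixes))
    retained = []
    for f in fixes:
        bad_sat = f.n_satellites < qc.min_satellites
        bad_res = f.residual > qc.max_residual
        bad = (bad_sat or bad_res) if qc.rule == "or" else (bad_sat and bad_res)
        if bad:
            report.removed_quality += 1
            report.per_tag.setdefault(f.tag_id, {"quality": 0, "speed": 0})
            report.per_tag[f.tag_id]["quality"] += 1
        else:
            retained.append(f)
    report.n_retained = len(retained)
    report.check()
    return retained, report


def _speeds_kmh(fixes: Sequence[FixRecord]) -> np.ndarray:
    """Required speed (km/h) between consecutive fixes; length n-1."""
    lons = np.array([f.lon for f in fixes])
    lats = np.array([f.lat for f in fixes])
    d = haversine_km(lons[:-1], lats[:-1], lons[1:], lats[1:])
    dt_h = np.array(
        [(b.timestamp - a.timestamp).total_seconds() / 3600.0
         for a, b in zip(fixes[:-1], fixes[1:])]
    )
    dt_h = np.where(dt_h <= 0, np.nan, dt_h)
    return np.atleast_1d(d) / dt_h


def speed_filter(fixes: Sequence[FixRecord], vmax_kmh: float = 10.0) -> List[FixRecord]:
    """Iterative great-circle speed filter (per tag).

    An interior fix is removed when both its inbound and outbound required
    speeds exceed ``vmax_kmh``; the pass repeats until stable.  Endpoints are
    removed only when their single adjacent speed exceeds ``3 * vmax_kmh``.
    """
    by_tag: dict = {}
    for f in fixes:
        by_tag.setdefault(f.tag_id, []).append(f)
    out: List[FixRecord] = []
    for tag, seq in by_tag.items():
        seq = sorted(seq, key=lambda f: f.timestamp)
        if len(seq) < 3:
            warnings.warn(f"speed_filter: tag {tag} has <3 fixes; returned unchanged",
                          stacklevel=2)
            out.extend(seq)
            continue
        changed = True
        while changed and len(seq) >= 2:
            changed = False
            v = _speeds_kmh(seq)
            keep = np.ones(len(seq), dtype=bool)
            for i in range(1, len(seq) - 1):
                vin, vout = v[i - 1], v[i]
                if np.isfinite(vin) and np.isfinite(vout) and vin > vmax_kmh and vout > vmax_kmh:
                    keep[i] = False
            if keep.all():
                # endpoint pass only once interior fixes are stable
                if np.isfinite(v[0]) and v[0] > 3 * vmax_kmh:
                    keep[0] = False
                if np.isfinite(v[-1]) and v[-1] > 3 * vmax_kmh:
                    keep[-1] = False
            if not keep.all():
                seq = [f for f, k in zip(seq, keep) if k]
                changed = True
        out.extend(seq)
    out.sort(key=lambda f: (f.tag_id, f.timestamp))
    return out


def exclude_initial_window(fixes: Sequence[FixRecord], deployment_time,
                           hours: float = 24.0) -> List[FixRecord]:
    """Drop fixes within ``hours`` of ``deployment_time`` (release effects)."""
    cutoff = deployment_time + timedelta(hours=hours)
    kept = [f for f in fixes if f.timestamp >= cutoff]
    if fixes and not kept:
        warnings.warn("exclude_initial_window: all fixes fall inside the window",
                      stacklevel=2)
    return kept


def split_on_gaps(fixes: Sequence[FixRecord], max_gap_days: float = 3.0
                  ) -> List[List[FixRecord]]:
    """Split a sorted fix sequence into contiguous bursts at gaps > max_gap_days."""
    if not fixes:
        return []
    bursts: List[List[FixRecord]] = [[fixes[0]]]
    for prev, cur in zip(fixes[:-1], fixes[1:]):
        gap_days = (cur.timestamp - prev.timestamp).total_seconds() / 86400.0
        if gap_days > max_gap_days:
            bursts.append([cur])
        else:
            bursts[-1].append(cur)
    return bursts
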