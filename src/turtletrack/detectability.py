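"""Net-capture detectability of resident animals.

Detectability is estimated per animal as the number of entrapment-net
captures divided by the number of net sets made within its presumed foraging
area during its residency period.  The study-level summary restricts to
animals with at least one year of residency that stayed at a single sampling
site, so the set count is attributable to one location.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import List, Optional, Sequence, Tuple

import numpy as np


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (report display convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ResidencyRecord:
    turtle_id: str
    first_capture: object           # date
    last_observation: object        # date
    residency_months: float
    single_site: bool
    n_sets: Optional[int]
    n_captures: Optional[int]

    def __post_init__(self):
        if self.n_captures is not None and self.n_captures < 0:
            raise ValueError("n_captures must be >= 0")


@dataclass
class DetectabilityEstimate:
    turtle_id: str
    rate_percent: float             # full precision; round for display
    eligible: bool

    @property
    def rate_percent_display(self) -> float:
        return round_half_up(self.rate_percent, 1)


def detection_rate(record: ResidencyRecord,
                   min_residency_months: float = 12.0) -> Optional[DetectabilityEstimate]:
    """Per-animal detection rate (percent) with eligibility flags.

    Returns ``None`` when no set count is available (rate undefined).
    Eligible animals have residency of at least ``min_residency_months``
    months and a single sampling site.
    """
    if record.n_sets is None or record.n_captures is None:
        return None
    if record.n_sets < 1:
        return None
    rate = 100.0 * record.n_captures / record.n_sets
    eligible = (record.residency_months >= min_residency_months
                and record.single_site)
    return DetectabilityEstimate(record.turtle_id, rate, eligible)


def detectability_summary(estimates: Sequence[DetectabilityEstimate]
                          ) -> Tuple[float, float, int]:
    """(mean, sample SD, n) of eligible detection rates, percent.

    Computed from full-precision rates, not display-rounded ones.
    """
    rates = [e.rate_percent for e in estimates if e is not None and e.eligible]
    if len(rates) < 2:
        raise ValueError("need at least 2 eligible estimates")
    arr = np.asarray(rates, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)


def count_sets_in_area(sets, foraging_polygon, buffer_m: float = 100.0,
                       projection=None) -> int:
    """Number of net sets falling inside a foraging area polygon buffered by
    the net enclosure radius (geometric assignment)."""
    from shapely.geometry import Point

    if projection is not None:
        poly = foraging_polygon
        n = 0
        for s in sets:
            x, y = projection.forward(s.lon, s.lat)
            if poly.buffer(buffer_m).covers(Point(float(x), float(y))):
                n += 1
        return n
    # lon/lat polygon: buffer in degrees approximated at this latitude
    deg = buffer_m / 111_195.0
    poly = foraging_polygon.buffer(deg)
    return sum(poly.covers(Point(s.lon, s.lat)) for s in sets)
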