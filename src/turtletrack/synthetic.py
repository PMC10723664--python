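"""Ground-truthed synthetic tracks of a central-place forager.

The generator emulates a benthic-stage green turtle resident on a shallow
platform: daily transits between a seagrass foraging site and day/night
resting sites (a biased random walk toward the hour's active center),
temperature-driven excursions to a deeper cool-weather refuge when simulated
water temperature drops below a threshold, optional pre-departure forays, and
a directed open-ocean migration after a departure date.  Observation follows
the tag duty cycle: candidate Fastloc-GPS fixes every 2 h on even hours GMT,
satellite-count-dependent position error, and a synthetic residual-error
model constructed so that quality screening has known true/false positives.

Default parameter values are the study conditions of the system being
emulated: local time is UTC-4 (Atlantic Standard Time, no daylight saving),
seasonal water temperature is a sinusoid with mean 23.9 degC and amplitude
7.75 (observed seasonal range ~15.7-31.2 degC, maximum in mid-August), the
cool threshold is 20 degC, resting centers sit several hundred meters from
the foraging site and the refuge ~3 km away, and migration proceeds
southwestward at ~2.3 km/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .geo import LocalProjection
from .trackio import DiveHistogram, FixRecord

LOCAL_UTC_OFFSET_H = -4          # Atlantic Standard Time, fixed
STEP_MINUTES = 30                # movement-model time step
ROLES = ("foraging", "day_rest", "night_rest", "refuge", "release")


def default_diel_schedule() -> Dict[int, str]:
    """Foraging 06-09 and 17-20 local, day rest 10-16, night rest otherwise."""
    sched = {}
    for h in range(24):
        if 6 <= h <= 9 or 17 <= h <= 20:
            sched[h] = "foraging"
        elif 10 <= h <= 16:
            sched[h] = "day_rest"
        else:
            sched[h] = "night_rest"
    return sched


def default_centers() -> Dict[int, str]:
    """Centers on a Bermuda-like platform; resting sites a few hundred meters
    from the foraging meadow, the refuge ~3 km away in deeper water."""
    return {
        "foraging": (-64.800, 32.300),
        "day_rest": (-64.7915, 32.300),     # ~800 m east
        "night_rest": (-64.800, 32.3063),   # ~700 m north
        "refuge": (-64.800, 32.273),        # ~3 km south
        "release": (-64.800, 32.300),
    }


@dataclass
class SimConfig:
    centers: Dict[str, Tuple[float, float]] = field(default_factory=default_centers)
    attraction: Dict[str, float] = field(
        default_factory=lambda: {r: 1.5 for r in ROLES})   # 1/h pull toward center
    step_sd: float = 30.0                 # m per 30-min step
    diel_schedule: Dict[int, str] = field(default_factory=default_diel_schedule)
    temp_mean: float = 23.9               # degC
    temp_amplitude: float = 7.75          # degC
    temp_phase_doy: int = 227             # day of year of the seasonal maximum
    temp_ar_sd: float = 0.0               # AR(1) noise sd, degC
    temp_ar_phi: float = 0.95
    refuge_threshold: float = 20.0        # degC
    migration_start: Optional[datetime] = None
    migration_bearing: float = 232.5      # degrees true (southwest)
    migration_speed: float = 2.3          # km/h
    persistence: float = 10.0             # von Mises concentration of step headings
    fix_interval: float = 2.0             # h, even hours GMT
    retention_prob: float = 0.85
    error_sd_good: float = 15.0           # m
    error_sd_bad: float = 75.0            # m
    p_good_fix: float = 0.9               # P(satellite count >= 6)
    outlier_prob: float = 0.02
    outlier_km: float = 10.0
    depth_by_role: Dict[str, float] = field(
        default_factory=lambda: {"foraging": 3.0, "day_rest": 8.0,
                                 "night_rest": 8.0, "refuge": 10.4,
                                 "release": 3.0, "migration": 5.0})
    seed: int = 0
    tag_id: str = "sim-000"

    def __post_init__(self):
        for name in ("retention_prob", "p_good_fix", "outlier_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.step_sd < 0 or self.error_sd_good < 0 or self.error_sd_bad < 0:
            raise ValueError("step_sd and error sds must be >= 0")
        if set(self.diel_schedule.keys()) != set(range(24)):
            raise ValueError("diel_schedule must cover all 24 hours")
        for h, role in self.diel_schedule.items():
            if role not in self.centers:
                raise ValueError(f"schedule hour {h} references unknown role {role!r}")


@dataclass
class SimTrack:
    """A simulated track: true positions, truth labels, and observations."""

    config: SimConfig
    times: List[datetime]          # strictly increasing, STEP_MINUTES apart
    lonlat: np.ndarray             # (n, 2) true positions
    xy: np.ndarray                 # (n, 2) projected meters
    states: List[str]              # active role per step (truth)
    temperatures: np.ndarray       # simulated water temperature per step
    projection: LocalProjection
    truth: dict                    # breakpoints, departure_time, refuge_days

    def __len__(self) -> int:
        return len(self.times)


def water_temperature(config: SimConfig, when: datetime) -> float:
    """Seasonal sinusoid of day-of-year (no noise term)."""
    doy = when.timetuple().tm_yday
    return config.temp_mean + config.temp_amplitude * np.cos(
        2.0 * np.pi * (doy - config.temp_phase_doy) / 365.25)


def _local_hour(when: datetime) -> int:
    return (when.hour + LOCAL_UTC_OFFSET_H) % 24


def simulate_track(config: SimConfig, n_days: int,
                   start: Optional[datetime] = None) -> SimTrack:
    """Simulate ``n_days`` of movement at 30-min steps.

    Each step pulls the animal toward the active center — the diel schedule's
    role for the local hour, overridden to the refuge while simulated water
    temperature is below ``refuge_threshold``, overridden to directed
    migration after ``migration_start`` — plus isotropic Gaussian noise.
    Identical configs (including seed) give identical output.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if start is None:
        start = datetime(2016, 8, 15, 0, 0, tzinfo=timezone.utc)
    if start.tzinfo is None:
        start = start.replace(tzinfo=timezone.utc)
    if config.migration_start is not None:
        mig = config.migration_start
        if mig.tzinfo is None:
            mig = mig.replace(tzinfo=timezone.utc)
        if mig < start:
            raise ValueError("migration_start precedes the track start")
    else:
        mig = None

    rng = np.random.default_rng([max(config.seed, 0), 11])
    proj = LocalProjection(*config.centers["release"])
    centers_xy = {r: np.array(proj.forward(*c)).ravel()
                  for r, c in config.centers.items()}

    dt_h = STEP_MINUTES / 60.0
    n_steps = int(n_days * 24 / dt_h)
    times = [start + timedelta(minutes=STEP_MINUTES * i) for i in range(n_steps + 1)]

    # AR(1) temperature noise (optional)
    noise = np.zeros(n_steps + 1)
    if config.temp_ar_sd > 0:
        eps = rng.normal(0.0, config.temp_ar_sd, n_steps + 1)
        for i in range(1, n_steps + 1):
            noise[i] = config.temp_ar_phi * noise[i - 1] + eps[i]
    temps = np.array([water_temperature(config, t) for t in times]) + noise

    pos = centers_xy["release"].astype(float).copy()
    xs = np.empty((n_steps + 1, 2))
    states: List[str] = []
    xs[0] = pos
    mig_rad = np.radians(config.migration_bearing)
    step_noise = rng.normal(0.0, config.step_sd if config.step_sd > 0 else 0.0,
                            size=(n_steps + 1, 2)) if config.step_sd > 0 else np.zeros((n_steps + 1, 2))
    headings = (rng.vonmises(0.0, config.persistence, n_steps + 1)
                if config.persistence > 0 else np.zeros(n_steps + 1))

    departure_time = None
    breakpoints: List[datetime] = []
    prev_regime = None
    refuge_days = set()
    for i in range(n_steps + 1):
        t = times[i]
        if mig is not None and t >= mig:
            role = "migration"
        elif temps[i] < config.refuge_threshold:
            role = "refuge"
        else:
            role = config.diel_schedule[_local_hour(t)]
        states.append(role)
        regime = "migration" if role == "migration" else ("refuge" if role == "refuge" else "resident")
        if prev_regime is not None and regime != prev_regime:
            breakpoints.append(t)
            if regime == "migration" and departure_time is None:
                departure_time = t
        prev_regime = regime
        if role == "refuge":
            refuge_days.add(t.date())
        if i == n_steps:
            break
        if role == "migration":
            theta = mig_rad + headings[i]
            step_m = config.migration_speed * 1000.0 * dt_h
            pos = pos + step_m * np.array([np.sin(theta), np.cos(theta)])
        else:
            pull = min(config.attraction.get(role, 1.5) * dt_h, 1.0)
            pos = pos + pull * (centers_xy[role] - pos) + step_noise[i]
        xs[i + 1] = pos

    lon, lat = proj.inverse(xs[:, 0], xs[:, 1])
    return SimTrack(
        config=config,
        times=times,
        lonlat=np.column_stack([lon, lat]),
        xy=xs,
        states=states,
        temperatures=temps,
        projection=proj,
        truth={
            "breakpoints": breakpoints,
            "departure_time": departure_time,
            "refuge_days": sorted(refuge_days),
        },
    )


def observe_fixes(track: SimTrack, config: Optional[SimConfig] = None) -> List[FixRecord]:
    """Sample noisy Fastloc-GPS fixes from the true track.

    One candidate fix per scheduled even-hour (GMT) epoch, retained with
    ``retention_prob``.  Retained fixes get Gaussian position error with sd
    ``error_sd_good`` when the drawn satellite count is >= 6 (probability
    ``p_good_fix``), else ``error_sd_bad``; with ``outlier_prob`` the fix is
    additionally displaced by ``outlier_km``.  The residual value is drawn so
    that fixes with < 6 satellites or planted outliers receive residuals > 30
    with probability 0.95, while clean fixes stay below 30.  Each record's
    ``extra`` dict carries the truth flags ``planted_outlier`` and
    ``low_quality``.
    """
    if config is None:
        config = track.config
    rng = np.random.default_rng([max(config.seed, 0), 23])
    interval = timedelta(hours=config.fix_interval)
    step = timedelta(minutes=STEP_MINUTES)

    t0 = track.times[0]
    first = t0.replace(minute=0, second=0, microsecond=0)
    while first.hour % 2 != 0 or first < t0:
        first += timedelta(hours=1)
    index_of = {t: i for i, t in enumerate(track.times)}

    fixes: List[FixRecord] = []
    t = first
    while t <= track.times[-1]:
        i = index_of.get(t)
        if i is None:  # epoch not aligned to the step grid (should not happen)
            t += interval
            continue
        draws = rng.random(3)  # retention, quality, outlier — fixed per epoch
        if draws[0] <= config.retention_prob:
            good = draws[1] <= config.p_good_fix
            is_outlier = draws[2] <= config.outlier_prob
            nsat = int(rng.integers(6, 11)) if good else int(rng.integers(3, 6))
            sd = config.error_sd_good if good else config.error_sd_bad
            err = rng.normal(0.0, sd, 2) if sd > 0 else np.zeros(2)
            xy = track.xy[i] + err
            if is_outlier:
                theta = rng.uniform(0.0, 2.0 * np.pi)
                xy = xy + config.outlier_km * 1000.0 * np.array(
                    [np.sin(theta), np.cos(theta)])
            if (not good) or is_outlier:
                residual = float(rng.uniform(30.5, 120.0)) if rng.random() < 0.95 \
                    else float(rng.uniform(0.0, 30.0))
            else:
                residual = float(rng.uniform(0.0, 15.0))
            lon, lat = track.projection.inverse(xy[0], xy[1])
            fixes.append(FixRecord(
                tag_id=config.tag_id,
                timestamp=t,
                lon=float(lon), lat=float(lat),
                n_satellites=nsat,
                residual=residual,
                source="fastloc",
                extra={"planted_outlier": bool(is_outlier),
                       "low_quality": bool(not good),
                       "true_state": track.states[i]},
            ))
        t += interval
    return fixes


def make_dive_histograms(track: SimTrack, bin_edges: Sequence[float],
                         period_h: float = 24.0,
                         depth_noise_sd: float = 0.0,
                         variable: str = "depth_m") -> List[DiveHistogram]:
    """Time-at-depth histograms per period from the truth states.

    Depth at each step is the configured per-role depth (plus optional
    Gaussian noise, truncated at 0).  Bins follow the tag convention: with n
    edges there are n+1 bins, the last open-ended.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size == 0 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing and non-empty")
    rng = np.random.default_rng([max(track.config.seed, 0), 37])
    depth = np.array([track.config.depth_by_role.get(s, 3.0) for s in track.states])
    if depth_noise_sd > 0:
        depth = np.maximum(depth + rng.normal(0.0, depth_noise_sd, depth.size), 0.0)

    period = timedelta(hours=period_h)
    t0 = track.times[0]
    out: List[DiveHistogram] = []
    start = t0
    while start < track.times[-1]:
        end = start + period
        idx = [i for i, t in enumerate(track.times) if start <= t < end]
        if idx:
            sub = depth[idx]
            which = np.searchsorted(edges, sub, side="left")
            counts = np.bincount(which, minlength=edges.size + 1).astype(float)
            out.append(DiveHistogram(
                tag_id=track.config.tag_id,
                period_start=start, period_end=end,
                variable=variable,
                bin_edges=edges.tolist(),
                proportions=(counts / counts.sum()).tolist(),
            ))
        start = end
    return out


def write_truth_labels(track: SimTrack, path) -> None:
    """Sidecar delimited file of per-step truth labels."""
    import pandas as pd

    pd.DataFrame({
        "timestamp": [t.isoformat() for t in track.times],
        "lon": track.lonlat[:, 0],
        "lat": track.lonlat[:, 1],
        "state": track.states,
        "temperature_c": track.temperatures,
    }).to_csv(path, index=False)
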