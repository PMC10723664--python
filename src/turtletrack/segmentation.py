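"""Track re-discretization and segmentation into stationary phases.

Tracks are resampled to a regular 12-h series by linear interpolation along
the chord between bracketing fixes, then segmented by exact dynamic
programming under a per-segment Gaussian model (independent x and y, each
with its own mean and variance per segment).  The number of segments is
chosen by Lavielle's adaptive penalty on the normalized contrast curve.
Distinctness of two phases is judged by the Bhattacharyya coefficient of
their 95%-masked utilization distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import timedelta
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .geo import LocalProjection
from .trackio import FixRecord

#: absolute variance floor (m^2) guarding the Gaussian contrast against the
#: unbounded-likelihood degeneracy of zero-variance segments; a relative floor
#: (1e-6 of the series variance) is applied on top, so the guard never
#: distorts the contrast at data scale.
VAR_FLOOR = 1e-12


def _var_floor(xy: np.ndarray) -> float:
    total = float(np.asarray(xy, dtype=float).var(axis=0).mean())
    return max(VAR_FLOOR, 1e-6 * total)


@dataclass
class RegularizedTrack:
    """A 12-h re-discretized path in local projected coordinates."""

    tag_id: str
    epochs: list                 # UTC datetimes, fixed spacing within a burst
    xy: np.ndarray               # (n, 2) meters
    interpolated: np.ndarray     # bool per epoch (no fix within 1 h)
    burst_id: np.ndarray         # int per epoch
    projection: LocalProjection

    def __len__(self) -> int:
        return len(self.epochs)


@dataclass
class PhaseModel:
    breakpoints: List[int]       # segment start indices, excluding 0
    k: int
    segment_means: np.ndarray    # (k, 2)
    segment_vars: np.ndarray     # (k, 2)
    contrast_by_k: dict          # K -> minimized contrast J(K)
    lmin: int
    note: str = ""

    def segments(self, n: int) -> List[Tuple[int, int]]:
        """Half-open [start, end) index ranges covering 0..n."""
        bounds = [0] + list(self.breakpoints) + [n]
        return list(zip(bounds[:-1], bounds[1:]))


@dataclass
class PhasePair:
    phase_a: int
    phase_b: int
    bc: float
    distinct: bool


# ---------------------------------------------------------------------------
# Re-discretization
# ---------------------------------------------------------------------------

def rediscretize(fixes: Sequence[FixRecord], dt_h: float = 12.0,
                 max_gap_days: float = 3.0,
                 projection: Optional[LocalProjection] = None) -> RegularizedTrack:
    """Resample fixes to a fixed ``dt_h`` series by chord interpolation.

    Epochs start at the first fix and advance by ``dt_h``; an epoch falling
    inside a positional gap longer than ``max_gap_days`` is not emitted.  The
    ``interpolated`` flag marks epochs with no observed fix within 1 h.
    """
    fixes = sorted(fixes, key=lambda f: f.timestamp)
    if len(fixes) < 2:
        raise ValueError("need at least 2 fixes to re-discretize")
    lons = np.array([f.lon for f in fixes])
    lats = np.array([f.lat for f in fixes])
    if projection is None:
        projection = LocalProjection.for_points(lons, lats)
    x, y = projection.forward(lons, lats)
    t = np.array([f.timestamp.timestamp() for f in fixes])

    t0, t_end = t[0], t[-1]
    n_epochs = int(np.floor((t_end - t0) / (dt_h * 3600.0))) + 1
    epoch_ts = t0 + np.arange(n_epochs) * dt_h * 3600.0

    idx = np.searchsorted(t, epoch_ts, side="right") - 1
    idx = np.clip(idx, 0, len(t) - 2)
    left_t, right_t = t[idx], t[idx + 1]
    # bracketing fixes; epochs exactly on a fix use it verbatim
    on_fix = np.isin(epoch_ts, t)
    gap_days = (right_t - left_t) / 86400.0
    in_gap = (gap_days > max_gap_days) & ~on_fix

    frac = np.where(right_t > left_t, (epoch_ts - left_t) / np.where(right_t > left_t, right_t - left_t, 1.0), 0.0)
    ex = x[idx] + frac * (x[idx + 1] - x[idx])
    ey = y[idx] + frac * (y[idx + 1] - y[idx])
    exact = np.isin(epoch_ts, t)
    ex = np.where(exact, x[np.searchsorted(t, epoch_ts).clip(0, len(t) - 1)], ex)
    ey = np.where(exact, y[np.searchsorted(t, epoch_ts).clip(0, len(t) - 1)], ey)

    near = np.array([np.min(np.abs(t - et)) <= 3600.0 for et in epoch_ts])

    keep = ~in_gap
    epoch_ts, ex, ey, near = epoch_ts[keep], ex[keep], ey[keep], near[keep]
    # burst ids: increment wherever consecutive emitted epochs are no longer dt apart
    burst = np.zeros(len(epoch_ts), dtype=int)
    if len(epoch_ts) > 1:
        burst[1:] = np.cumsum(np.diff(epoch_ts) > dt_h * 3600.0 + 1.0)

    from datetime import datetime, timezone

    epochs = [datetime.fromtimestamp(ts, tz=timezone.utc) for ts in epoch_ts]
    return RegularizedTrack(
        tag_id=fixes[0].tag_id,
        epochs=epochs,
        xy=np.column_stack([ex, ey]),
        interpolated=~near,
        burst_id=burst,
        projection=projection,
    )


# ---------------------------------------------------------------------------
# Dynamic-programming segmentation (Gaussian contrast, Lavielle penalty)
# ---------------------------------------------------------------------------

def _segment_cost_table(xy: np.ndarray, lmin: int) -> np.ndarray:
    """cost[i, j] = negative Gaussian log-likelihood (up to constants) of
    segment [i, j) under per-coordinate MLE mean and variance.

    Uses the contrast  sum_coords  m * log(sigma2_hat)  (the m*(1+log 2 pi)
    term is common to all segmentations of fixed n and drops out).
    """
    n = len(xy)
    floor = _var_floor(xy)
    s1 = np.vstack([np.zeros(2), np.cumsum(xy, axis=0)])          # (n+1, 2)
    s2 = np.vstack([np.zeros(2), np.cumsum(xy ** 2, axis=0)])
    cost = np.full((n + 1, n + 1), np.inf)
    for i in range(n):
        m = np.arange(1, n - i + 1)[:, None]                       # segment lengths
        seg_sum = s1[i + 1:] - s1[i]
        seg_sq = s2[i + 1:] - s2[i]
        var = seg_sq / m - (seg_sum / m) ** 2
        var = np.maximum(var, floor)
        c = (m * np.log(var)).sum(axis=1)
        js = np.arange(i + 1, n + 1)
        ok = (js - i) >= lmin
        cost[i, js[ok]] = c[ok]
    return cost


def _dp_optimal(cost: np.ndarray, n: int, k: int, lmin: int):
    """Exact minimum-contrast segmentation into k segments; returns
    (total contrast, breakpoint list)."""
    best = np.full((k + 1, n + 1), np.inf)
    argmin = np.zeros((k + 1, n + 1), dtype=int)
    best[0, 0] = 0.0
    for kk in range(1, k + 1):
        for j in range(kk * lmin, n + 1):
            lo, hi = (kk - 1) * lmin, j - lmin + 1
            cand = best[kk - 1, lo:hi] + cost[lo:hi, j]
            if cand.size == 0 or not np.isfinite(cand).any():
                continue
            a = int(np.nanargmin(cand))
            best[kk, j] = cand[a]
            argmin[kk, j] = lo + a
    if not np.isfinite(best[k, n]):
        return np.inf, []
    bps, j = [], n
    for kk in range(k, 0, -1):
        i = argmin[kk, j]
        if kk > 1:
            bps.append(int(i))
        j = i
    return float(best[k, n]), sorted(bps)


def lavielle_select_k(contrasts: Sequence[float], threshold: float = 0.75) -> int:
    """Choose K from the decreasing contrast curve J(1..Kmax) by Lavielle's
    normalized second-difference rule.

    The curve is first trimmed to its strictly decreasing prefix: once the
    minimum-segment-length constraint makes extra segments infeasible to
    place, J(K) stops improving, and those trailing values carry no
    information about K (they would otherwise fake a curvature spike).  The
    trimmed curve is rescaled so J~(1) = Keff and J~(Keff) = 1; K is the
    largest value whose second difference D(K) = J~(K-1) - 2 J~(K) + J~(K+1)
    exceeds ``threshold``; 1 when none does.
    """
    J = np.asarray(contrasts, dtype=float)
    tol = 1e-9 * max(1.0, abs(float(J[0])))
    keff = 1
    while keff < len(J) and J[keff] < J[keff - 1] - tol:
        keff += 1
    J = J[:keff]
    kmax = len(J)
    if kmax < 3 or J[0] == J[-1]:
        return 1
    Jn = (J[-1] - J) / (J[-1] - J[0]) * (kmax - 1) + 1   # J~(1)=Kmax ... J~(Kmax)=1
    best_k = 1
    for k in range(2, kmax):                              # K has neighbors K-1, K+1
        d = Jn[k - 2] - 2.0 * Jn[k - 1] + Jn[k]
        if d > threshold:
            best_k = k
    return best_k


def segment(track: RegularizedTrack, lmin: int = 40, kmax: Optional[int] = None,
            threshold: float = 0.75) -> PhaseModel:
    """Segment a regularized track into stationary phases.

    ``lmin`` is the minimum segment length in epochs (40 epochs = 20 days at
    the 12-h spacing).  For each K up to ``kmax`` the exact optimum is found
    by dynamic programming; K is selected by :func:`lavielle_select_k`.
    """
    xy = np.asarray(track.xy, dtype=float)
    n = len(xy)
    if kmax is None:
        kmax = min(10, n // lmin) if lmin else 10
    kmax = max(1, kmax)
    if n < 2 * lmin or kmax == 1:
        mean = xy.mean(axis=0, keepdims=True)
        var = np.maximum(xy.var(axis=0, keepdims=True), VAR_FLOOR)
        return PhaseModel([], 1, mean, var, {1: float("nan")}, lmin,
                          note="series too short for multi-phase segmentation" if n < 2 * lmin else "")

    cost = _segment_cost_table(xy, lmin)
    contrasts, bps_by_k = {}, {}
    for k in range(1, kmax + 1):
        J, bps = _dp_optimal(cost, n, k, lmin)
        if not np.isfinite(J):
            break
        contrasts[k] = J
        bps_by_k[k] = bps
    ks = sorted(contrasts)
    k_sel = lavielle_select_k([contrasts[k] for k in ks], threshold=threshold)
    k_sel = ks[k_sel - 1]
    # minimum-evidence guard: each extra segment costs ~5 parameters (two
    # means, two variances, one breakpoint), so its contrast drop (-2 delta
    # log L) must exceed 5 log n to be kept; the curvature rule alone is
    # noisy when lmin caps Kmax at a handful of segments.
    penalty = 5.0 * np.log(n)
    k_guard = 1
    while (k_guard + 1 in contrasts
           and contrasts[k_guard] - contrasts[k_guard + 1] >= penalty):
        k_guard += 1
    k_sel = min(k_sel, k_guard)
    bps = bps_by_k[k_sel]

    bounds = [0] + bps + [n]
    means = np.array([xy[a:b].mean(axis=0) for a, b in zip(bounds[:-1], bounds[1:])])
    varis = np.array([np.maximum(xy[a:b].var(axis=0), VAR_FLOOR)
                      for a, b in zip(bounds[:-1], bounds[1:])])
    return PhaseModel(bps, k_sel, means, varis, contrasts, lmin)


# ---------------------------------------------------------------------------
# Phase overlap (Bhattacharyya coefficient of masked UDs)
# ---------------------------------------------------------------------------

def bhattacharyya_coefficient(pa: np.ndarray, pb: np.ndarray) -> float:
    """BC = sum sqrt(pa * pb) for two discrete densities on a shared grid."""
    pa = np.asarray(pa, dtype=float)
    pb = np.asarray(pb, dtype=float)
    if pa.shape != pb.shape:
        raise ValueError("densities must share a grid")
    return float(np.sqrt(pa * pb).sum())


def phase_ud_overlap(xy_a: np.ndarray, xy_b: np.ndarray, h: float,
                     cell_size: float = 50.0, mask_level: Optional[float] = 0.95,
                     distinct_below: float = 0.5, min_fixes: int = 30) -> PhasePair:
    """Bhattacharyya overlap of two phases' utilization distributions.

    Both UDs are evaluated on a shared grid covering both point sets; each is
    (optionally) masked to its own ``mask_level`` isopleth and renormalized
    before the coefficient is computed.  ``distinct`` is ``bc < distinct_below``.
    """
    from .homerange import kde_ud  # late import; homerange depends on nothing here

    xy_a = np.asarray(xy_a, dtype=float)
    xy_b = np.asarray(xy_b, dtype=float)
    for name, pts in (("a", xy_a), ("b", xy_b)):
        if len(pts) < min_fixes:
            warnings.warn(f"phase {name} has fewer than {min_fixes} fixes; "
                          "BC may be unstable", stacklevel=2)
        if len(pts) and np.allclose(pts.std(axis=0), 0.0):
            warnings.warn(f"phase {name} is degenerate (all fixes identical); "
                          "computing BC with minimum smoothing", stacklevel=2)

    allpts = np.vstack([xy_a, xy_b])
    lo = allpts.min(axis=0) - 3.0 * h
    hi = allpts.max(axis=0) + 3.0 * h
    grid_a = kde_ud(xy_a, h=h, cell_size=cell_size, bounds=(lo, hi))
    grid_b = kde_ud(xy_b, h=h, cell_size=cell_size, bounds=(lo, hi))
    pa = grid_a.density * grid_a.cell_area
    pb = grid_b.density * grid_b.cell_area

    if mask_level is not None and mask_level < 1.0:
        for p in (pa, pb):
            flat = p.ravel()
            order = np.argsort(flat)[::-1]
            cum = np.cumsum(flat[order])
            k = int(np.searchsorted(cum, mask_level)) + 1
            mask = np.zeros(flat.shape, dtype=bool)
            mask[order[:k]] = True
            flat[~mask] = 0.0
        pa /= pa.sum()
        pb /= pb.sum()

    bc = bhattacharyya_coefficient(pa, pb)
    bc = min(max(bc, 0.0), 1.0)
    return PhasePair(0, 1, bc, bc < distinct_below)
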