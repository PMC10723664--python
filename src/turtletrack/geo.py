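"""Spherical geometry primitives: great-circle distance and bearing, circular
statistics, and a local azimuthal equidistant projection.

All distance computations use a spherical Earth of radius 6371 km, which keeps
errors well below 0.1% at the spatial scale of a shallow-water platform
(~50 km) and is the convention used throughout the pipeline.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or numpy arrays (broadcast).
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    if np.isscalar(lon1) or d.ndim == 0:
        return float(d)
    return d


def initial_bearing_deg(lon1, lat1, lon2, lat2):
    """Initial great-circle bearing (degrees clockwise from true north) from
    point 1 to point 2."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    b = np.degrees(np.arctan2(y, x)) % 360.0
    if b.ndim == 0:
        return float(b)
    return b


def circular_mean_deg(angles_deg):
    """Circular mean of angles in degrees, in [0, 360)."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("circular mean of empty set")
    s, c = np.sin(a).mean(), np.cos(a).mean()
    deg = float(np.degrees(np.arctan2(s, c)) % 360.0)
    return 0.0 if deg >= 360.0 - 1e-9 else deg


def circular_sd_deg(angles_deg):
    """Circular standard deviation (Mardia) of angles in degrees."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("circular sd of empty set")
    r = float(np.hypot(np.sin(a).mean(), np.cos(a).mean()))
    r = min(max(r, 1e-12), 1.0)
    return float(np.degrees(np.sqrt(-2.0 * np.log(r))))


class LocalProjection:
    """Azimuthal equidistant projection on the sphere, centered at
    ``(lon0, lat0)``; forward maps degrees to meters (x east, y north).

    Distances from the center are exact; distortion elsewhere is second order
    in (extent / Earth radius), negligible at tens of km.
    """

    def __init__(self, lon0: float, lat0: float):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self._lam0 = np.radians(self.lon0)
        self._phi0 = np.radians(self.lat0)

    @classmethod
    def for_points(cls, lons, lats) -> "LocalProjection":
        """Projection centered on the centroid of the given coordinates."""
        return cls(float(np.mean(lons)), float(np.mean(lats)))

    def forward(self, lons, lats):
        """(lon, lat) degrees -> (x, y) meters."""
        lam = np.radians(np.asarray(lons, dtype=float))
        phi = np.radians(np.asarray(lats, dtype=float))
        sin0, cos0 = np.sin(self._phi0), np.cos(self._phi0)
        cosc = np.clip(sin0 * np.sin(phi) + cos0 * np.cos(phi) * np.cos(lam - self._lam0),
                       -1.0, 1.0)
        c = np.arccos(cosc)
        # k = c / sin(c), with the removable singularity at c = 0
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
        r_m = EARTH_RADIUS_KM * 1000.0
        x = r_m * k * np.cos(phi) * np.sin(lam - self._lam0)
        y = r_m * k * (cos0 * np.sin(phi) - sin0 * np.cos(phi) * np.cos(lam - self._lam0))
        return np.asarray(x, dtype=float), np.asarray(y, dtype=float)

    def inverse(self, xs, ys):
        """(x, y) meters -> (lon, lat) degrees."""
        x = np.asarray(xs, dtype=float)
        y = np.asarray(ys, dtype=float)
        r_m = EARTH_RADIUS_KM * 1000.0
        rho = np.hypot(x, y)
        c = rho / r_m
        sin0, cos0 = np.sin(self._phi0), np.cos(self._phi0)
        sinc, cosc = np.sin(c), np.cos(c)
        safe_rho = np.where(rho > 1e-9, rho, 1.0)
        phi = np.arcsin(np.clip(cosc * sin0 + y * sinc * cos0 / safe_rho, -1.0, 1.0))
        lam = self._lam0 + np.arctan2(x * sinc,
                                      safe_rho * cosc * cos0 - y * sinc * sin0)
        phi = np.where(rho > 1e-9, phi, self._phi0)
        lam = np.where(rho > 1e-9, lam, self._lam0)
        return np.degrees(lam), np.degrees(phi)
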