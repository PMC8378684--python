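"""Great-circle geometry on the WGS-84 equatorial sphere (R = 6378137 m).

All functions accept degrees and are vectorized over numpy arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = ["EARTH_RADIUS_M", "haversine_km", "destination_point", "geographic_median"]

EARTH_RADIUS_M = 6_378_137.0


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km (haversine formula, sphere R = 6378137 m)."""
    p1, l1, p2, l2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dphi = p2 - p1
    dlam = l2 - l1
    h = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_M / 1000.0 * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def destination_point(lat, lon, bearing_deg, distance_km):
    """Point reached from (lat, lon) travelling ``distance_km`` at a bearing."""
    phi1, lam1, theta = map(np.radians, (lat, lon, bearing_deg))
    delta = np.asarray(distance_km) * 1000.0 / EARTH_RADIUS_M
    phi2 = np.arcsin(
        np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(theta)
    )
    lam2 = lam1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(phi1),
        np.cos(delta) - np.sin(phi1) * np.sin(phi2),
    )
    lat2 = np.degrees(phi2)
    lon2 = (np.degrees(lam2) + 180.0) % 360.0 - 180.0
    return lat2, lon2


def _to_unit_vectors(lat, lon):
    phi, lam = np.radians(lat), np.radians(lon)
    return np.stack(
        [np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)], axis=-1
    )


def geographic_median(
    lats, lons, *, tol_m: float = 1.0, max_iter: int = 200
) -> tuple[float, float]:
    """Point minimizing summed great-circle distances to the inputs.

    Riemannian Weiszfeld iteration: points are mapped into the tangent plane
    at the current estimate (log map), the inverse-distance-weighted mean is
    taken there, and the step is mapped back (exp map).  Stops when the
    estimate moves by less than ``tol_m`` metres.  Inputs coincident with the
    current estimate are handled by the standard epsilon guard.
    """
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    if lats.size == 0:
        raise ValueError("geographic_median requires at least one point")
    if lats.size == 1:
        return float(lats[0]), float(lons[0])

    pts = _to_unit_vectors(lats, lons)
    x = pts.mean(axis=0)
    norm = np.linalg.norm(x)
    x = pts[0] if norm < 1e-12 else x / norm

    eps = 1e-12
    for _ in range(max_iter):
        cosd = np.clip(pts @ x, -1.0, 1.0)
        d = np.arccos(cosd)  # radians ∝ great-circle distance
        # tangent vectors at x pointing to each point, with length d
        tang = pts - cosd[:, None] * x
        tnorm = np.linalg.norm(tang, axis=1)
        keep = tnorm > eps
        unit_tang = np.zeros_like(tang)
        unit_tang[keep] = tang[keep] / tnorm[keep, None]
        w = 1.0 / np.maximum(d, eps)
        u = (unit_tang * (w * d)[:, None]).sum(axis=0) / w.sum()
        step_rad = np.linalg.norm(u)
        if step_rad > eps:
            x = np.cos(step_rad) * x + np.sin(step_rad) * u / step_rad
            x /= np.linalg.norm(x)
        if step_rad * EARTH_RADIUS_M < tol_m:
            break

    # Weiszfeld stalls at input points (the objective is non-smooth there);
    # if a data point beats the iterate, the median is that point.
    def total(v: np.ndarray) -> float:
        return float(np.arccos(np.clip(pts @ v, -1.0, 1.0)).sum())

    best_idx = int(np.argmin([total(p) for p in pts]))
    if total(pts[best_idx]) < total(x):
        x = pts[best_idx]
    lat = float(np.degrees(np.arcsin(np.clip(x[2], -1.0, 1.0))))
    lon = float(np.degrees(np.arctan2(x[1], x[0])))
    return lat, lon
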