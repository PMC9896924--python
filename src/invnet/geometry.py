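"""Distance and projection helpers for the two coordinate modes.

``planar_km`` treats coordinates as kilometres on a flat plane, so Euclidean
distances are exact.  ``geographic_lonlat`` treats coordinates as WGS84
longitude/latitude: point distances are great-circle (haversine) and area
work (rasterization) goes through a Lambert cylindrical equal-area
projection centred on the data.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius

PLANAR = "planar_km"
GEOGRAPHIC = "geographic_lonlat"
CRS_MODES = (PLANAR, GEOGRAPHIC)


def haversine_km(x1, y1, x2, y2) -> np.ndarray:
    """Great-circle distance in km between lon/lat points (degrees)."""
    lam1, phi1, lam2, phi2 = (np.radians(np.asarray(v, dtype=float)) for v in (x1, y1, x2, y2))
    dphi = phi2 - phi1
    dlam = lam2 - lam1
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def point_distance_km(x1, y1, x2, y2, crs_mode: str = PLANAR) -> np.ndarray:
    """Distance in km between two point arrays under the given mode."""
    if crs_mode == PLANAR:
        x1, y1, x2, y2 = (np.asarray(v, dtype=float) for v in (x1, y1, x2, y2))
        return np.hypot(x2 - x1, y2 - y1)
    if crs_mode == GEOGRAPHIC:
        return haversine_km(x1, y1, x2, y2)
    raise ValueError(f"unknown crs_mode: {crs_mode!r}")


def equal_area_xy_km(lon, lat, lat_std: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Lambert cylindrical equal-area forward projection, output in km.

    ``lat_std`` is the standard parallel (degrees); pick the data's mean
    latitude to limit shape distortion.
    """
    lam = np.radians(np.asarray(lon, dtype=float))
    phi = np.radians(np.asarray(lat, dtype=float))
    k = np.cos(np.radians(lat_std))
    return EARTH_RADIUS_KM * lam * k, EARTH_RADIUS_KM * np.sin(phi) / k


def pairwise_distance_km(xy_a: np.ndarray, xy_b: np.ndarray, crs_mode: str = PLANAR) -> np.ndarray:
    """(n, m) distance matrix between two (·, 2) coordinate arrays."""
    a = np.asarray(xy_a, dtype=float)
    b = np.asarray(xy_b, dtype=float)
    if crs_mode == PLANAR:
        diff = a[:, None, :] - b[None, :, :]
        return np.hypot(diff[..., 0], diff[..., 1])
    return haversine_km(
        a[:, None, 0], a[:, None, 1], b[None, :, 0], b[None, :, 1]
    )
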