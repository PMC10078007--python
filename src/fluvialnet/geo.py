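"""Small geodesic helpers (WGS84, haversine).

All public functions take longitude/latitude in decimal degrees and return
kilometres or metres as stated. At the sub-degree extents this package works
with, haversine great-circle distance is accurate to far better than the
1 m junction-merge tolerance, so no ellipsoidal correction is applied.
"""
from __future__ import annotations

import math
from collections.abc import Sequence

import numpy as np

EARTH_RADIUS_KM = 6371.0088
#: metres per degree of great-circle arc (2*pi*R / 360)
METERS_PER_DEGREE = 2.0 * math.pi * EARTH_RADIUS_KM * 1000.0 / 360.0


def haversine_km(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Great-circle distance between two points, in kilometres."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlmb / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def haversine_km_many(lon: float, lat: float, lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
    """Vectorised haversine from one point to arrays of points, in km."""
    phi1 = math.radians(lat)
    phi2 = np.radians(lats)
    dphi = phi2 - phi1
    dlmb = np.radians(lons - lon)
    a = np.sin(dphi / 2.0) ** 2 + math.cos(phi1) * np.cos(phi2) * np.sin(dlmb / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def polyline_length_km(coords: Sequence[tuple[float, float]]) -> float:
    """Geodesic length of a (lon, lat) polyline, in kilometres."""
    return sum(
        haversine_km(coords[i][0], coords[i][1], coords[i + 1][0], coords[i + 1][1])
        for i in range(len(coords) - 1)
    )


def meters_to_degrees(meters: float) -> float:
    """Convert a metric tolerance to degrees of great-circle arc."""
    return meters / METERS_PER_DEGREE


def degrees_to_meters(degrees: float) -> float:
    return degrees * METERS_PER_DEGREE
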