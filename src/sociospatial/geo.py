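"""Planar-geometry helpers.

All package geometry is done in planar metres. Survey data that arrives in
longitude/latitude must be projected first; :func:`lonlat_to_local` applies
a local equirectangular projection about a reference point, which is
accurate to well under 1% for study areas up to ~100 km across — adequate
for travel rings and kernel bandwidths at that scale. No geodesic distances
are computed anywhere.
"""

from __future__ import annotations

import math

import numpy as np

EARTH_RADIUS_M = 6_371_008.8  # mean Earth radius

Point = tuple[float, float]


def distance(a: Point, b: Point) -> float:
    """Euclidean distance between two planar points (metres)."""
    return math.hypot(a[0] - b[0], a[1] - b[1])


def lonlat_to_local(
    lon: np.ndarray | float,
    lat: np.ndarray | float,
    origin: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Project (lon, lat) degrees to planar metres about ``origin``
    (lon0, lat0) with a local equirectangular projection:

        x = R * cos(lat0) * (lon - lon0),  y = R * (lat - lat0)   [radians]
    """
    lon0, lat0 = origin
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x = EARTH_RADIUS_M * math.cos(math.radians(lat0)) * np.radians(lon - lon0)
    y = EARTH_RADIUS_M * np.radians(lat - lat0)
    return x, y


def sample_disk(
    rng: np.random.Generator, center: Point, radius: float
) -> Point:
    """One point uniformly distributed on the disk of ``radius`` about
    ``center`` (area-uniform: r = R·√u)."""
    u = rng.random()
    theta = rng.random() * 2.0 * math.pi
    r = radius * math.sqrt(u)
    return (center[0] + r * math.cos(theta), center[1] + r * math.sin(theta))
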