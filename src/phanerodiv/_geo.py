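"""Spherical geometry and raster-line primitives.

All distances are great-circle kilometres on a sphere of radius 6,371 km.
Raster paths are traced with Bresenham's line algorithm in grid-index space,
wrapping longitude along the shorter arc.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points given in degrees.

    Accepts scalars or broadcastable arrays.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    # clip guards rounding for antipodal/coincident points
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def unit_vectors(lat, lon):
    """(n, 3) unit vectors on the sphere for lat/lon in degrees.

    Chord distance between unit vectors is monotone in great-circle
    distance, so KD-tree nearest neighbours on these are exact.
    """
    lat = np.radians(np.asarray(lat, dtype=float))
    lon = np.radians(np.asarray(lon, dtype=float))
    return np.column_stack(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)]
    )


def chord_from_km(d_km: float) -> float:
    """Chord length subtending a great-circle distance on the unit sphere."""
    return 2.0 * np.sin(min(d_km / EARTH_RADIUS_KM, np.pi) / 2.0)


def wrap_lon(lon):
    """Wrap longitudes into [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


def bresenham(r0: int, c0: int, r1: int, c1: int) -> list[tuple[int, int]]:
    """Integer raster line from (r0, c0) to (r1, c1), endpoints inclusive."""
    cells = []
    dr = abs(r1 - r0)
    dc = abs(c1 - c0)
    sr = 1 if r1 >= r0 else -1
    sc = 1 if c1 >= c0 else -1
    err = dc - dr
    r, c = r0, c0
    while True:
        cells.append((r, c))
        if r == r1 and c == c1:
            break
        e2 = 2 * err
        if e2 > -dr:
            err -= dr
            c += sc
        if e2 < dc:
            err += dc
            r += sr
    return cells


def bresenham_wrap(r0: int, c0: int, r1: int, c1: int, n_cols: int) -> list[tuple[int, int]]:
    """Bresenham path on a longitude-periodic grid.

    Columns wrap modulo ``n_cols``; the path takes the shorter longitudinal
    direction across the antimeridian.
    """
    dc = c1 - c0
    if dc > n_cols / 2:
        c1 -= n_cols
    elif dc < -n_cols / 2:
        c1 += n_cols
    return [(r, c % n_cols) for r, c in bresenham(r0, c0, r1, c1)]
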