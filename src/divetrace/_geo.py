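"""Great-circle geometry helpers shared across the package.

All functions take longitude/latitude in WGS84 decimal degrees and work on
numpy arrays. Distances use the haversine formula with a spherical Earth of
radius 6,371 km.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_000.0

#: metres per degree of latitude on the 6371-km sphere
M_PER_DEG = EARTH_RADIUS_M * np.pi / 180.0


def haversine_m(lon1, lat1, lon2, lat2):
    """Great-circle distance in metres between two points (degrees)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def initial_bearing_rad(lon1, lat1, lon2, lat2):
    """Initial great-circle bearing, clockwise from north, in (-pi, pi]."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    x = np.sin(dlon) * np.cos(lat2)
    y = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.arctan2(x, y)


def wrap_angle(a):
    """Wrap angles to (-pi, pi]; exactly -pi maps to +pi."""
    a = np.asarray(a, dtype=float)
    w = np.mod(a + np.pi, 2.0 * np.pi) - np.pi
    return np.where(w == -np.pi, np.pi, w)
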