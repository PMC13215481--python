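"""Spherical-Earth geodesy helpers.

All distances use a spherical Earth of radius 6371 km. Local east-west
kilometre conversions scale degrees of longitude by cos(latitude); this is
accurate to well under a percent at the sub-degree scales of coastal search
areas.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0
#: kilometres per degree of latitude (pi * R / 180)
KM_PER_DEG = np.pi * EARTH_RADIUS_KM / 180.0
#: metres per degree of latitude
M_PER_DEG = KM_PER_DEG * 1000.0


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def local_km_offsets(lat, lon, ref_lat, ref_lon):
    """East/north offsets in km of (lat, lon) from a reference point.

    Uses the equirectangular approximation with cos(ref_lat) scaling for
    longitude; adequate for search-area membership tests spanning < 2 degrees.
    """
    dx = (np.asarray(lon, dtype=float) - ref_lon) * KM_PER_DEG * np.cos(np.radians(ref_lat))
    dy = (np.asarray(lat, dtype=float) - ref_lat) * KM_PER_DEG
    return dx, dy


def degree_distance(lat, lon, ref_lat, ref_lon):
    """Distance in 'local degrees' with cos-latitude longitude scaling.

    A circle of radius r in this metric approximates a geographic circle of
    radius r degrees of latitude around the reference point.
    """
    dx = (np.asarray(lon, dtype=float) - ref_lon) * np.cos(np.radians(ref_lat))
    dy = np.asarray(lat, dtype=float) - ref_lat
    return np.hypot(dx, dy)
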