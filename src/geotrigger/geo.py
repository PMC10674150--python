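"""Great-circle geometry helpers.

All coordinates are WGS84 decimal degrees; all distances are meters on a
spherical Earth (mean radius). Accuracy is ample for the sub-kilometer
displacement thresholds used in dwell detection.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_008.8

__all__ = ["EARTH_RADIUS_M", "haversine_m", "offset_point"]


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in meters between coordinate pairs.

    Accepts scalars or numpy arrays (broadcast); returns the same shape.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def offset_point(lat: float, lon: float, north_m: float, east_m: float) -> tuple[float, float]:
    """Displace a coordinate by meters north/east (local equirectangular).

    Used by the simulator to lay out synthetic places; error is negligible
    for the few-kilometer offsets involved.
    """
    dlat = north_m / 111_320.0
    dlon = east_m / (111_320.0 * np.cos(np.radians(lat)))
    return float(lat + dlat), float(lon + dlon)
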