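"""Great-circle geometry on the WGS84 mean-radius sphere."""

from __future__ import annotations

import numpy as np

#: IUGG mean Earth radius, km.
EARTH_RADIUS_KM = 6371.0088


def great_circle_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Haversine distance in km between two (latitude, longitude) pairs."""
    lat1, lon1, lat2, lon2 = map(np.radians, (*a, *b))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 \
        + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1))))
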