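"""Great-circle distance helpers (haversine on a spherical Earth)."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Pairwise-broadcasting great-circle distance in km.

    Inputs are decimal degrees; standard numpy broadcasting applies, so
    ``haversine_km(lons[:, None], lats[:, None], lons, lats)`` yields the full
    distance matrix.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
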