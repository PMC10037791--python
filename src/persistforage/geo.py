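"""Local tangent-plane coordinates.

Movement processes here are defined on displacements in km, so tracks are
projected onto a local equirectangular tangent plane anchored at a reference
point (by default the domain centre).  At the ~10^2-km scale of a foraging
study the distortion of this projection is negligible relative to Argos
location error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

KM_PER_DEG_LAT = 110.574
KM_PER_DEG_LON_EQ = 111.320


@dataclass(frozen=True)
class TangentPlane:
    """Equirectangular projection anchored at (lon0, lat0)."""

    lon0: float
    lat0: float

    @property
    def _kx(self) -> float:
        return KM_PER_DEG_LON_EQ * np.cos(np.deg2rad(self.lat0))

    def to_km(self, lon, lat):
        """Project lon/lat (degrees) to x/y in km east/north of the anchor."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (lon - self.lon0) * self._kx, (lat - self.lat0) * KM_PER_DEG_LAT

    def to_lonlat(self, x_km, y_km):
        """Inverse of :meth:`to_km`."""
        x_km = np.asarray(x_km, dtype=float)
        y_km = np.asarray(y_km, dtype=float)
        return self.lon0 + x_km / self._kx, self.lat0 + y_km / KM_PER_DEG_LAT
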