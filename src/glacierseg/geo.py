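"""Spherical geometry helpers: great-circle distances and a local planar projection.

All geographic coordinates are WGS84 lon/lat degrees.  Planar work (buffers,
kernel grids, Euclidean colony separation) happens in a local azimuthal
equidistant projection centred on the study area, where distances from the
centre are exact and distortion is negligible over a ~100-km study region.
"""

from __future__ import annotations

import numpy as np

#: Mean Earth radius (km), IUGG value.
EARTH_RADIUS_KM = 6371.0088


def great_circle_km(p1, p2) -> float | np.ndarray:
    """Great-circle (haversine) distance in km between lon/lat points.

    Accepts scalar pairs or broadcastable arrays of ``(lon, lat)`` degrees.
    """
    lon1, lat1 = np.radians(np.asarray(p1, dtype=float)[..., 0]), np.radians(
        np.asarray(p1, dtype=float)[..., 1]
    )
    lon2, lat2 = np.radians(np.asarray(p2, dtype=float)[..., 0]), np.radians(
        np.asarray(p2, dtype=float)[..., 1]
    )
    a = (
        np.sin((lat2 - lat1) / 2.0) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2
    )
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if np.ndim(d) == 0 else d


class LocalProjection:
    """Azimuthal equidistant projection (spherical) centred on ``(lon0, lat0)``.

    ``forward`` maps lon/lat degrees to planar metres; ``inverse`` round-trips
    to well under a metre within a few hundred km of the centre.
    """

    def __init__(self, lon0: float, lat0: float):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self._lam0 = np.radians(lon0)
        self._phi0 = np.radians(lat0)

    @property
    def centre(self) -> tuple[float, float]:
        return (self.lon0, self.lat0)

    def forward(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        lam = np.radians(np.asarray(lon, dtype=float))
        phi = np.radians(np.asarray(lat, dtype=float))
        sin0, cos0 = np.sin(self._phi0), np.cos(self._phi0)
        dlam = lam - self._lam0
        cosc = sin0 * np.sin(phi) + cos0 * np.cos(phi) * np.cos(dlam)
        c = np.arccos(np.clip(cosc, -1.0, 1.0))
        # k = c / sin(c) -> 1 at the centre
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
        R = EARTH_RADIUS_KM * 1000.0
        x = R * k * np.cos(phi) * np.sin(dlam)
        y = R * k * (cos0 * np.sin(phi) - sin0 * np.cos(phi) * np.cos(dlam))
        return x, y

    def inverse(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        R = EARTH_RADIUS_KM * 1000.0
        rho = np.hypot(x, y)
        c = rho / R
        sin0, cos0 = np.sin(self._phi0), np.cos(self._phi0)
        sinc, cosc = np.sin(c), np.cos(c)
        with np.errstate(invalid="ignore", divide="ignore"):
            safe_rho = np.where(rho > 1e-12, rho, 1.0)
            phi = np.arcsin(
                np.clip(cosc * sin0 + np.where(rho > 1e-12, y * sinc * cos0 / safe_rho, 0.0), -1.0, 1.0)
            )
            lam = self._lam0 + np.arctan2(
                x * sinc, safe_rho * cos0 * cosc - y * sin0 * sinc
            )
        lam = np.where(rho > 1e-12, lam, self._lam0)
        phi = np.where(rho > 1e-12, phi, self._phi0)
        return np.degrees(lam), np.degrees(phi)
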