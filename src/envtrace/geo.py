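"""Geodetic helpers: WGS84 transverse-Mercator (UTM) projection and haversine.

Pasture-scale trajectories need metric coordinates so that Euclidean
distances approximate great-circle distances to well under 0.1%.  The
forward/inverse transverse-Mercator series below (Snyder, *Map
Projections — A Working Manual*, USGS PP 1395, eqs. 8-9..8-25) are
accurate to centimetres anywhere inside a UTM zone, which is orders of
magnitude below GPS noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_E2 = _F * (2.0 - _F)
_EP2 = _E2 / (1.0 - _E2)
_K0 = 0.9996
_FALSE_EASTING = 500000.0


@dataclass(frozen=True)
class UtmZone:
    """A UTM zone configuration (defaults to zone 31 N, central meridian 3 E)."""

    number: int = 31
    north: bool = True

    @property
    def central_meridian_deg(self) -> float:
        return -183.0 + 6.0 * self.number

    @property
    def false_northing(self) -> float:
        return 0.0 if self.north else 10000000.0


def _meridian_arc(phi: np.ndarray) -> np.ndarray:
    e2, e4, e6 = _E2, _E2**2, _E2**3
    return _A * (
        (1 - e2 / 4 - 3 * e4 / 64 - 5 * e6 / 256) * phi
        - (3 * e2 / 8 + 3 * e4 / 32 + 45 * e6 / 1024) * np.sin(2 * phi)
        + (15 * e4 / 256 + 45 * e6 / 1024) * np.sin(4 * phi)
        - (35 * e6 / 3072) * np.sin(6 * phi)
    )


def geodetic_to_utm(lat_deg, lon_deg, zone: UtmZone = UtmZone()):
    """Project latitude/longitude (degrees) to UTM easting/northing (metres)."""
    phi = np.radians(np.asarray(lat_deg, dtype=float))
    lam = np.radians(np.asarray(lon_deg, dtype=float))
    lam0 = np.radians(zone.central_meridian_deg)

    sin_phi, cos_phi, tan_phi = np.sin(phi), np.cos(phi), np.tan(phi)
    n_rad = _A / np.sqrt(1 - _E2 * sin_phi**2)
    t = tan_phi**2
    c = _EP2 * cos_phi**2
    a_ = (lam - lam0) * cos_phi
    m = _meridian_arc(phi)

    x = _K0 * n_rad * (
        a_
        + (1 - t + c) * a_**3 / 6
        + (5 - 18 * t + t**2 + 72 * c - 58 * _EP2) * a_**5 / 120
    ) + _FALSE_EASTING
    y = _K0 * (
        m
        + n_rad
        * tan_phi
        * (
            a_**2 / 2
            + (5 - t + 9 * c + 4 * c**2) * a_**4 / 24
            + (61 - 58 * t + t**2 + 600 * c - 330 * _EP2) * a_**6 / 720
        )
    ) + zone.false_northing
    return x, y


def utm_to_geodetic(x, y, zone: UtmZone = UtmZone()):
    """Inverse projection: UTM easting/northing (metres) to lat/lon degrees."""
    x = np.asarray(x, dtype=float) - _FALSE_EASTING
    y = np.asarray(y, dtype=float) - zone.false_northing
    lam0 = np.radians(zone.central_meridian_deg)

    m = y / _K0
    e1 = (1 - np.sqrt(1 - _E2)) / (1 + np.sqrt(1 - _E2))
    mu = m / (_A * (1 - _E2 / 4 - 3 * _E2**2 / 64 - 5 * _E2**3 / 256))
    phi1 = (
        mu
        + (3 * e1 / 2 - 27 * e1**3 / 32) * np.sin(2 * mu)
        + (21 * e1**2 / 16 - 55 * e1**4 / 32) * np.sin(4 * mu)
        + (151 * e1**3 / 96) * np.sin(6 * mu)
        + (1097 * e1**4 / 512) * np.sin(8 * mu)
    )

    sin1, cos1, tan1 = np.sin(phi1), np.cos(phi1), np.tan(phi1)
    c1 = _EP2 * cos1**2
    t1 = tan1**2
    n1 = _A / np.sqrt(1 - _E2 * sin1**2)
    r1 = _A * (1 - _E2) / (1 - _E2 * sin1**2) ** 1.5
    d = x / (n1 * _K0)

    phi = phi1 - (n1 * tan1 / r1) * (
        d**2 / 2
        - (5 + 3 * t1 + 10 * c1 - 4 * c1**2 - 9 * _EP2) * d**4 / 24
        + (61 + 90 * t1 + 298 * c1 + 45 * t1**2 - 252 * _EP2 - 3 * c1**2)
        * d**6
        / 720
    )
    lam = lam0 + (
        d
        - (1 + 2 * t1 + c1) * d**3 / 6
        + (5 - 2 * c1 + 28 * t1 - 3 * c1**2 + 8 * _EP2 + 24 * t1**2) * d**5 / 120
    ) / cos1
    return np.degrees(phi), np.degrees(lam)


def haversine_m(lat1, lon1, lat2, lon2, radius_m: float = 6371008.8):
    """Great-circle distance in metres (spherical earth, mean radius)."""
    p1, p2 = np.radians(np.asarray(lat1, float)), np.radians(np.asarray(lat2, float))
    dphi = p2 - p1
    dlam = np.radians(np.asarray(lon2, float)) - np.radians(np.asarray(lon1, float))
    h = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return 2 * radius_m * np.arcsin(np.sqrt(h))
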