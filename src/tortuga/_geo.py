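"""Transverse-Mercator (UTM) <-> geographic conversion on WGS84.

Handheld GPS receivers used on the beaches report UTM zone 16Q positions;
the audit's regional bounding box is stated in decimal degrees, so the
range check needs a projection inverse.  The classic truncated series for
the transverse Mercator projection (Snyder's formulation) is accurate to
well under a metre across a UTM zone, far below the tolerance of a
beach-scale bounding box.
"""

from __future__ import annotations

import math

__all__ = ["utm_to_latlon", "latlon_to_utm", "parse_zone"]

_A = 6378137.0                       # WGS84 semi-major axis (m)
_F = 1 / 298.257223563               # WGS84 flattening
_E2 = _F * (2 - _F)                  # first eccentricity squared
_EP2 = _E2 / (1 - _E2)               # second eccentricity squared
_K0 = 0.9996                         # UTM scale on the central meridian
_E4 = _E2 * _E2
_E6 = _E4 * _E2
# coefficient of the meridian-arc series
_M0 = 1 - _E2 / 4 - 3 * _E4 / 64 - 5 * _E6 / 256

# Latitude bands C..X (I and O skipped); N and later are northern hemisphere.
_BANDS = "CDEFGHJKLMNPQRSTUVWX"


def parse_zone(zone: str) -> tuple[int, bool]:
    """Split a zone designator like ``"16Q"`` into (number, northern)."""
    z = zone.strip().upper()
    if not z:
        raise ValueError("empty UTM zone")
    letter = ""
    if z[-1].isalpha():
        letter, z = z[-1], z[:-1]
    try:
        num = int(z)
    except ValueError as exc:
        raise ValueError(f"unparseable UTM zone {zone!r}") from exc
    if not 1 <= num <= 60:
        raise ValueError(f"UTM zone number {num} out of 1..60")
    if letter:
        if letter not in _BANDS:
            raise ValueError(f"unknown UTM band letter {letter!r}")
        northern = _BANDS.index(letter) >= _BANDS.index("N")
    else:
        northern = True
    return num, northern


def _central_meridian(zone_number: int) -> float:
    return math.radians((zone_number - 1) * 6 - 180 + 3)


def latlon_to_utm(lat: float, lon: float,
                  zone_number: int | None = None) -> tuple[float, float, int]:
    """Forward projection; returns (easting, northing, zone_number)."""
    if not (-80.0 <= lat <= 84.0):
        raise ValueError(f"latitude {lat} outside UTM validity")
    if zone_number is None:
        zone_number = int((lon + 180) // 6) + 1
        zone_number = min(max(zone_number, 1), 60)
    phi = math.radians(lat)
    lam = math.radians(lon) - _central_meridian(zone_number)
    sin_phi, cos_phi, tan_phi = math.sin(phi), math.cos(phi), math.tan(phi)

    n = _A / math.sqrt(1 - _E2 * sin_phi**2)
    t = tan_phi**2
    c = _EP2 * cos_phi**2
    a = cos_phi * lam
    m = _A * (
        _M0 * phi
        - (3 * _E2 / 8 + 3 * _E4 / 32 + 45 * _E6 / 1024) * math.sin(2 * phi)
        + (15 * _E4 / 256 + 45 * _E6 / 1024) * math.sin(4 * phi)
        - (35 * _E6 / 3072) * math.sin(6 * phi)
    )
    easting = _K0 * n * (
        a + (1 - t + c) * a**3 / 6
        + (5 - 18 * t + t**2 + 72 * c - 58 * _EP2) * a**5 / 120
    ) + 500000.0
    northing = _K0 * (
        m + n * tan_phi * (
            a**2 / 2 + (5 - t + 9 * c + 4 * c**2) * a**4 / 24
            + (61 - 58 * t + t**2 + 600 * c - 330 * _EP2) * a**6 / 720
        )
    )
    if lat < 0:
        northing += 10000000.0
    return easting, northing, zone_number


def utm_to_latlon(easting: float, northing: float, zone_number: int,
                  northern: bool = True) -> tuple[float, float]:
    """Inverse projection; returns (lat, lon) in decimal degrees."""
    if not 1 <= zone_number <= 60:
        raise ValueError(f"UTM zone number {zone_number} out of 1..60")
    x = easting - 500000.0
    y = northing if northern else northing - 10000000.0

    m = y / _K0
    mu = m / (_A * _M0)
    e1 = (1 - math.sqrt(1 - _E2)) / (1 + math.sqrt(1 - _E2))
    phi1 = mu + (
        (3 * e1 / 2 - 27 * e1**3 / 32) * math.sin(2 * mu)
        + (21 * e1**2 / 16 - 55 * e1**4 / 32) * math.sin(4 * mu)
        + (151 * e1**3 / 96) * math.sin(6 * mu)
        + (1097 * e1**4 / 512) * math.sin(8 * mu)
    )
    sin1, cos1, tan1 = math.sin(phi1), math.cos(phi1), math.tan(phi1)
    c1 = _EP2 * cos1**2
    t1 = tan1**2
    n1 = _A / math.sqrt(1 - _E2 * sin1**2)
    r1 = _A * (1 - _E2) / (1 - _E2 * sin1**2) ** 1.5
    d = x / (n1 * _K0)

    phi = phi1 - (n1 * tan1 / r1) * (
        d**2 / 2
        - (5 + 3 * t1 + 10 * c1 - 4 * c1**2 - 9 * _EP2) * d**4 / 24
        + (61 + 90 * t1 + 298 * c1 + 45 * t1**2 - 252 * _EP2 - 3 * c1**2)
        * d**6 / 720
    )
    lam = (
        d - (1 + 2 * t1 + c1) * d**3 / 6
        + (5 - 2 * c1 + 28 * t1 - 3 * c1**2 + 8 * _EP2 + 24 * t1**2)
        * d**5 / 120
    ) / cos1
    lat = math.degrees(phi)
    lon = math.degrees(_central_meridian(zone_number) + lam)
    return lat, lon
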