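"""Sun and moon positions, phases, and nightly rise/set events.

Implements a self-contained geocentric ephemeris from the standard
low-precision solar theory and a truncated lunar periodic-term series
(Meeus, *Astronomical Algorithms*, chs. 25 and 47).  Accuracy is well
inside the contract used by the light simulator: zenith angles to
better than 0.2 degrees and rise/set events to a minute or two, over
roughly 1950-2050.

All public functions take and return UTC.  Internally times are Julian
Dates; dynamical time is obtained with a slowly varying Delta-T model.
A "night" is keyed by the *local solar date* of its sunset, where local
solar time is UTC + longitude / 15 h, so that days-from-full-moon is a
well defined per-night integer without civil timezone tables.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GeoTime",
    "SkyGeometry",
    "NightEvents",
    "sky_geometry",
    "night_events",
    "full_moon_instants",
    "local_night_date",
    "days_from_full_moon",
    "sun_altitude",
    "moon_topocentric_altitude",
    "moon_phase_angle",
]

_J2000 = 2451545.0
_AU_KM = 1.495978707e8
_DEG = np.pi / 180.0

# Rise/set horizon conventions (geometric altitude of the body centre, deg).
SUN_RISESET_ALTITUDE = -0.8333  # refraction 34' + semi-diameter 16'
_MOON_REFRACTION = 0.5667       # refraction + semi-diameter, deg; parallax handled explicitly


# ---------------------------------------------------------------------------
# time scales

def to_jd(t) -> np.ndarray | float:
    """UTC datetime / ISO string / numpy datetime64 -> Julian Date (UTC)."""
    if isinstance(t, (float, int, np.floating)):
        return float(t)
    arr = np.asarray(t, dtype="datetime64[s]")
    jd = arr.astype("int64") / 86400.0 + 2440587.5
    return float(jd) if jd.ndim == 0 else jd


def from_jd(jd) -> np.ndarray:
    """Julian Date (UTC) -> numpy datetime64[s]."""
    jd = np.asarray(jd, dtype=float)
    secs = np.round((jd - 2440587.5) * 86400.0).astype("int64")
    return secs.astype("datetime64[s]")


def _delta_t_seconds(jd) -> np.ndarray:
    # Smooth fit adequate for 1950-2050 (~69 s in 2020).
    y = 2000.0 + (np.asarray(jd, dtype=float) - _J2000) / 365.25
    t = y - 2000.0
    return 63.86 + 0.3345 * t - 0.060374 * t**2 / 10 + 0.005589 * t**2


def _jd_tt(jd_utc):
    return np.asarray(jd_utc, dtype=float) + _delta_t_seconds(jd_utc) / 86400.0


# ---------------------------------------------------------------------------
# solar position (low precision theory, ~0.01 deg)

def _sun_ecliptic(jd_tt):
    T = (jd_tt - _J2000) / 36525.0
    L0 = 280.46646 + 36000.76983 * T + 0.0003032 * T**2
    M = 357.52911 + 35999.05029 * T - 0.0001537 * T**2
    Mr = np.radians(M)
    C = ((1.914602 - 0.004817 * T - 0.000014 * T**2) * np.sin(Mr)
         + (0.019993 - 0.000101 * T) * np.sin(2 * Mr)
         + 0.000289 * np.sin(3 * Mr))
    true_lon = L0 + C
    nu = np.radians(M + C)
    e = 0.016708634 - 0.000042037 * T
    R = 1.000001018 * (1 - e**2) / (1 + e * np.cos(nu))  # AU
    omega = np.radians(125.04 - 1934.136 * T)
    app_lon = true_lon - 0.00569 - 0.00478 * np.sin(omega)
    return np.mod(app_lon, 360.0), R, T, omega


def _obliquity(T, omega):
    eps0 = 23.439291111 - 0.013004167 * T - 1.639e-7 * T**2
    return np.radians(eps0 + 0.00256 * np.cos(omega))


def sun_radec(jd_utc):
    """Apparent geocentric right ascension / declination (radians) and distance (AU)."""
    jd_tt = _jd_tt(jd_utc)
    lon, R, T, omega = _sun_ecliptic(jd_tt)
    eps = _obliquity(T, omega)
    lr = np.radians(lon)
    ra = np.arctan2(np.cos(eps) * np.sin(lr), np.cos(lr))
    dec = np.arcsin(np.sin(eps) * np.sin(lr))
    return ra, dec, R, lon


# ---------------------------------------------------------------------------
# lunar position (truncated periodic series; ~0.01-0.03 deg)

# (D, M, M', F, coeff) for longitude (1e-6 deg) and distance (1e-3 km)
_LUNAR_LR = [
    (0, 0, 1, 0, 6288774, -20905355),
    (2, 0, -1, 0, 1274027, -3699111),
    (2, 0, 0, 0, 658314, -2955968),
    (0, 0, 2, 0, 213618, -569925),
    (0, 1, 0, 0, -185116, 48888),
    (0, 0, 0, 2, -114332, -3149),
    (2, 0, -2, 0, 58793, 246158),
    (2, -1, -1, 0, 57066, -152138),
    (2, 0, 1, 0, 53322, -170733),
    (2, -1, 0, 0, 45758, -204586),
    (0, 1, -1, 0, -40923, -129620),
    (1, 0, 0, 0, -34720, 108743),
    (0, 1, 1, 0, -30383, 104755),
    (2, 0, 0, -2, 15327, 10321),
    (0, 0, 1, 2, -12528, 0),
    (0, 0, 1, -2, 10980, 79661),
    (4, 0, -1, 0, 10675, -34782),
    (0, 0, 3, 0, 10034, -23210),
    (4, 0, -2, 0, 8548, -21636),
    (2, 1, -1, 0, -7888, 24208),
    (2, 1, 0, 0, -6766, 30824),
    (1, 0, -1, 0, -5163, -8379),
    (1, 1, 0, 0, 4987, -16675),
    (2, -1, 1, 0, 4036, -12831),
    (2, 0, 2, 0, 3994, -10445),
    (4, 0, 0, 0, 3861, -11650),
    (2, 0, -3, 0, 3665, 14403),
    (0, 1, -2, 0, -2689, -7003),
    (2, 0, -1, 2, -2602, 0),
    (2, -1, -2, 0, 2390, 10056),
    (1, 0, 1, 0, -2348, 6322),
    (2, -2, 0, 0, 2236, -9884),
]

# (D, M, M', F, coeff) for latitude (1e-6 deg)
_LUNAR_B = [
    (0, 0, 0, 1, 5128122),
    (0, 0, 1, 1, 280602),
    (0, 0, 1, -1, 277693),
    (2, 0, 0, -1, 173237),
    (2, 0, -1, 1, 55413),
    (2, 0, -1, -1, 46271),
    (2, 0, 0, 1, 32573),
    (0, 0, 2, 1, 17198),
    (2, 0, 1, -1, 9266),
    (0, 0, 2, -1, 8822),
    (2, -1, 0, -1, 8216),
    (2, 0, -2, -1, 4324),
    (2, 0, 1, 1, 4200),
    (2, 1, 0, -1, -3359),
    (2, -1, -1, 1, 2463),
    (2, -1, 0, 1, 2211),
    (2, -1, -1, -1, 2065),
    (0, 1, -1, -1, -1870),
    (4, 0, -1, -1, 1828),
    (0, 1, 0, 1, -1794),
    (0, 0, 0, 3, -1749),
    (0, 1, -1, 1, -1565),
    (1, 0, 0, 1, -1491),
    (0, 1, 1, 1, -1475),
    (0, 1, 1, -1, -1410),
    (0, 1, 0, -1, -1344),
    (1, 0, 0, -1, -1335),
    (0, 0, 3, 1, 1107),
    (4, 0, 0, -1, 1021),
    (4, 0, -1, 1, 833),
]


def moon_eclgeo(jd_utc):
    """Geocentric ecliptic longitude/latitude (deg) and distance (km)."""
    jd_tt = _jd_tt(jd_utc)
    T = (jd_tt - _J2000) / 36525.0
    Lp = 218.3164477 + 481267.88123421 * T - 0.0015786 * T**2 + T**3 / 538841.0
    D = 297.8501921 + 445267.1114034 * T - 0.0018819 * T**2 + T**3 / 545868.0
    M = 357.5291092 + 35999.0502909 * T - 0.0001536 * T**2
    Mp = 134.9633964 + 477198.8675055 * T + 0.0087414 * T**2 + T**3 / 69699.0
    F = 93.2720950 + 483202.0175233 * T - 0.0036539 * T**2 - T**3 / 3526000.0
    A1 = 119.75 + 131.849 * T
    A2 = 53.09 + 479264.290 * T
    A3 = 313.45 + 481266.484 * T
    E = 1 - 0.002516 * T - 0.0000074 * T**2

    Dr, Mr, Mpr, Fr = (np.radians(x) for x in (D, M, Mp, F))
    sl = np.zeros_like(np.asarray(jd_tt, dtype=float))
    sr = np.zeros_like(sl)
    for d, m, mp, f, cl, cr in _LUNAR_LR:
        arg = d * Dr + m * Mr + mp * Mpr + f * Fr
        ecc = E ** abs(m)
        sl = sl + cl * ecc * np.sin(arg)
        sr = sr + cr * ecc * np.cos(arg)
    sl = sl + 3958 * np.sin(np.radians(A1)) + 1962 * np.sin(np.radians(Lp - F)) \
        + 318 * np.sin(np.radians(A2))

    sb = np.zeros_like(sl)
    for d, m, mp, f, cb in _LUNAR_B:
        arg = d * Dr + m * Mr + mp * Mpr + f * Fr
        sb = sb + cb * (E ** abs(m)) * np.sin(arg)
    sb = sb - 2235 * np.sin(np.radians(Lp)) + 382 * np.sin(np.radians(A3)) \
        + 175 * np.sin(np.radians(A1 - F)) + 175 * np.sin(np.radians(A1 + F)) \
        + 127 * np.sin(np.radians(Lp - Mp)) - 115 * np.sin(np.radians(Lp + Mp))

    lon = np.mod(Lp + sl * 1e-6, 360.0)
    lat = sb * 1e-6
    dist = 385000.56 + sr * 1e-3
    return lon, lat, dist


def moon_radec(jd_utc):
    """Apparent geocentric RA/Dec (radians) and distance (km)."""
    lon, lat, dist = moon_eclgeo(jd_utc)
    jd_tt = _jd_tt(jd_utc)
    T = (jd_tt - _J2000) / 36525.0
    omega = np.radians(125.04 - 1934.136 * T)
    eps = _obliquity(T, omega)
    lr, br = np.radians(lon), np.radians(lat)
    ra = np.arctan2(np.sin(lr) * np.cos(eps) - np.tan(br) * np.sin(eps), np.cos(lr))
    dec = np.arcsin(np.sin(br) * np.cos(eps) + np.cos(br) * np.sin(eps) * np.sin(lr))
    return ra, dec, dist


def _gmst_rad(jd_utc):
    jd = np.asarray(jd_utc, dtype=float)
    T = (jd - _J2000) / 36525.0
    gmst = (280.46061837 + 360.98564736629 * (jd - _J2000)
            + 0.000387933 * T**2 - T**3 / 38710000.0)
    return np.radians(np.mod(gmst, 360.0))


def _altitude(ra, dec, jd_utc, lat_deg, lon_deg):
    H = _gmst_rad(jd_utc) + np.radians(lon_deg) - ra
    phi = np.radians(lat_deg)
    sin_h = np.sin(phi) * np.sin(dec) + np.cos(phi) * np.cos(dec) * np.cos(H)
    return np.degrees(np.arcsin(np.clip(sin_h, -1, 1)))


def sun_altitude(jd_utc, lat_deg, lon_deg):
    """Geometric (unrefracted) solar altitude in degrees."""
    ra, dec, _, _ = sun_radec(jd_utc)
    return _altitude(ra, dec, jd_utc, lat_deg, lon_deg)


def moon_topocentric_altitude(jd_utc, lat_deg, lon_deg):
    """Topocentric lunar altitude in degrees (geocentric minus parallax-in-altitude)."""
    ra, dec, dist = moon_radec(jd_utc)
    h = _altitude(ra, dec, jd_utc, lat_deg, lon_deg)
    parallax = np.degrees(np.arcsin(6378.14 / dist))
    return h - parallax * np.cos(np.radians(h))


def moon_parallax_deg(jd_utc):
    _, _, dist = moon_radec(jd_utc)
    return np.degrees(np.arcsin(6378.14 / dist))


def moon_phase_angle(jd_utc):
    """Phase angle in degrees (0 = full moon) and illuminated fraction."""
    ra_s, dec_s, R, _ = sun_radec(jd_utc)
    ra_m, dec_m, dist = moon_radec(jd_utc)
    cos_psi = (np.sin(dec_s) * np.sin(dec_m)
               + np.cos(dec_s) * np.cos(dec_m) * np.cos(ra_s - ra_m))
    psi = np.arccos(np.clip(cos_psi, -1, 1))
    R_km = R * _AU_KM
    # i is the sun-moon-earth angle: ~0 at opposition (full), ~180 at conjunction (new)
    i = np.arctan2(R_km * np.sin(psi), dist - R_km * np.cos(psi))
    phase = np.degrees(i)
    frac = (1 + np.cos(i)) / 2.0
    return phase, frac


# ---------------------------------------------------------------------------
# public types

@dataclass(frozen=True)
class GeoTime:
    """A site (WGS84 decimal degrees) and a UTC instant."""
    latitude: float
    longitude: float
    instant: _dt.datetime | str | np.datetime64

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")

    @property
    def jd(self) -> float:
        return float(to_jd(self.instant))


@dataclass(frozen=True)
class SkyGeometry:
    """Solar/lunar geometry at one instant.

    ``lunar_phase_angle`` is 0 at full moon and 180 at new moon;
    ``illuminated_fraction`` equals (1 + cos(phase_angle)) / 2.
    """
    solar_zenith: float
    solar_altitude: float
    lunar_zenith: float
    lunar_phase_angle: float
    illuminated_fraction: float


@dataclass(frozen=True)
class NightEvents:
    """Rise/set and twilight events for one local night (all UTC, numpy datetime64[s]).

    Events that do not occur (polar day/night, no moonrise that night) are None.
    Dusk events belong to the evening of `night_date`; dawn events to the
    following morning.
    """
    night_date: _dt.date
    sunset: Optional[np.datetime64]
    sunrise: Optional[np.datetime64]
    civil_dusk: Optional[np.datetime64]
    nautical_dusk: Optional[np.datetime64]
    astronomical_dusk: Optional[np.datetime64]
    civil_dawn: Optional[np.datetime64]
    nautical_dawn: Optional[np.datetime64]
    astronomical_dawn: Optional[np.datetime64]
    moonrise: Optional[np.datetime64]
    moonset: Optional[np.datetime64]


def sky_geometry(gt: GeoTime) -> SkyGeometry:
    """Solar and lunar zenith angles, lunar phase angle and illuminated fraction."""
    jd = gt.jd
    alt_s = float(sun_altitude(jd, gt.latitude, gt.longitude))
    alt_m = float(moon_topocentric_altitude(jd, gt.latitude, gt.longitude))
    phase, frac = moon_phase_angle(jd)
    return SkyGeometry(
        solar_zenith=90.0 - alt_s,
        solar_altitude=alt_s,
        lunar_zenith=90.0 - alt_m,
        lunar_phase_angle=float(phase),
        illuminated_fraction=float(frac),
    )


# ---------------------------------------------------------------------------
# event finding

def _refine_crossing(f, jd_lo, jd_hi, iters=30):
    lo, hi = jd_lo, jd_hi
    flo = f(lo)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if (flo < 0) == (fm < 0):
            lo, flo = mid, fm
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _crossings(f_vec, jd_grid, direction):
    """Times where a sampled function crosses zero (direction=-1 falling, +1 rising)."""
    v = f_vec
    out = []
    for k in range(len(jd_grid) - 1):
        if direction < 0 and v[k] >= 0 > v[k + 1]:
            out.append((jd_grid[k], jd_grid[k + 1]))
        elif direction > 0 and v[k] < 0 <= v[k + 1]:
            out.append((jd_grid[k], jd_grid[k + 1]))
    return out


def night_events(latitude: float, longitude: float, night_date) -> NightEvents:
    """Sun/moon events for the night whose sunset falls on `night_date` (local solar date).

    The search window runs from local solar noon of `night_date` to local
    solar noon of the next day.  Sun rise/set uses a -0.8333 deg horizon;
    the moon uses refraction + semi-diameter + horizontal parallax
    (0.7275*parallax - 0.5667 deg geocentric altitude).
    """
    if isinstance(night_date, str):
        night_date = _dt.date.fromisoformat(night_date)
    # local solar noon in UTC
    noon_utc = (np.datetime64(night_date.isoformat()).astype("datetime64[s]")
                + np.timedelta64(int(round((12.0 - longitude / 15.0) * 3600)), "s"))
    jd0 = float(to_jd(noon_utc))
    jd_grid = jd0 + np.arange(0, 24 * 60 + 1, 4) / (24.0 * 60.0)  # 4-min sampling

    alt_sun = sun_altitude(jd_grid, latitude, longitude)
    alt_moon = moon_topocentric_altitude(jd_grid, latitude, longitude)
    par = moon_parallax_deg(jd_grid)
    # horizon offsets already folded into topocentric altitude except refraction+semidiam:
    h0_moon = -(_MOON_REFRACTION - 0.0)  # topocentric altitude threshold
    moon_f = alt_moon - h0_moon

    def first(pairs, f):
        if not pairs:
            return None
        lo, hi = pairs[0]
        jd = _refine_crossing(f, lo, hi)
        return from_jd(jd)

    f_sun = lambda jd: sun_altitude(jd, latitude, longitude) - SUN_RISESET_ALTITUDE
    f_moon = lambda jd: (moon_topocentric_altitude(jd, latitude, longitude) - h0_moon)

    sunset = first(_crossings(alt_sun - SUN_RISESET_ALTITUDE, jd_grid, -1), f_sun)
    sunrise = first(_crossings(alt_sun - SUN_RISESET_ALTITUDE, jd_grid, +1), f_sun)

    def dusk_dawn(thresh):
        f = lambda jd: sun_altitude(jd, latitude, longitude) - thresh
        d1 = first(_crossings(alt_sun - thresh, jd_grid, -1), f)
        d2 = first(_crossings(alt_sun - thresh, jd_grid, +1), f)
        return d1, d2

    cdusk, cdawn = dusk_dawn(-6.0)
    ndusk, ndawn = dusk_dawn(-12.0)
    adusk, adawn = dusk_dawn(-18.0)
    moonrise = first(_crossings(moon_f, jd_grid, +1), f_moon)
    moonset = first(_crossings(moon_f, jd_grid, -1), f_moon)

    return NightEvents(
        night_date=night_date, sunset=sunset, sunrise=sunrise,
        civil_dusk=cdusk, nautical_dusk=ndusk, astronomical_dusk=adusk,
        civil_dawn=cdawn, nautical_dawn=ndawn, astronomical_dawn=adawn,
        moonrise=moonrise, moonset=moonset,
    )


# ---------------------------------------------------------------------------
# lunar phases and days-from-full-moon

def full_moon_instants(year: int) -> list:
    """UTC instants (numpy datetime64[s]) of every full moon in `year`.

    Full moon is the almanac convention: geocentric apparent ecliptic
    longitudes of moon and sun in opposition (excess longitude = 180 deg).
    """
    jd_a = float(to_jd(np.datetime64(f"{year - 1}-12-29")))
    jd_b = float(to_jd(np.datetime64(f"{year + 1}-01-03")))
    grid = np.arange(jd_a, jd_b, 0.25)
    _, _, _, lon_s = sun_radec(grid)
    lon_m, _, _ = moon_eclgeo(grid)
    f = np.mod(lon_m - lon_s - 180.0 + 180.0, 360.0) - 180.0  # wrapped excess

    def ffun(jd):
        _, _, _, ls = sun_radec(jd)
        lm, _, _ = moon_eclgeo(jd)
        return float(np.mod(lm - ls - 180.0 + 180.0, 360.0) - 180.0)

    out = []
    for lo, hi in _crossings(f, grid, +1):
        jd = _refine_crossing(ffun, lo, hi)
        t = from_jd(jd)
        if np.datetime64(f"{year}-01-01") <= t < np.datetime64(f"{year + 1}-01-01"):
            out.append(t)
    return out


def local_night_date(longitude: float, instant) -> _dt.date:
    """Local solar date of the *night* containing `instant`.

    Instants before local solar noon belong to the previous night.
    """
    jd = float(to_jd(instant))
    local = jd + longitude / 360.0
    # JD local noon boundary: local JD has .0 at noon, so floor at noon boundaries
    day = int(np.floor(local + 0.0))  # JD x.0 == noon
    t = from_jd(day - longitude / 360.0)
    d = t.astype("datetime64[D]").astype(_dt.date)
    return d


def days_from_full_moon(longitude: float, night_date, full_moons: Sequence) -> int:
    """Signed whole nights between `night_date` and the nearest full-moon night.

    Negative before full moon.  Ties (+/-15 nights to two different full
    moons) break toward the earlier full moon.
    """
    if isinstance(night_date, str):
        night_date = _dt.date.fromisoformat(night_date)
    fm_dates = [local_night_date(longitude, t) for t in full_moons]
    best = None
    for fmd in fm_dates:
        d = (night_date - fmd).days
        if best is None or abs(d) < abs(best) or (abs(d) == abs(best) and d > best):
            best = d
    if best is None:
        raise ValueError("no full-moon instants supplied")
    return best
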