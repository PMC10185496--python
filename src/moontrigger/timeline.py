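"""Nightly 5-minute light timelines and the spawning-trigger detector.

A `LightTimeline` holds broadband (400-700 nm) irradiance at the sea
surface in uW m^-2, resolved into solar, twilight, lunar, ALAN and
dark-floor components on a fixed 5-minute step, together with per-night
sun/moon events.

The detector finds "extended periods of minimum light intensity": maximal
runs of steps whose total irradiance stays within (1 + tolerance) x the
night's own minimum, lasting at least `min_duration` minutes.  On an
unlit night such a period can only exist once the sky has reached the
dark floor and before the waning moon has risen appreciably, so it ends
at moonrise for all practical purposes.  Under ALAN the minimum is the
ALAN level itself; the period begins as soon as twilight decays below
the tolerance band and persists until *moonlight* outgrows the band —
artificial light masks both the late-twilight decline and the first
hours of low-altitude moonlight, which is what advances the trigger
night after full moon.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from . import ephemeris as eph
from . import spectra as sp

__all__ = [
    "NightWindow",
    "LightTimeline",
    "MinimumPeriod",
    "TriggerResult",
    "build_timeline",
    "detect_minimum_periods",
    "first_trigger_night",
    "DEFAULT_ALAN_UW",
    "default_alan_config",
]

STEP_MINUTES = 5

#: Default broadband ALAN scenario for the two demonstration reefs, uW m^-2.
#: The source atlas's *maximum* sea-surface irradiances near developed coasts
#: are of order 1e-2 W m^-2 (a few times full-moon irradiance); that magnitude
#: is required for ALAN to mask both late twilight and low-altitude moonlight,
#: the mechanism that advances the trigger night.
DEFAULT_ALAN_UW = 1.0e4


def default_alan_config(total_uW: float = DEFAULT_ALAN_UW) -> sp.AlanConfig:
    """Default demonstration scenario: equal-thirds RGB bands, lights on at sunset.

    Switching at sunset (rather than civil dusk) keeps the lit series
    monotone into its nighttime plateau; a switch-on near civil dusk at
    ALAN levels comparable to civil-twilight irradiance leaves a brief
    pre-switch-on dip below the plateau that a minimum-relative detector
    would treat as the night's minimum.
    """
    third = total_uW / 3.0
    return sp.AlanConfig(lamp_class="rgb_bands", blue_uW=third, green_uW=third,
                         red_uW=third, on_event="sunset", off_event="sunrise")


@dataclass(frozen=True)
class NightWindow:
    """One local night inside a timeline: events plus step-index bounds."""
    night_date: _dt.date
    events: Optional[eph.NightEvents]
    i_start: int   # first step at/after sunset
    i_end: int     # last step at/before sunrise (inclusive)


@dataclass
class LightTimeline:
    """5-minute broadband irradiance series for one site (all uW m^-2)."""
    latitude: float
    longitude: float
    times: np.ndarray          # datetime64[s]
    solar: np.ndarray
    twilight: np.ndarray
    lunar: np.ndarray
    alan: np.ndarray
    floor: np.ndarray
    nights: List[NightWindow]

    @property
    def total(self) -> np.ndarray:
        return self.solar + self.twilight + self.lunar + self.alan + self.floor

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "utc": self.times, "solar": self.solar, "twilight": self.twilight,
            "lunar": self.lunar, "alan": self.alan, "floor": self.floor,
            "total": self.total,
        })


@dataclass(frozen=True)
class MinimumPeriod:
    night_date: _dt.date
    start: np.datetime64
    end: np.datetime64
    duration_min: float
    level_uW: float


@dataclass(frozen=True)
class TriggerResult:
    """First post-full-moon night with an extended minimum period, lit vs natural."""
    full_moon_night: _dt.date
    first_trigger_night_natural: Optional[int]
    first_trigger_night_lit: Optional[int]

    @property
    def advance_days(self) -> Optional[int]:
        if (self.first_trigger_night_natural is None
                or self.first_trigger_night_lit is None):
            return None
        return self.first_trigger_night_natural - self.first_trigger_night_lit


# ---------------------------------------------------------------------------

def _night_dates(start, end) -> List[_dt.date]:
    if isinstance(start, str):
        start = _dt.date.fromisoformat(start)
    if isinstance(end, str):
        end = _dt.date.fromisoformat(end)
    n = (end - start).days
    if n < 0:
        raise ValueError("end before start")
    return [start + _dt.timedelta(days=k) for k in range(n + 1)]


def build_timeline(latitude: float, longitude: float, start, end,
                   alan: Optional[sp.AlanConfig] = None,
                   atm: Optional[sp.AtmosphereParams] = None,
                   grid: Optional[sp.SpectralGrid] = None) -> LightTimeline:
    """Compose the broadband surface light field for local nights `start`..`end`.

    `start` and `end` are local night dates (the night keyed by its
    sunset).  The series covers local noon of `start` through local noon
    after `end` at exactly 5-minute steps.  With `alan=None` the
    nighttime minima sit on the dark-sky floor.
    """
    atm = atm or sp.AtmosphereParams.defaults()
    grid = grid or sp.SpectralGrid()
    dates = _night_dates(start, end)

    noon0 = (np.datetime64(dates[0].isoformat()).astype("datetime64[s]")
             + np.timedelta64(int(round((12.0 - longitude / 15.0) * 3600)), "s"))
    n_steps = (len(dates)) * (24 * 60 // STEP_MINUTES) + 1
    times = noon0 + np.arange(n_steps) * np.timedelta64(STEP_MINUTES * 60, "s")
    jd = eph.to_jd(times)

    sun_alt = eph.sun_altitude(jd, latitude, longitude)
    moon_alt = eph.moon_topocentric_altitude(jd, latitude, longitude)
    phase, _ = eph.moon_phase_angle(jd)

    # orbital-eccentricity multiplier per step
    doy = np.array([int(t.astype("datetime64[D]").astype(object).timetuple().tm_yday)
                    for t in times])
    ecc_mult = (1 + 0.0167 * np.cos(2 * np.pi * (doy - 3) / 365.0)) ** 2

    h0 = sp.SolarTOAConfig(day_of_year=1, grid=grid).h0_values
    lam = grid.wavelengths
    lunar_cfg = sp.LunarConfig(grid=grid)
    dil = np.sin(np.radians(lunar_cfg.semi_diameter_deg)) ** 2
    s_moon = h0 * lunar_cfg.albedo_values * dil  # TOA lunar shape before ecc/phase

    solar = np.zeros(n_steps)
    lunar = np.zeros(n_steps)

    def _surface_bb(theta_deg, source_vals, out, mask):
        # chunked (steps, wavelengths) transmittance integration
        idx = np.flatnonzero(mask)
        for c in range(0, len(idx), 4000):
            ii = idx[c:c + 4000]
            t_dir, t_dif = sp._gc_transmittances(grid, theta_deg[ii], atm)
            out[ii] = np.trapezoid(source_vals * (t_dir + t_dif), lam, axis=-1)

    day = sun_alt > 0
    _surface_bb(np.minimum(90.0 - sun_alt, sp.TWILIGHT_ANCHOR_ZENITH), h0, solar, day)
    solar *= ecc_mult * 1e6  # -> uW

    moon_up = moon_alt > 0
    _surface_bb(90.0 - moon_alt, s_moon, lunar, moon_up)
    lunar *= ecc_mult * sp.allen_phase_factor(phase) * 1e6

    # twilight surrogate: log-linear decay from the horizon anchor to the floor
    anchor_base = 0.0
    t_dir, t_dif = sp._gc_transmittances(grid, sp.TWILIGHT_ANCHOR_ZENITH, atm)
    anchor_base = float(np.trapezoid(h0 * (t_dir + t_dif), lam)) * 1e6  # uW at ecc=1
    floor_uW = sp.dark_sky_floor(grid).broadband_uW()
    twilight = np.zeros(n_steps)
    tw = (sun_alt < 0) & (sun_alt >= -18.0)
    depr = -sun_alt[tw]
    anchor = anchor_base * ecc_mult[tw]
    twilight[tw] = 10 ** (np.log10(anchor) * (1 - depr / 18.0)
                          + np.log10(floor_uW) * (depr / 18.0))

    # nights and events
    nights: List[NightWindow] = []
    for d in dates:
        ev = eph.night_events(latitude, longitude, d)
        if ev.sunset is None or ev.sunrise is None:
            nights.append(NightWindow(d, ev, 0, -1))
            continue
        i0 = int(np.searchsorted(times, ev.sunset, side="left"))
        i1 = int(np.searchsorted(times, ev.sunrise, side="right")) - 1
        nights.append(NightWindow(d, ev, i0, min(i1, n_steps - 1)))

    # ALAN schedule: on at the configured dusk event, off at the dawn event
    alan_arr = np.zeros(n_steps)
    if alan is not None:
        level = sp.alan_spectrum(alan, grid).broadband_uW()
        for nw in nights:
            if nw.events is None:
                continue
            on = getattr(nw.events, alan.on_event, None)
            off = getattr(nw.events, alan.off_event, None)
            if on is None or off is None:
                continue
            alan_arr[(times >= on) & (times <= off)] = level

    floor_arr = np.full(n_steps, floor_uW)
    return LightTimeline(latitude, longitude, times, solar, twilight, lunar,
                         alan_arr, floor_arr, nights)


# ---------------------------------------------------------------------------

def detect_minimum_periods(tl: LightTimeline, tolerance_rel: float = 0.05,
                           min_duration: float = 30.0) -> List[MinimumPeriod]:
    """Maximal runs of steps within (1+tolerance) x the nightly minimum.

    One run per contiguous stretch; only runs spanning at least
    `min_duration` minutes between a night's sunset and sunrise are
    reported.  The level reported is the night's minimum itself.
    """
    total = tl.total
    out: List[MinimumPeriod] = []
    for nw in tl.nights:
        if nw.i_end <= nw.i_start:
            continue
        seg = total[nw.i_start:nw.i_end + 1]
        m = float(seg.min())
        mask = seg <= (1.0 + tolerance_rel) * m
        k = 0
        while k < len(mask):
            if not mask[k]:
                k += 1
                continue
            j = k
            while j + 1 < len(mask) and mask[j + 1]:
                j += 1
            dur = (j - k) * STEP_MINUTES
            if dur >= min_duration:
                out.append(MinimumPeriod(
                    night_date=nw.night_date,
                    start=tl.times[nw.i_start + k],
                    end=tl.times[nw.i_start + j],
                    duration_min=float(dur),
                    level_uW=m,
                ))
            k = j + 1
    return out


def first_trigger_night(tl_natural: LightTimeline, tl_lit: LightTimeline,
                        full_moons: Sequence, tolerance_rel: float = 0.05,
                        min_duration: float = 30.0,
                        max_night: int = 14) -> TriggerResult:
    """First night (0..max_night after full moon) with a qualifying minimum period.

    Both timelines must cover the same nights; they normally differ only
    in the ALAN component.  `full_moons` are full-moon instants (UTC)
    bracketing the window, e.g. from :func:`ephemeris.full_moon_instants`.
    """
    lon = tl_natural.longitude

    def first_night(tl):
        periods = detect_minimum_periods(tl, tolerance_rel, min_duration)
        nights_with = {p.night_date for p in periods}
        best = None
        for nw in tl.nights:
            d = eph.days_from_full_moon(lon, nw.night_date, full_moons)
            if 0 <= d <= max_night and nw.night_date in nights_with:
                if best is None or d < best:
                    best = d
        return best

    # the full-moon night covered by the natural timeline
    fm_night = None
    for nw in tl_natural.nights:
        if eph.days_from_full_moon(lon, nw.night_date, full_moons) == 0:
            fm_night = nw.night_date
            break
    nat = first_night(tl_natural)
    lit = first_night(tl_lit)
    return TriggerResult(full_moon_night=fm_night,
                         first_trigger_night_natural=nat,
                         first_trigger_night_lit=lit)
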