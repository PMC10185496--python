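"""Spectral irradiance of every sea-surface light component.

Five components make up the nocturnal light field: direct + diffuse
sunlight (clear-sky marine atmosphere in the style of Gregg & Carder),
a parametric twilight surrogate for solar altitudes 0 to -18 deg, scaled
moonlight (TOA solar spectrum x spectral albedo x solid-angle dilution x
phase curve, passed through the same atmosphere), artificial light at
night (ALAN) in blue/green/red bands or lamp spectral shapes, and a flat
dark-sky floor equivalent to a 22 mag arcsec^-2 sky (~0.25 uW m^-2).

All spectra live on a common wavelength grid (default 400-700 nm at
1 nm) in W m^-2 nm^-1.  The reference tables shipped with the package
(TOA solar spectrum, lunar albedo) are smooth synthetic analogs of the
published lookup tables, normalized to realistic broadband values; both
are plain CSV and can be replaced by measured tables of the same shape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable, Optional

import numpy as np

__all__ = [
    "SpectralGrid",
    "SpectralIrradiance",
    "SolarTOAConfig",
    "AtmosphereParams",
    "LunarConfig",
    "AlanConfig",
    "toa_solar",
    "clear_sky_surface",
    "twilight_irradiance",
    "toa_lunar",
    "surface_lunar",
    "alan_spectrum",
    "mag_to_luminance",
    "luminance_to_irradiance",
    "dark_sky_floor",
    "DARK_SKY_MAG",
    "allen_phase_factor",
]

DARK_SKY_MAG = 22.0
_LUNAR_SEMIDIAMETER_DEG = 0.26
#: zenith angle used as the "sun on the horizon" anchor for the twilight surrogate;
#: the plane-parallel clear-sky model degenerates at exactly 90 deg.
TWILIGHT_ANCHOR_ZENITH = 89.5

_ALAN_BANDS = {  # printed bands blue 400-500 / green 495-560 / red 640-720 overlap at
    # 495-500 and exceed the grid at 720; supports are kept disjoint and clipped so each
    # configured band integral is reproduced exactly.
    "blue": (400.0, 494.0),
    "green": (501.0, 560.0),
    "red": (640.0, 700.0),
}


def _load_csv(name: str):
    with resources.files("moontrigger.data").joinpath(name).open() as f:
        rows = np.loadtxt(f, delimiter=",", skiprows=1)
    return rows[:, 0], rows[:, 1]


def _load_atm_defaults() -> dict:
    with resources.files("moontrigger.data").joinpath("atmosphere_defaults.json").open() as f:
        return json.load(f)


@dataclass(frozen=True)
class SpectralGrid:
    """Strictly increasing wavelength grid in nm (default 400-700 at 1 nm)."""
    wavelengths: np.ndarray = field(default_factory=lambda: np.arange(400.0, 701.0, 1.0))

    def __post_init__(self):
        w = np.asarray(self.wavelengths, dtype=float)
        if w.ndim != 1 or len(w) < 2 or np.any(np.diff(w) <= 0):
            raise ValueError("wavelengths must be strictly increasing 1-D")
        if w[0] < 380.0 or w[-1] > 750.0:
            raise ValueError("grid must lie within 380-750 nm")
        object.__setattr__(self, "wavelengths", w)

    @property
    def span_nm(self) -> float:
        return float(self.wavelengths[-1] - self.wavelengths[0])


@dataclass(frozen=True)
class SpectralIrradiance:
    """Per-wavelength irradiance in W m^-2 nm^-1 with a component tag."""
    grid: SpectralGrid
    values: np.ndarray
    component: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.wavelengths.shape:
            raise ValueError("values shape must match grid")
        if np.any(v < 0):
            raise ValueError("spectral irradiance must be non-negative")
        object.__setattr__(self, "values", v)

    def broadband(self) -> float:
        """Trapezoid integral over the grid, W m^-2."""
        return float(np.trapezoid(self.values, self.grid.wavelengths))

    def broadband_uW(self) -> float:
        return self.broadband() * 1e6

    def __add__(self, other: "SpectralIrradiance") -> "SpectralIrradiance":
        if not np.array_equal(self.grid.wavelengths, other.grid.wavelengths):
            raise ValueError("grids differ")
        return SpectralIrradiance(self.grid, self.values + other.values, "total")


@dataclass(frozen=True)
class SolarTOAConfig:
    """Top-of-atmosphere solar spectrum H0 and orbital-eccentricity correction inputs."""
    day_of_year: int
    eccentricity: float = 0.0167
    grid: SpectralGrid = field(default_factory=SpectralGrid)
    h0_values: Optional[np.ndarray] = None  # W m^-2 nm^-1 on `grid`; default table if None

    def __post_init__(self):
        if not 1 <= self.day_of_year <= 366:
            raise ValueError("day_of_year must be 1..366")
        if self.h0_values is None:
            lam, h0 = _load_csv("toa_solar_synthetic.csv")
            vals = np.interp(self.grid.wavelengths, lam, h0)
            object.__setattr__(self, "h0_values", vals)
        else:
            v = np.asarray(self.h0_values, dtype=float)
            if v.shape != self.grid.wavelengths.shape:
                raise ValueError("h0_values shape must match grid")
            object.__setattr__(self, "h0_values", v)


@dataclass(frozen=True)
class AtmosphereParams:
    """Clear-sky marine atmosphere parameters (defaults from package data)."""
    aerosol_optical_thickness_550: float = 0.10
    angstrom_exponent: float = 1.0
    single_scattering_albedo: float = 0.97
    forward_scatter_fraction: float = 0.90
    ozone_atm_cm: float = 0.30
    water_vapor_cm: float = 2.5
    pressure_hPa: float = 1013.25
    relative_humidity: float = 0.80
    wind_speed_m_s: float = 5.0

    @classmethod
    def defaults(cls) -> "AtmosphereParams":
        return cls(**_load_atm_defaults())

    def __post_init__(self):
        for name in ("aerosol_optical_thickness_550", "ozone_atm_cm", "water_vapor_cm",
                     "pressure_hPa", "relative_humidity", "wind_speed_m_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def allen_phase_factor(phase_angle_deg) -> np.ndarray:
    """Analytic lunar phase curve, normalized to 1 at opposition.

    Brightness drop of 0.026 mag/deg plus a quartic term (Allen-style fit),
    which reproduces the steep "full-moon brightening": a quarter moon
    (g = 90 deg) is ~9% of full.
    """
    g = np.abs(np.asarray(phase_angle_deg, dtype=float))
    dm = 0.026 * g + 4e-9 * g**4
    return 10.0 ** (-0.4 * dm)


@dataclass(frozen=True)
class LunarConfig:
    """Spectral albedo, angular size, and phase curve of the moon."""
    semi_diameter_deg: float = _LUNAR_SEMIDIAMETER_DEG
    grid: SpectralGrid = field(default_factory=SpectralGrid)
    albedo_values: Optional[np.ndarray] = None
    phase_factor: Callable = allen_phase_factor

    def __post_init__(self):
        if self.albedo_values is None:
            lam, a = _load_csv("lunar_albedo_synthetic.csv")
            vals = np.interp(self.grid.wavelengths, lam, a)
            object.__setattr__(self, "albedo_values", vals)
        else:
            v = np.asarray(self.albedo_values, dtype=float)
            if v.shape != self.grid.wavelengths.shape:
                raise ValueError("albedo shape must match grid")
            if np.any(v <= 0) or np.any(v >= 1):
                raise ValueError("albedo must be in (0, 1)")
            object.__setattr__(self, "albedo_values", v)


@dataclass(frozen=True)
class AlanConfig:
    """Artificial-light source: either explicit RGB band irradiances or a lamp class.

    Band irradiances are broadband uW m^-2 integrated over each band.
    `schedule` names the NightEvents fields that switch the lights
    ("dusk" pairs with the matching dawn event).
    """
    lamp_class: str = "rgb_bands"           # rgb_bands | LED | HPS | LPS
    blue_uW: float = 0.0
    green_uW: float = 0.0
    red_uW: float = 0.0
    total_uW: Optional[float] = None        # for lamp classes: total broadband
    on_event: str = "civil_dusk"
    off_event: str = "civil_dawn"

    def __post_init__(self):
        if min(self.blue_uW, self.green_uW, self.red_uW) < 0:
            raise ValueError("band irradiances must be non-negative")
        if self.total_uW is not None and self.total_uW < 0:
            raise ValueError("total irradiance must be non-negative")
        if self.lamp_class not in ("rgb_bands", "LED", "HPS", "LPS"):
            raise ValueError(f"unknown lamp class {self.lamp_class!r}")


# ---------------------------------------------------------------------------
# solar chain

def toa_solar(cfg: SolarTOAConfig) -> SpectralIrradiance:
    """TOA solar spectrum corrected for orbital eccentricity.

    E0(lambda) = H0(lambda) * (1 + eps * cos(2*pi*(D - 3)/365))^2
    """
    mult = (1.0 + cfg.eccentricity
            * np.cos(2 * np.pi * (cfg.day_of_year - 3) / 365.0)) ** 2
    return SpectralIrradiance(cfg.grid, cfg.h0_values * mult, "solar_toa")


# coarse Chappuis-band ozone absorption (atm-cm)^-1
_OZ_NM = np.array([380, 400, 420, 440, 450, 480, 500, 520, 540, 560, 580, 600,
                   620, 640, 660, 680, 700, 720, 750], dtype=float)
_OZ_A = np.array([0.0, 0.0003, 0.0006, 0.0018, 0.003, 0.012, 0.033, 0.048, 0.075,
                  0.106, 0.120, 0.132, 0.122, 0.100, 0.078, 0.057, 0.040, 0.028,
                  0.014])


def _airmass(theta_z_deg):
    t = np.asarray(theta_z_deg, dtype=float)
    return 1.0 / (np.cos(np.radians(t)) + 0.50572 * (96.07995 - t) ** -1.6364)


def _gc_transmittances(grid: SpectralGrid, theta_z_deg, atm: AtmosphereParams):
    """Direct-beam and diffuse transmittance factors of the clear-sky marine model.

    Returns (t_direct, t_diffuse): multiply a TOA spectrum by these (they
    include the cos(theta_z) geometry) to get direct and diffuse surface
    components.  theta_z may be a scalar or an array (broadcast against
    wavelength on the last axis).
    """
    lam_um = grid.wavelengths / 1000.0
    theta = np.atleast_1d(np.asarray(theta_z_deg, dtype=float))[..., None]
    mu = np.cos(np.radians(theta))
    M = _airmass(theta)
    Mp = M * atm.pressure_hPa / 1013.25
    Moz = 1.0035 / np.sqrt(mu**2 + 0.007)

    tau_r = 1.0 / (115.6406 * lam_um**4 - 1.335 * lam_um**2)
    Tr = np.exp(-Mp * tau_r)
    a_oz = np.interp(grid.wavelengths, _OZ_NM, _OZ_A)
    Toz = np.exp(-a_oz * atm.ozone_atm_cm * Moz)
    tau_a = atm.aerosol_optical_thickness_550 * (lam_um / 0.55) ** (-atm.angstrom_exponent)
    Ta = np.exp(-tau_a * M)
    wa = atm.single_scattering_albedo
    Taa = np.exp(-(1 - wa) * tau_a * M)
    Tas = np.exp(-wa * tau_a * M)

    t_dir = mu * Tr * Ta * Toz
    t_dif = mu * Toz * Taa * ((1 - Tr**0.95) / 2.0
                              + Tr**1.5 * (1 - Tas) * atm.forward_scatter_fraction)
    if np.isscalar(theta_z_deg):
        return t_dir[0], t_dif[0]
    return t_dir, t_dif


def clear_sky_surface(toa: SpectralIrradiance, theta_z_deg: float,
                      atm: AtmosphereParams | None = None):
    """Direct (Edd) and diffuse (Eds) surface spectra for sun above the horizon.

    The total above-surface irradiance is their sum, Ed = Edd + Eds.
    """
    if not 0.0 <= theta_z_deg < 90.0:
        raise ValueError(
            "clear_sky_surface requires 0 <= zenith < 90 deg; "
            "use twilight_irradiance for a sun below the horizon")
    atm = atm or AtmosphereParams()
    t_dir, t_dif = _gc_transmittances(toa.grid, theta_z_deg, atm)
    edd = SpectralIrradiance(toa.grid, toa.values * t_dir, "solar_direct")
    eds = SpectralIrradiance(toa.grid, toa.values * t_dif, "solar_diffuse")
    return edd, eds


def twilight_partition(sun_altitude_deg: float) -> str:
    a = sun_altitude_deg
    if 0 > a >= -6:
        return "civil"
    if -6 > a >= -12:
        return "nautical"
    if -12 > a >= -18:
        return "astronomical"
    return "night" if a < -18 else "day"


def twilight_irradiance(sun_altitude_deg: float, toa: SpectralIrradiance,
                        atm: AtmosphereParams | None = None,
                        lut: Optional[Callable] = None) -> SpectralIrradiance:
    """Sky irradiance for solar altitudes in [-18, 0) deg.

    Parametric surrogate for the published rural-sky twilight lookup
    table: log10(broadband) declines linearly in solar depression from
    the clear-sky value with the sun on the horizon down to the dark-sky
    floor at -18 deg, with a mild blue shift of the spectral shape as
    depression grows.  A drop-in replacement LUT (callable mapping
    altitude -> broadband W m^-2) may be supplied.  Below -18 deg the
    dark-sky floor is returned, tagged "night".
    """
    atm = atm or AtmosphereParams()
    a = float(sun_altitude_deg)
    if a >= 0:
        raise ValueError("twilight requires sun below the horizon")
    if a < -18.0:
        floor = dark_sky_floor(toa.grid)
        return SpectralIrradiance(toa.grid, floor.values, "night")
    edd, eds = clear_sky_surface(toa, TWILIGHT_ANCHOR_ZENITH, atm)
    anchor = edd.broadband() + eds.broadband()
    floor_bb = 0.25e-6
    depression = -a
    if lut is not None:
        target = float(lut(a))
    else:
        target = 10 ** (np.log10(anchor) * (1 - depression / 18.0)
                        + np.log10(floor_bb) * (depression / 18.0))
    shape = (edd.values + eds.values) * (550.0 / toa.grid.wavelengths) ** (1.5 * depression / 18.0)
    shape = shape / np.trapezoid(shape, toa.grid.wavelengths)
    return SpectralIrradiance(toa.grid, shape * target, "twilight")


# ---------------------------------------------------------------------------
# lunar chain

def toa_lunar(cfg: SolarTOAConfig, lunar: LunarConfig, phase_angle_deg: float) -> SpectralIrradiance:
    """TOA lunar spectrum: solar spectrum x albedo x solid-angle dilution x phase curve.

    E_moon(lambda) = E0(lambda) * a(lambda) * sin^2(semi_diameter) * f(g).
    At full moon the broadband lunar/solar ratio is ~2.5e-6 (five to six
    orders of magnitude below the sun).
    """
    if not 0.0 <= phase_angle_deg <= 180.0:
        raise ValueError("phase angle must be in [0, 180] deg")
    sun = toa_solar(cfg)
    dilution = np.sin(np.radians(lunar.semi_diameter_deg)) ** 2
    pf = float(lunar.phase_factor(phase_angle_deg))
    vals = sun.values * lunar.albedo_values * dilution * pf
    return SpectralIrradiance(cfg.grid, vals, "lunar_toa")


def surface_lunar(toa_moon: SpectralIrradiance, lunar_zenith_deg: float,
                  atm: AtmosphereParams | None = None) -> SpectralIrradiance:
    """Surface lunar spectrum through the same clear-sky atmosphere.

    The transmittance model is source-agnostic, so the surface/TOA ratio
    equals the solar one at the same zenith angle.  Moon below the
    horizon yields zeros.
    """
    if lunar_zenith_deg >= 90.0:
        return SpectralIrradiance(toa_moon.grid, np.zeros_like(toa_moon.values), "lunar")
    atm = atm or AtmosphereParams()
    t_dir, t_dif = _gc_transmittances(toa_moon.grid, lunar_zenith_deg, atm)
    return SpectralIrradiance(toa_moon.grid, toa_moon.values * (t_dir + t_dif), "lunar")


# ---------------------------------------------------------------------------
# ALAN and the dark-sky floor

def _band_shape(grid: SpectralGrid, lo: float, hi: float) -> np.ndarray:
    lam = grid.wavelengths
    lo = max(lo, lam[0])
    hi = min(hi, lam[-1])
    shape = ((lam >= lo) & (lam <= hi)).astype(float)
    area = np.trapezoid(shape, lam)
    return shape / area if area > 0 else shape


def _lamp_shape(grid: SpectralGrid, lamp: str) -> np.ndarray:
    lam = grid.wavelengths
    if lamp == "LED":  # cool-white: blue pump + phosphor hump
        s = np.exp(-0.5 * ((lam - 450) / 12.0) ** 2) + 0.75 * np.exp(-0.5 * ((lam - 555) / 45.0) ** 2)
    elif lamp == "HPS":
        s = np.exp(-0.5 * ((lam - 569) / 4.0) ** 2) * 0.6 + np.exp(-0.5 * ((lam - 600) / 25.0) ** 2)
    elif lamp == "LPS":
        s = np.exp(-0.5 * ((lam - 589) / 2.5) ** 2)
    else:
        raise ValueError(f"unknown lamp class {lamp!r}")
    return s / np.trapezoid(s, lam)


def alan_spectrum(cfg: AlanConfig, grid: SpectralGrid | None = None) -> SpectralIrradiance:
    """Artificial-light spectrum scaled to the configured band/total irradiances."""
    grid = grid or SpectralGrid()
    lam = grid.wavelengths
    vals = np.zeros_like(lam)
    if cfg.lamp_class == "rgb_bands":
        for band, uw in (("blue", cfg.blue_uW), ("green", cfg.green_uW), ("red", cfg.red_uW)):
            lo, hi = _ALAN_BANDS[band]
            vals = vals + _band_shape(grid, lo, hi) * uw * 1e-6
    else:
        total = cfg.total_uW if cfg.total_uW is not None else (
            cfg.blue_uW + cfg.green_uW + cfg.red_uW)
        vals = _lamp_shape(grid, cfg.lamp_class) * total * 1e-6
    return SpectralIrradiance(grid, vals, "alan")


def mag_to_luminance(mag_arcsec2: float) -> float:
    """Sky surface brightness (mag arcsec^-2) -> luminance (cd m^-2).

    L = 10.8e4 * 10^(-0.4 m); 22 mag arcsec^-2 -> 1.712e-4 cd m^-2.
    """
    return 10.8e4 * 10 ** (-0.4 * mag_arcsec2)


def luminance_to_irradiance(luminance_cd_m2: float) -> float:
    """Luminance (cd m^-2) -> broadband irradiance in uW m^-2 via 683 lm/W."""
    if luminance_cd_m2 < 0:
        raise ValueError("luminance must be non-negative")
    return luminance_cd_m2 / 683.0 * 1e6


def dark_sky_floor(grid: SpectralGrid | None = None) -> SpectralIrradiance:
    """Flat nighttime background (airglow + zodiacal + starlight) of 0.25 uW m^-2."""
    grid = grid or SpectralGrid()
    bb = luminance_to_irradiance(mag_to_luminance(DARK_SKY_MAG)) * 1e-6  # W m^-2
    vals = np.full_like(grid.wavelengths, bb / grid.span_nm)
    return SpectralIrradiance(grid, vals, "floor")
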