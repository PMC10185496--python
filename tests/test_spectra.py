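"""Spectral components: solar chain, twilight surrogate, moonlight, ALAN, floor."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from moontrigger import (AlanConfig, AtmosphereParams, LunarConfig, SolarTOAConfig,
                         alan_spectrum, clear_sky_surface, dark_sky_floor,
                         luminance_to_irradiance, mag_to_luminance, surface_lunar,
                         toa_lunar, toa_solar, twilight_irradiance)
from moontrigger.spectra import SpectralGrid, allen_phase_factor, twilight_partition


@pytest.fixture(scope="module")
def sun():
    return toa_solar(SolarTOAConfig(day_of_year=172))


@pytest.fixture(scope="module")
def atm():
    return AtmosphereParams.defaults()


class TestToaSolar:
    @pytest.mark.parametrize("day,expected", [(3, 1.0167**2), (185, None)])
    def test_eccentricity_multiplier(self, day, expected):
        cfg = SolarTOAConfig(day_of_year=day)
        ratio = toa_solar(cfg).values / cfg.h0_values
        if day == 3:
            assert np.allclose(ratio, 1.0167**2, rtol=1e-6)  # ~1.03368
        else:
            # D=185 is close to aphelion phase: cos ~ -1
            assert np.allclose(ratio, 0.9833**2, rtol=1e-3)  # ~0.96688

    def test_zero_eccentricity_identity(self):
        cfg = SolarTOAConfig(day_of_year=100, eccentricity=0.0)
        assert np.array_equal(toa_solar(cfg).values, cfg.h0_values)


class TestClearSky:
    def test_zenith_visible_irradiance_realistic(self, sun, atm):
        edd, eds = clear_sky_surface(sun, 0.0, atm)
        total = edd.broadband() + eds.broadband()
        assert 350 <= total <= 550  # clear-sky 400-700 nm at zenith
        assert 0 < edd.broadband() / sun.broadband() < 1

    def test_monotone_decrease_with_zenith(self, sun, atm):
        totals = []
        for tz in (0, 30, 60, 85, 89):
            edd, eds = clear_sky_surface(sun, tz, atm)
            totals.append(edd.broadband() + eds.broadband())
        assert all(a > b for a, b in zip(totals, totals[1:]))

    def test_diffuse_fraction_grows_with_zenith(self, sun, atm):
        fracs = []
        for tz in (10, 50, 80):
            edd, eds = clear_sky_surface(sun, tz, atm)
            fracs.append(eds.broadband() / (edd.broadband() + eds.broadband()))
        assert fracs[0] < fracs[1] < fracs[2]

    def test_sum_identity_and_nonnegativity(self, sun, atm):
        edd, eds = clear_sky_surface(sun, 40.0, atm)
        total = edd + eds
        assert np.allclose(total.values, edd.values + eds.values)
        assert (edd.values >= 0).all() and (eds.values >= 0).all()

    def test_below_horizon_rejected(self, sun, atm):
        with pytest.raises(ValueError, match="twilight"):
            clear_sky_surface(sun, 92.0, atm)


class TestTwilight:
    @pytest.mark.parametrize("alt,part", [(-3, "civil"), (-7, "nautical"),
                                          (-13, "astronomical"), (-20, "night")])
    def test_partitions(self, alt, part):
        assert twilight_partition(alt) == part

    def test_monotone_decay_with_depression(self, sun, atm):
        vals = [twilight_irradiance(a, sun, atm).broadband() for a in
                (-1, -3, -6, -9, -12, -15, -17.5)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_continuity_with_daylight_at_horizon(self, sun, atm):
        from moontrigger.spectra import TWILIGHT_ANCHOR_ZENITH
        edd, eds = clear_sky_surface(sun, TWILIGHT_ANCHOR_ZENITH, atm)
        horizon = edd.broadband() + eds.broadband()
        tw = twilight_irradiance(-0.01, sun, atm).broadband()
        assert abs(tw - horizon) / horizon <= 0.2

    def test_floor_reached_at_minus_18(self, sun, atm):
        tw = twilight_irradiance(-18.0, sun, atm).broadband_uW()
        floor = dark_sky_floor().broadband_uW()
        assert tw <= 10 * floor

    def test_below_minus_18_is_night_floor(self, sun, atm):
        si = twilight_irradiance(-25.0, sun, atm)
        assert si.component == "night"
        assert si.broadband_uW() == pytest.approx(dark_sky_floor().broadband_uW())


class TestLunar:
    def test_solid_angle_dilution(self):
        assert np.sin(np.radians(0.26)) ** 2 == pytest.approx(2.06e-5, rel=0.01)

    def test_full_moon_toa_ratio_five_orders_below_solar(self, sun):
        cfg = SolarTOAConfig(day_of_year=172)
        moon = toa_lunar(cfg, LunarConfig(), 0.0)
        ratio = moon.broadband() / sun.broadband()
        assert 1e-6 <= ratio <= 1e-5

    def test_quarter_moon_much_dimmer_than_full(self):
        cfg = SolarTOAConfig(day_of_year=172)
        full = toa_lunar(cfg, LunarConfig(), 0.0).broadband()
        quarter = toa_lunar(cfg, LunarConfig(), 90.0).broadband()
        assert quarter < 0.15 * full

    def test_phase_factor_monotone_and_normalized(self):
        g = np.linspace(0, 180, 50)
        f = allen_phase_factor(g)
        assert f[0] == pytest.approx(1.0)
        assert np.all(np.diff(f) <= 0)

    def test_full_moon_zenith_surface_order_of_magnitude(self, atm):
        cfg = SolarTOAConfig(day_of_year=172)
        moon = toa_lunar(cfg, LunarConfig(), 0.0)
        bb_mW = surface_lunar(moon, 0.0, atm).broadband() * 1e3
        assert 0.5 <= bb_mW <= 5.0  # published full-moon surface irradiance ~1-3 mW

    def test_below_horizon_is_zero(self, atm):
        cfg = SolarTOAConfig(day_of_year=172)
        moon = toa_lunar(cfg, LunarConfig(), 0.0)
        assert surface_lunar(moon, 95.0, atm).broadband() == 0.0

    def test_atmosphere_is_source_agnostic(self, sun, atm):
        # scaling the TOA source scales the surface by the same ratio
        cfg = SolarTOAConfig(day_of_year=172)
        moon = toa_lunar(cfg, LunarConfig(), 0.0)
        s1 = surface_lunar(moon, 40.0, atm).broadband()
        from moontrigger.spectra import SpectralIrradiance
        doubled = SpectralIrradiance(moon.grid, 2 * moon.values, "lunar_toa")
        s2 = surface_lunar(doubled, 40.0, atm).broadband()
        assert s2 / s1 == pytest.approx(2.0, rel=0.05)


class TestAlan:
    def test_zero_bands_zero_spectrum(self):
        si = alan_spectrum(AlanConfig())
        assert si.broadband() == 0.0

    def test_unit_bands_sum_to_three(self):
        si = alan_spectrum(AlanConfig(blue_uW=1, green_uW=1, red_uW=1))
        assert si.broadband_uW() == pytest.approx(3.0, rel=0.01)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(b=st.floats(0, 100), g=st.floats(0, 100), r=st.floats(0, 100))
    def test_band_integrals_match_configuration(self, b, g, r):
        si = alan_spectrum(AlanConfig(blue_uW=b, green_uW=g, red_uW=r))
        lam = si.grid.wavelengths
        for (lo, hi), target in (((400, 500), b), ((495, 560), g), ((640, 720), r)):
            m = (lam >= lo) & (lam <= hi)
            got = np.trapezoid(si.values[m], lam[m]) * 1e6
            assert got == pytest.approx(target, rel=0.01, abs=1e-9)

    @pytest.mark.parametrize("lamp", ["LED", "HPS", "LPS"])
    def test_lamp_shapes_normalized_to_total(self, lamp):
        si = alan_spectrum(AlanConfig(lamp_class=lamp, total_uW=10.0))
        assert si.broadband_uW() == pytest.approx(10.0, rel=0.01)

    def test_negative_band_rejected(self):
        with pytest.raises(ValueError):
            AlanConfig(blue_uW=-1.0)


class TestPhotometricChain:
    def test_dark_sky_luminance(self):
        assert mag_to_luminance(22) == pytest.approx(1.712e-4, rel=5e-4)

    def test_dark_sky_irradiance(self):
        assert luminance_to_irradiance(mag_to_luminance(22)) == pytest.approx(0.25, rel=0.005)

    def test_magnitude_definition(self):
        assert mag_to_luminance(2.5) / mag_to_luminance(0.0) == pytest.approx(0.1)
        assert mag_to_luminance(0.0) == pytest.approx(1.08e5)

    def test_inverse_constant(self):
        assert luminance_to_irradiance(683e-6) == pytest.approx(1.0)
        assert luminance_to_irradiance(0.0) == 0.0

    def test_floor_flat_and_site_independent(self):
        f = dark_sky_floor()
        assert f.broadband_uW() == pytest.approx(0.25, rel=0.01)
        assert np.allclose(f.values, f.values[0])
        per_nm_uW = f.values[0] * 1e6
        assert per_nm_uW == pytest.approx(0.25 / 300, rel=0.01)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(tz=st.floats(0, 89.4), g=st.floats(0, 180), day=st.integers(1, 366))
def test_every_component_nonnegative(tz, g, day):
    cfg = SolarTOAConfig(day_of_year=day)
    atm = AtmosphereParams()
    edd, eds = clear_sky_surface(toa_solar(cfg), tz, atm)
    moon = surface_lunar(toa_lunar(cfg, LunarConfig(), g), tz, atm)
    assert (edd.values >= 0).all() and (eds.values >= 0).all()
    assert (moon.values >= 0).all()
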