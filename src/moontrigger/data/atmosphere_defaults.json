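{
  "aerosol_optical_thickness_550": 0.10,
  "angstrom_exponent": 1.0,
  "single_scattering_albedo": 0.97,
  "forward_scatter_fraction": 0.90,
  "ozone_atm_cm": 0.30,
  "water_vapor_cm": 2.5,
  "pressure_hPa": 1013.25,
  "relative_humidity": 0.80,
  "wind_speed_m_s": 5.0
}
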