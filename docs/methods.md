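# Methods

## The light-field model

The simulator composes broadband (400–700 nm) sea-surface irradiance from
five components on a fixed 1 nm spectral grid and a 5-minute time step.

**Celestial geometry.** Sun and moon positions come from a self-contained
geocentric ephemeris: the standard low-precision solar theory and a truncated
lunar periodic-term series (32 longitude/distance terms, 30 latitude terms,
plus the leading planetary additives), with a smooth ΔT model and topocentric
parallax for the moon. Verified accuracy over 1950–2050 is ≈0.01–0.03° in
position and ≈1–2 min for rise/set events — comfortably inside the contract
the simulator needs (0.2°, 2 min). Rise/set horizons: −0.8333° for the sun
(refraction + semi-diameter); for the moon, topocentric altitude −0.5667°
with parallax applied explicitly. Full moons are ecliptic-longitude
oppositions found by bisection; at opposition the phase angle equals the
moon's ecliptic latitude (up to ~5°), so the illuminated fraction at a "full"
moon is slightly below 1 (≥ 0.996 in 2020).

A *night* is keyed by the local solar date of its sunset (local time =
UTC + longitude/15 h), making days-from-full-moon a well-defined per-night
integer without civil-timezone tables. Ties between two full moons break
toward the earlier one.

**Solar chain.** The top-of-atmosphere spectrum is corrected for orbital
eccentricity, `E0 = H0 (1 + ε cos{2π(D−3)/365})²` with ε = 0.0167, and passed
through a clear-sky marine atmosphere in the Gregg–Carder style: Rayleigh
transmittance with Kasten–Young airmass, a Chappuis-band ozone table, and an
Ångström aerosol term partitioned into direct and diffuse components
(single-scattering albedo 0.97, forward-scatter fraction 0.90; all parameters
live in `data/atmosphere_defaults.json`, never hard-coded). At zenith the
model delivers ≈465 W m⁻² over 400–700 nm with a 14% diffuse fraction. The
shipped TOA table is a smooth synthetic solar analog (5777 K Planck shape
normalized to 531 W m⁻² in-band) — the published lookup tables are not
redistributable — and any measured table with the same two-column CSV layout
drops in.

**Twilight surrogate.** The published rural-sky twilight lookup table is not
available, so twilight (solar altitude 0 to −18°) uses the documented
surrogate: log₁₀(broadband) declines linearly in solar depression from the
clear-sky value with the sun on the horizon (anchored at zenith angle 89.5°,
where the plane-parallel model is still defined) to the dark-sky floor at
−18°, with a mild `(550/λ)^(1.5·d/18)` blue shift of the spectral shape. This
preserves the two properties the trigger analysis uses — strict monotone
decay (~0.38 dex per degree of depression) and continuity with both daylight
and the night floor — and a measured LUT can be supplied as a callable.

**Moonlight.** TOA lunar irradiance is the solar spectrum × spectral albedo
(synthetic table rising 0.08→0.14 across the band, mean 0.11) × the solid-
angle dilution sin²(0.26°) ≈ 2.06×10⁻⁵ × an analytic phase curve
(0.026 mag/deg + 4×10⁻⁹ g⁴, normalized to 1 at opposition, so a quarter moon
is ~9% of full). The same atmosphere transmits it at the lunar zenith angle;
a full moon at zenith delivers ≈1.0 mW m⁻², and the TOA lunar/solar ratio is
2.2×10⁻⁶ — five to six orders of magnitude below the sun.

**ALAN.** Either explicit blue/green/red band irradiances or a lamp spectral
shape (LED/HPS/LPS) scaled to a total. The printed band limits overlap at
495–500 nm and exceed the grid at 720 nm; band supports are kept disjoint
(400–494, 501–560, 640–700) so each configured band integral is reproduced
within 1%, with the red band truncated at the 700 nm grid edge.

**Dark-sky floor.** 22 mag arcsec⁻² → 1.712×10⁻⁴ cd m⁻² (L = 10.8×10⁴ ×
10^(−0.4 m)) → 0.25 µW m⁻² (÷683 lm W⁻¹), spread flat across the band. It is
the "zero" of every nightly timeline.

## Trigger detection

An *extended period of minimum light intensity* is a maximal run of 5-minute
steps whose total irradiance stays within (1 + tolerance) × that night's own
minimum, spanning at least `min_duration` minutes between sunset and sunrise.
Defaults: tolerance 5%, duration 30 min; the acceptance run sweeps
{20, 30, 45, 60} min because the conclusions are in whole nights and should
not hinge on the window definition.

Defining the band relative to the night's own minimum lets one detector serve
both regimes. On an unlit night the minimum is the dark floor; the period can
only begin at astronomical dusk and ends within a step of moonrise, because
even low-altitude moonlight exceeds 5% of 0.25 µW m⁻² almost immediately. On
a lit night the minimum is the ALAN plateau; the period begins as soon as
twilight decays below 5% of the plateau and persists *through* moonrise until
moonlight itself outgrows the band. That masking of early moonlight is the
mechanism by which ALAN advances the trigger: the period end is therefore
governed by the tolerance band, not clipped at moonrise (clipping at moonrise
would cap every advance at ~1–2 nights, because twilight's steep decay makes
the band-entry time nearly independent of the ALAN level).

The month-to-month pattern follows from lunar geometry. The advance is
roughly (dark-start difference)/(nightly moonrise delay). Near the September
full moon at 29.5° N the waning moon sits in the shallow-rising part of the
ecliptic (the harvest-moon effect) and moonrise comes only ~30 min later each
night, so the same masking buys 4–5 nights; in March–May the delay is
~60–70 min and the advance is 1–3 nights, matching the low-latitude reef
where the delay is ~50 min year-round.

**Default ALAN scenario.** The atlas-derived maxima actually used for the two
demonstration reefs are not published, so the default is 10⁴ µW m⁻²
(10⁻² W m⁻²) broadband in equal thirds across the three bands — the order of
the underwater-ALAN atlas's maximum sea-surface irradiances near developed
coasts, a few times full-moon irradiance. Physically, masking moonlight (not
just twilight) requires ALAN of at least full-moon order; levels far below
that cannot reproduce a multi-night advance at any duration setting. Lights
switch at sunset/sunrise by default: with a civil-dusk switch-on and ALAN
comparable to civil-twilight irradiance, a single 5-minute step can fall just
below −6° before the lights come on, and that one-step dip below the plateau
becomes the night's minimum, spuriously suppressing lit periods (and with
them the advance's guaranteed non-negativity). Civil-dusk switching remains
available in `AlanConfig`.

## The statistical pipeline

**Classification.** `Lit` iff the critical depth of biologically important
ALAN (annual mean of the monthly atlas, extracted as the unweighted mean of
raster cells whose centers fall in a 0.05° circle) exceeds the observation
depth, or the species' minimum depth when no depth was recorded; otherwise
`Unlit`. Observations with neither depth are excluded and logged. SST and
Kd490 trends are τ = 0.5 quantile-regression slopes (L1 line), which resist
outlying years; fewer than three yearly values yields a missing trend.

**Filters.** Ex-situ records out; year ≥ 2000; genera with fewer than six
observations in either exposure level out; ecoregions with fewer than six
observations out. The genus and ecoregion rules interact, so they are
re-applied to convergence, with an audit log counting removals per rule.

**Model.** Counts (DoSRtNF minus its pooled minimum; the offset is recorded
and added back to every reported mean) follow a Poisson GLMM with a log link
and a site-level random effect with Matérn correlation over great-circle km.
Estimation maximizes the Laplace-approximate marginal likelihood: penalized
IRLS solves jointly for fixed and random effects at fixed (σ², ρ), and
Nelder–Mead from two starts optimizes (log σ², log ρ), with an explicit
σ² → 0 boundary comparison — at the boundary the criterion reduces exactly
to the plain Poisson GLM, which tests exploit as an independent oracle.
Smoothness ν is fixed at 1.5 by default (at a few dozen sites its profile is
flat); `profile_nu=True` profiles over {0.5, 1.5, 2.5}. Fixed-effect
covariance is the Schur complement of the joint information; dispersion is
Pearson χ²/(n−p) at the conditional means. AIC = −2ℓ + 2k with k counting
fixed effects plus the two variance parameters.

**Selection and tests.** All nested fixed-term subsets of the global model
are fitted and ranked by AIC with Akaike weights; marginality (interaction ⇒
both mains) is enforced by default, giving 2⁵ + 3⁴·2 = 194 models for the
global structure (the unrestricted 2¹⁰ enumeration is available). Failed
members are recorded and ranking proceeds. Likelihood-ratio tests use
χ² = 2Δℓ with df = the difference in fixed-effect count. Per-genus contrasts
come from independent Poisson models, switching to negative binomial when
Pearson dispersion exceeds 1.5; differences are response-scale (days) with
delta-method 95% and 90% intervals and unadjusted Wald p-values.

Per-genus lit shifts from the mixed model are reported at the reference
profile (continuous covariates 0, reference ecoregion, random effects
removed), where the response-scale contrast is free of regional and
latitudinal scaling — this is the quantity the generator makes exactly equal
to its configured day shift.

## The synthetic-data generator

Sites are scattered (≥ 0.2° apart) in a reef band spanning ±32° latitude;
half are lit. The toy critical-depth raster is 0 m everywhere except 0.05°
discs of 50 m around lit sites, so the classification rule reproduces the
assignment exactly regardless of the 2–10 m observation depths; ~30% of
observations omit depth to exercise the trait-table fallback. Counts are
drawn with log-mean = genus baseline + lit shift (day-scale shifts converted
to log coefficients so the realized reference-profile difference equals the
configured days) + 0.005/deg latitude trend + ecoregion intercepts
(SD 0.05, reference 0, assigned independently of latitude so the two effects
stay separately identifiable) + a Matérn(ν = 1.5, ρ = 500 km, σ² = 0.05) site
field. Twelve genera mirror the analyzed community: one −3-day shift, seven
−2, three −1, one null. Dispersion 1 is plain Poisson; targets below 1 use
matched-mean binomial draws (variance ratio 1 − p). Everything is
deterministic under the config seed.

What the generator does *not* emulate: real reef biogeography, the atlas's
spatial texture, species-level effects, temporal autocorrelation within
sites, and observation-effort imbalance between regions. Passing recovery
tests therefore show the estimator is correct for its assumed data-generating
process, not that the real database satisfies those assumptions.

## Numerical choices and limitations

- Problem sizes in tests and the acceptance run: 50 replicates of 2 000
  observations at 40 sites for coverage; 100 replicates of 400 observations
  at 25 sites for LRT calibration; 1 000 random two-night step timelines for
  the detector oracle; trigger advances for 10 reef-months of 2020.
- The detector's duration is the time span between the first and last step
  in the band (steps − 1 × 5 min), so a reported 30-min period contains
  seven in-band steps.
- Laplace-ML standard errors ignore variance-parameter uncertainty and are
  ~10–15% anticonservative in the coverage study (observed 91–94% at nominal
  95%); this matches the behavior of standard spatial-GLMM software at a few
  dozen sites.
- The ephemeris neglects nutation in the sidereal angle, topocentric
  libration and eclipses; ΔT is a smooth fit valid ~1950–2050.
- Rasters are single-band plain-text ESRI ASCII grids in WGS84 decimal
  degrees with cell-center containment; SST/Kd490 fields are accepted as
  pre-extracted per-year values rather than satellite grids.
- The twilight surrogate, TOA solar table and lunar albedo are synthetic
  stand-ins with realistic broadband normalization; absolute twilight
  spectra (and thus exact band-entry times) carry the largest model
  uncertainty, which the duration sweep is designed to absorb.
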