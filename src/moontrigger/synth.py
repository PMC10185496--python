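"""Synthetic spawning data with the statistical structure the pipeline assumes.

Generates a site table with Lit/Unlit assignment, a toy critical-ALAN-
depth raster constructed so the classification rule reproduces that
assignment exactly, a species trait table, and a spawning-observation
CSV drawn from the fitted model's own data-generating process:

    y_is ~ Poisson(mu_is),
    log mu_is = log m_g + 1[Lit_s] log((m_g + delta_g)/m_g)
                + gamma * DfE_s + eco_e(s) + b_s,
    b ~ N(0, sigma^2 Matern(d; rho, nu)),

where m_g is the genus baseline mean (days, on the positive-transformed
scale), delta_g the lit shift in days (negative = closer to full moon),
gamma a latitude trend per degree, and b a site-level Matern Gaussian
field over great-circle distance.  Written days-from-full-moon is
y - offset_days.  The lit-shift parametrization makes the realized
lit-unlit difference at reference covariates equal delta_g exactly.

A target dispersion below 1 replaces the Poisson draw with a binomial
of matched mean (variance ratio = 1 - p), emulating the mild
underdispersion seen in real spawning tables; the default is plain
Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .glmm import haversine_km, matern_correlation
from .io import Raster

__all__ = ["GeneratorConfig", "DEFAULT_GENERA", "gen_sites", "gen_observations",
           "generate_dataset"]

#: genus -> (baseline mean days on transformed scale, lit shift in days).
#: Mirrors the analyzed genera: one three-day shift, seven two-day, three
#: one-day (one of them weakly supported), one null genus.
DEFAULT_GENERA: Dict[str, Tuple[float, float]] = {
    "Porites": (7.0, -3.0),
    "Acropora": (6.0, -2.0),
    "Dipsastraea": (6.5, -2.0),
    "Goniastrea": (6.0, -2.0),
    "Galaxea": (7.0, -2.0),
    "Acanthastrea": (6.5, -2.0),
    "Platygyra": (6.0, -2.0),
    "Cyphastrea": (7.5, -2.0),
    "Montipora": (5.5, -1.0),
    "Favites": (6.0, -1.0),
    "Echinophyllia": (8.0, -1.0),
    "Lobophyllia": (6.5, 0.0),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic spawning dataset."""
    n_sites: int = 40
    n_obs: int = 2000
    genera: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GENERA))
    n_ecoregions: int = 6
    ecoregion_sd: float = 0.05      # log-scale intercept spread (reference region = 0)
    gamma_per_deg: float = 0.005    # latitude trend on the log link, per degree
    matern_nu: float = 1.5
    matern_rho_km: float = 500.0
    matern_sigma2: float = 0.05
    dispersion: float = 1.0         # <1 switches to matched-mean binomial draws
    offset_days: int = 8            # written DoSRtNF = y - offset_days
    lon_range: Tuple[float, float] = (145.0, 155.0)
    lat_range: Tuple[float, float] = (-32.0, 32.0)
    raster_cell_deg: float = 0.05
    lit_fraction: float = 0.5
    frac_missing_depth: float = 0.3
    seed: int = 0


def gen_sites(cfg: GeneratorConfig, rng: Optional[np.random.Generator] = None):
    """Site table, Lit/Unlit assignment, toy critical-depth raster, trait table.

    The raster holds 0 m everywhere except 0.05-degree discs of 50 m
    critical depth around lit sites, so the classification rule (critical
    depth > reference depth, all reference depths <= 10 m) reproduces the
    intended labels exactly.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    lon0, lon1 = cfg.lon_range
    lat0, lat1 = cfg.lat_range
    pts = []
    while len(pts) < cfg.n_sites:
        lat = rng.uniform(lat0, lat1)
        lon = rng.uniform(lon0, lon1)
        if all((lat - a) ** 2 + (lon - b) ** 2 > 0.2 ** 2 for a, b in pts):
            pts.append((lat, lon))
    lats, lons = map(np.array, zip(*pts))
    n_lit = int(round(cfg.lit_fraction * cfg.n_sites))
    lit = np.zeros(cfg.n_sites, bool)
    lit[rng.permutation(cfg.n_sites)[:n_lit]] = True
    ref_depth = np.round(rng.uniform(2.0, 10.0, cfg.n_sites), 1)
    # ecoregion membership independent of latitude so the regional intercepts
    # and the latitude trend stay separately identifiable
    eco_idx = rng.integers(0, cfg.n_ecoregions, cfg.n_sites)
    sites = pd.DataFrame({
        "site_id": [f"S{k:03d}" for k in range(cfg.n_sites)],
        "latitude": lats, "longitude": lons, "lit": lit,
        "ref_depth_m": ref_depth,
        "ecoregion": [f"ER{e + 1:02d}" for e in eco_idx],
    })

    pad = 0.2
    nc = int(np.ceil((lon1 - lon0 + 2 * pad) / cfg.raster_cell_deg))
    nr = int(np.ceil((lat1 - lat0 + 2 * pad) / cfg.raster_cell_deg))
    raster = Raster(data=np.zeros((nr, nc)), x_ll=lon0 - pad, y_ll=lat0 - pad,
                    cell=cfg.raster_cell_deg)
    for _, s in sites[sites["lit"]].iterrows():
        raster.set_circle(s["latitude"], s["longitude"], 0.05, 50.0)

    # one trait row per species; trait depth equals the depth used at sites,
    # so the no-recorded-depth fallback classifies identically
    traits = pd.DataFrame({
        "species": [f"{g} sp{k}" for g in cfg.genera for k in (1, 2)],
        "lower_depth_m": np.round(rng.uniform(2.0, 10.0, 2 * len(cfg.genera)), 1),
    })
    return sites, raster, traits


def gen_observations(cfg: GeneratorConfig, sites: pd.DataFrame,
                     rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Spawning-observation table in the external CSV schema, plus nothing else.

    Deterministic under a fixed config seed (pass the same rng used for
    gen_sites to continue its stream, or none to restart it).
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    n = cfg.n_obs
    m = len(sites)
    site_k = rng.integers(0, m, n)
    genera = list(cfg.genera)
    gen_k = rng.integers(0, len(genera), n)

    b = _matern_field(cfg, sites, rng)
    eco_names = sorted(sites["ecoregion"].unique())
    eco_eff = {e: (0.0 if i == 0 else rng.normal(0.0, cfg.ecoregion_sd))
               for i, e in enumerate(eco_names)}

    lat = sites["latitude"].to_numpy()[site_k]
    lon = sites["longitude"].to_numpy()[site_k]
    lit = sites["lit"].to_numpy()[site_k]
    eco = sites["ecoregion"].to_numpy()[site_k]
    dfe = np.abs(lat)
    base = np.array([cfg.genera[genera[k]][0] for k in gen_k])
    delta = np.array([cfg.genera[genera[k]][1] for k in gen_k])
    shifted = np.maximum(base + delta, 0.5)
    eta = (np.log(base) + lit * np.log(shifted / base)
           + cfg.gamma_per_deg * dfe
           + np.array([eco_eff[e] for e in eco])
           + b[site_k])
    mu = np.exp(eta)
    if cfg.dispersion >= 1.0:
        y = rng.poisson(mu)
    else:
        p = 1.0 - cfg.dispersion
        nn = np.maximum(np.round(mu / p).astype(int), 1)
        y = rng.binomial(nn, np.clip(mu / nn, 0, 1))

    depth = sites["ref_depth_m"].to_numpy()[site_k].astype(float)
    missing = rng.random(n) < cfg.frac_missing_depth
    species = np.array([f"{genera[k]} sp{rng.integers(1, 3)}" for k in gen_k])

    df = pd.DataFrame({
        "Site": sites["site_id"].to_numpy()[site_k],
        "Latitude": lat, "Longitude": lon,
        "Year": rng.integers(2000, 2020, n),
        "Genus": [genera[k] for k in gen_k],
        "Species": species,
        "Depth_m": np.where(missing, np.nan, depth),
        "DoSRtNF": y - cfg.offset_days,
        "Ecoregion": eco,
        "O_n": "in situ",
    })
    df.attrs["truth"] = {
        "genera": {g: {"baseline_days": v[0], "delta_days": v[1]}
                   for g, v in cfg.genera.items()},
        "gamma_per_deg": cfg.gamma_per_deg,
        "ecoregion_effects": eco_eff,
        "matern": {"nu": cfg.matern_nu, "rho_km": cfg.matern_rho_km,
                   "sigma2": cfg.matern_sigma2},
        "offset_days": cfg.offset_days,
        "site_effects": b.tolist(),
    }
    return df


def _matern_field(cfg: GeneratorConfig, sites: pd.DataFrame, rng) -> np.ndarray:
    D = haversine_km(sites["latitude"].to_numpy(), sites["longitude"].to_numpy())
    C = cfg.matern_sigma2 * matern_correlation(D, cfg.matern_rho_km, cfg.matern_nu)
    if cfg.matern_sigma2 <= 0:
        return np.zeros(len(sites))
    L = np.linalg.cholesky(C + 1e-10 * np.eye(len(sites)))
    return L @ rng.standard_normal(len(sites))


def generate_dataset(cfg: GeneratorConfig):
    """One call: sites, raster, traits, observations and the truth record."""
    rng = np.random.default_rng(cfg.seed)
    sites, raster, traits = gen_sites(cfg, rng)
    obs = gen_observations(cfg, sites, rng)
    return sites, raster, traits, obs, obs.attrs["truth"]


def to_pipeline_frame(obs: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """Observations in the canonical pipeline schema with the generator's labels.

    Uses the site table's Lit/Unlit assignment directly (identical to
    classifying through the toy raster, which is verified separately) and
    adds the covariate columns the model formula expects.
    """
    from .io import SPAWNING_COLUMNS
    df = obs.rename(columns=SPAWNING_COLUMNS).copy()
    df["in_situ"] = df["o_n"].astype(str).str.lower().eq("in situ")
    lit_sites = set(sites.loc[sites["lit"], "site_id"])
    df["exposure"] = np.where(df["site_id"].isin(lit_sites), "Lit", "Unlit")
    df["dsst"] = 0.0
    df["dkd490"] = 0.0
    df["dfe"] = df["latitude"].abs()
    return df
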