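"""Spawning-timing inference pipeline.

Steps mirror the published analysis: classify every observation as
ALAN-exposed ("Lit") or not by comparing the critical depth of
biologically important artificial light with the observation depth (or
the species' minimum depth when no depth was recorded); build site
covariates (median-regression trends of SST and water clarity, distance
from the equator); filter to in-situ 21st-century records with at least
six observations per genus-and-exposure cell and per ecoregion; fit a
Poisson mixed model with a Matern spatial random effect to the
positive-transformed days-from-full-moon response; select among all
marginality-respecting nested fixed-effect structures by AIC; and probe
effects with likelihood-ratio tests and per-genus Lit-vs-Unlit
contrasts from independent Poisson / negative-binomial models.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .glmm import GLMMFit, fit_poisson_glmm

__all__ = [
    "ModelSpec",
    "GLOBAL_TERMS",
    "classify_exposure",
    "buffer_mean",
    "median_trend",
    "apply_filters",
    "positive_transform",
    "build_design",
    "fit_glmm",
    "select_model",
    "enumerate_nested",
    "lrt",
    "genus_contrasts",
    "genus_exposure_means",
    "genus_shift_table",
]

#: fixed-effect terms of the global model (the random Matern term is always present)
GLOBAL_TERMS = ("ALAN", "Genus", "dSST", "dKd490", "DfE", "Ecoregion",
                "ALAN:Genus", "ALAN:dSST", "ALAN:dKd490", "ALAN:DfE")

NB_DISPERSION_SWITCH = 1.5  # per-genus models go negative-binomial above this


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure; the Matern random effect is always retained."""
    fixed_terms: Tuple[str, ...] = GLOBAL_TERMS
    nu: float = 1.5
    profile_nu: bool = False

    def __post_init__(self):
        for t in self.fixed_terms:
            if ":" in t:
                a, b = t.split(":")
                if a not in self.fixed_terms or b not in self.fixed_terms:
                    raise ValueError(f"interaction {t} lacks a main effect (marginality)")


# ---------------------------------------------------------------------------
# classification & covariates

def classify_exposure(df: pd.DataFrame, critical_depth: pd.Series | np.ndarray,
                      trait_min_depth: Mapping[str, float]) -> Tuple[pd.DataFrame, dict]:
    """Label each observation Lit/Unlit by the critical-ALAN-depth rule.

    Lit iff the critical depth of biologically important ALAN at the site
    exceeds the reference depth: the recorded observation depth, or the
    species' minimum depth when none was recorded.  Observations with
    neither depth are dropped and counted in the audit log.
    """
    out = df.copy()
    crit = np.asarray(critical_depth, dtype=float)
    if len(crit) != len(out):
        raise ValueError("critical_depth length must match table")
    ref = out["depth_m"].astype(float)
    fallback = out["species"].map(lambda s: float(trait_min_depth.get(s, np.nan)))
    ref = ref.where(~ref.isna(), fallback)
    keep = ~ref.isna()
    audit = {"no_depth_no_trait": int((~keep).sum())}
    out = out.loc[keep].copy()
    out["exposure"] = np.where(crit[keep.to_numpy()] > ref[keep].to_numpy(), "Lit", "Unlit")
    return out, audit


def buffer_mean(raster, lat: float, lon: float, radius_deg: float = 0.05) -> float:
    """Unweighted mean of raster cells whose centers fall inside a degree-space circle.

    No-data cells are excluded; a point outside the raster raises, and a
    buffer of only no-data cells returns NaN.
    """
    if not (raster.y_min <= lat <= raster.y_max and raster.x_min <= lon <= raster.x_max):
        raise ValueError(f"point ({lat}, {lon}) outside raster extent")
    xs, ys = raster.cell_centers()
    dx = xs[None, :] - lon
    dy = ys[:, None] - lat
    inside = dx**2 + dy**2 <= radius_deg**2
    vals = raster.data[inside]
    vals = vals[~np.isnan(vals)]
    if raster.nodata is not None:
        vals = vals[vals != raster.nodata]
    return float(vals.mean()) if len(vals) else float("nan")


def median_trend(years: Sequence[float], values: Sequence[float]) -> Optional[float]:
    """Slope per year of the tau=0.5 quantile-regression (L1) line.

    Returns None (logged by callers) for fewer than 3 yearly values.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(values)
    years, values = years[ok], values[ok]
    if len(years) < 3:
        return None
    import statsmodels.api as sm
    Xd = sm.add_constant(years - years.mean())
    fit = sm.QuantReg(values, Xd).fit(q=0.5)
    return float(fit.params[1])


def apply_filters(df: pd.DataFrame, min_per_cell: int = 6) -> Tuple[pd.DataFrame, dict]:
    """The published retention rules, re-applied to convergence.

    In order: drop ex-situ records; restrict to year >= 2000; drop genera
    with fewer than `min_per_cell` observations in either exposure level;
    drop ecoregions with fewer than `min_per_cell` observations.  The last
    two interact, so they are iterated until the table is stable.
    """
    audit: Dict[str, int] = {}
    out = df.copy()
    n0 = len(out)
    out = out[out["in_situ"]]
    audit["ex_situ"] = n0 - len(out)
    n0 = len(out)
    out = out[out["year"] >= 2000]
    audit["pre_2000"] = n0 - len(out)
    audit["genus_rule"] = 0
    audit["ecoregion_rule"] = 0
    for _ in range(100):
        n0 = len(out)
        cell = out.groupby(["genus", "exposure"]).size().unstack(fill_value=0)
        for lev in ("Lit", "Unlit"):
            if lev not in cell:
                cell[lev] = 0
        bad_genera = cell.index[(cell["Lit"] < min_per_cell) | (cell["Unlit"] < min_per_cell)]
        out = out[~out["genus"].isin(bad_genera)]
        audit["genus_rule"] += n0 - len(out)
        n0 = len(out)
        eco_n = out.groupby("ecoregion").size()
        bad_eco = eco_n.index[eco_n < min_per_cell]
        out = out[~out["ecoregion"].isin(bad_eco)]
        audit["ecoregion_rule"] += n0 - len(out)
        if len(out) == n0 and len(bad_genera) == 0:
            break
    if len(out) == 0:
        raise ValueError(f"all observations filtered out; audit: {audit}")
    return out.reset_index(drop=True), audit


@dataclass(frozen=True)
class PositiveTransform:
    """Record of the shift applied to make the response non-negative."""
    offset: float

    def forward(self, y):
        return np.asarray(y, dtype=float) - self.offset

    def backward(self, y_prime):
        return np.asarray(y_prime, dtype=float) + self.offset


def positive_transform(dosrtnf: Sequence[float],
                       offset: Optional[float] = None) -> Tuple[np.ndarray, PositiveTransform]:
    """Shift days-from-full-moon to non-negative integers (subtract the minimum).

    The offset is recorded so every fitted mean can be reported back on
    the days-from-full-moon scale.  An explicit offset (e.g. -15) may be
    supplied instead of the pooled minimum.
    """
    y = np.asarray(dosrtnf, dtype=float)
    if offset is None:
        offset = float(y.min())
    t = PositiveTransform(offset=offset)
    yp = t.forward(y)
    if np.any(yp < 0):
        raise ValueError("offset leaves negative values")
    return yp, t


# ---------------------------------------------------------------------------
# design matrices

def _dummies(series: pd.Series, prefix: str):
    cats = sorted(series.unique())
    cols, names = [], []
    for c in cats[1:]:
        cols.append((series == c).to_numpy(float))
        names.append(f"{prefix}[{c}]")
    return cols, names


def build_design(df: pd.DataFrame, terms: Sequence[str]):
    """Design matrix for a term list over the canonical pipeline columns.

    Categorical terms are treatment-coded against the alphabetically
    first level; interactions are products of the coded main effects.
    """
    n = len(df)
    cols: List[np.ndarray] = [np.ones(n)]
    names: List[str] = ["Intercept"]
    main: Dict[str, Tuple[List[np.ndarray], List[str]]] = {}

    def main_cols(term):
        if term in main:
            return main[term]
        if term == "ALAN":
            c, nm = [(df["exposure"] == "Lit").to_numpy(float)], ["ALAN[Lit]"]
        elif term == "Genus":
            c, nm = _dummies(df["genus"], "Genus")
        elif term == "Ecoregion":
            c, nm = _dummies(df["ecoregion"], "Ecoregion")
        elif term in ("dSST", "dKd490", "DfE"):
            c, nm = [df[term.lower()].to_numpy(float)], [term]
        else:
            raise ValueError(f"unknown term {term!r}")
        main[term] = (c, nm)
        return c, nm

    for t in terms:
        if ":" not in t:
            c, nm = main_cols(t)
            cols += c
            names += nm
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            ca, na = main_cols(a)
            cb, nb = main_cols(b)
            for x, xn in zip(ca, na):
                for z, zn in zip(cb, nb):
                    cols.append(x * z)
                    names.append(f"{xn}:{zn}")
    return np.column_stack(cols), names


def _site_structure(df: pd.DataFrame):
    sites = df.groupby("site_id").agg(latitude=("latitude", "first"),
                                      longitude=("longitude", "first"))
    site_ids = sites.index.to_numpy()
    idx = pd.Categorical(df["site_id"], categories=site_ids).codes
    return idx, sites["latitude"].to_numpy(), sites["longitude"].to_numpy()


# ---------------------------------------------------------------------------
# fitting, selection, testing

def fit_glmm(spec: ModelSpec, df: pd.DataFrame,
             transform: Optional[PositiveTransform] = None,
             fix_sigma2: Optional[float] = None) -> GLMMFit:
    """Fit the spatial Poisson mixed model for a fixed-effect structure.

    `df` must carry columns y (non-negative response), exposure, genus,
    ecoregion, dsst, dkd490, dfe, site_id, latitude, longitude.  Setting
    ``fix_sigma2=0`` pins the spatial variance at zero, which reduces the
    criterion exactly to a plain Poisson GLM.
    """
    X, names = build_design(df, spec.fixed_terms)
    idx, slat, slon = _site_structure(df)
    fit = fit_poisson_glmm(X, df["y"].to_numpy(), idx, slat, slon,
                           term_names=names, nu=spec.nu, profile_nu=spec.profile_nu,
                           offset=transform.offset if transform else 0.0,
                           fix_sigma2=fix_sigma2)
    fit.meta["fixed_terms"] = tuple(spec.fixed_terms)
    return fit


def enumerate_nested(global_terms: Sequence[str] = GLOBAL_TERMS,
                     marginality: bool = True) -> List[Tuple[str, ...]]:
    """All nested fixed-term subsets of the global model.

    With marginality (default) an interaction is only allowed when both
    of its main effects are present.
    """
    terms = list(global_terms)
    out = []
    for r in range(len(terms) + 1):
        for sub in itertools.combinations(terms, r):
            if marginality:
                ok = all((":" not in t) or all(p in sub for p in t.split(":")) for t in sub)
                if not ok:
                    continue
            out.append(tuple(sub))
    return out


def select_model(df: pd.DataFrame, global_terms: Sequence[str] = GLOBAL_TERMS,
                 marginality: bool = True, nu: float = 1.5,
                 transform: Optional[PositiveTransform] = None) -> pd.DataFrame:
    """Fit every nested model and rank by AIC (delta-AIC, Akaike weights)."""
    rows = []
    fits = {}
    for sub in enumerate_nested(global_terms, marginality):
        try:
            fit = fit_glmm(ModelSpec(fixed_terms=sub, nu=nu), df, transform)
            rows.append(dict(terms=" + ".join(sub) if sub else "1", n_terms=len(sub),
                             k=fit.k_params, loglik=fit.loglik, aic=fit.aic,
                             converged=fit.converged, failed=False))
            fits[sub] = fit
        except Exception as e:  # a failed member is recorded, ranking proceeds
            rows.append(dict(terms=" + ".join(sub) if sub else "1", n_terms=len(sub),
                             k=np.nan, loglik=np.nan, aic=np.inf,
                             converged=False, failed=True))
    tab = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    tab["delta_aic"] = tab["aic"] - tab["aic"].iloc[0]
    w = np.exp(-0.5 * tab["delta_aic"].to_numpy())
    w = np.where(np.isfinite(w), w, 0.0)
    tab["akaike_weight"] = w / w.sum()
    tab["cum_weight"] = tab["akaike_weight"].cumsum()
    tab.attrs["fits"] = fits
    return tab


def lrt(nested: GLMMFit, full: GLMMFit) -> Tuple[float, int, float]:
    """Likelihood-ratio test of a nested fixed-effect structure.

    chi^2 = 2 (l_full - l_nested), df = difference in fixed-effect count.
    """
    t_n = set(nested.meta.get("fixed_terms", ()))
    t_f = set(full.meta.get("fixed_terms", ()))
    if t_n and t_f and not t_n <= t_f:
        raise ValueError("models are not nested")
    df = full.n_fixed - nested.n_fixed
    if df < 0:
        raise ValueError("'full' model has fewer parameters than 'nested'")
    chi2 = max(2.0 * (full.loglik - nested.loglik), 0.0)
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else 1.0
    return chi2, df, p


# ---------------------------------------------------------------------------
# per-genus contrasts

def _fit_count_model(y, lit):
    """Poisson GLM, switching to negative binomial when overdispersed."""
    import statsmodels.api as sm
    X = sm.add_constant(lit.astype(float))
    pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    disp = float(pois.pearson_chi2 / pois.df_resid) if pois.df_resid > 0 else 1.0
    family = "poisson"
    fit = pois
    if disp > NB_DISPERSION_SWITCH:
        try:
            import statsmodels.discrete.discrete_model as smd
            nb = smd.NegativeBinomial(y, X).fit(disp=0, maxiter=200)
            fit = nb
            family = "negative_binomial"
        except Exception:
            pass
    return fit, family, disp


def genus_contrasts(df: pd.DataFrame, transform: Optional[PositiveTransform] = None,
                    levels=(0.95, 0.90)) -> pd.DataFrame:
    """Lit-vs-Unlit modeled mean days-from-full-moon per genus.

    Independent Poisson (negative binomial when Pearson dispersion
    exceeds 1.5) models per genus; the difference in days is the
    back-transformed response-scale contrast with delta-method CIs;
    p-values are unadjusted Wald tests of the exposure coefficient.
    """
    off = transform.offset if transform else 0.0
    rows = []
    for genus, g in df.groupby("genus"):
        y = g["y"].to_numpy(float)
        lit = (g["exposure"] == "Lit").to_numpy()
        if lit.sum() == 0 or (~lit).sum() == 0:
            continue
        fit, family, disp = _fit_count_model(y, lit)
        b = np.asarray(fit.params)[:2]
        V = np.asarray(fit.cov_params())[:2, :2]
        mu_u, mu_l = math.exp(b[0]), math.exp(b[0] + b[1])
        diff = mu_l - mu_u
        grad = np.array([diff, mu_l])
        se = float(np.sqrt(grad @ V @ grad))
        se_b1 = math.sqrt(max(V[1, 1], 0))
        pz = 2 * sps.norm.sf(abs(b[1]) / se_b1) if se_b1 > 0 else 1.0
        row = dict(genus=genus, n_lit=int(lit.sum()), n_unlit=int((~lit).sum()),
                   family=family, dispersion=disp,
                   mean_unlit_days=mu_u + off, mean_lit_days=mu_l + off,
                   difference_days=diff, p_unadjusted=float(pz))
        for lev in levels:
            z = sps.norm.ppf(0.5 + lev / 2)
            row[f"ci{int(lev * 100)}_lo"] = diff - z * se
            row[f"ci{int(lev * 100)}_hi"] = diff + z * se
        rows.append(row)
    return pd.DataFrame(rows)


def genus_shift_table(fit: GLMMFit, df: pd.DataFrame,
                      levels=(0.95, 0.90)) -> pd.DataFrame:
    """Per-genus lit-unlit difference in days from the mixed model.

    Evaluated at the reference covariate profile (continuous covariates
    at zero, reference ecoregion, spatial effects removed), where the
    response-scale contrast is free of regional and latitudinal scaling;
    CIs are delta-method using the full fixed-effect covariance.
    """
    names = fit.term_names
    rows = []
    for genus in sorted(df["genus"].unique()):
        x_u = np.zeros(len(names))
        x_l = np.zeros(len(names))
        for j, nm in enumerate(names):
            if nm == "Intercept" or nm == f"Genus[{genus}]":
                x_u[j] = x_l[j] = 1.0
            elif nm == "ALAN[Lit]" or nm == f"ALAN[Lit]:Genus[{genus}]":
                x_l[j] = 1.0
        mu_u = float(np.exp(x_u @ fit.beta))
        mu_l = float(np.exp(x_l @ fit.beta))
        diff = mu_l - mu_u
        grad = mu_l * x_l - mu_u * x_u
        se = float(np.sqrt(max(grad @ fit.beta_cov @ grad, 0.0)))
        row = dict(genus=genus, mean_unlit_days=mu_u + fit.offset,
                   mean_lit_days=mu_l + fit.offset, difference_days=diff, se=se)
        for lev in levels:
            z = sps.norm.ppf(0.5 + lev / 2)
            row[f"ci{int(lev * 100)}_lo"] = diff - z * se
            row[f"ci{int(lev * 100)}_hi"] = diff + z * se
        rows.append(row)
    return pd.DataFrame(rows)


def genus_exposure_means(fit: GLMMFit, df: pd.DataFrame,
                         level: float = 0.95) -> pd.DataFrame:
    """Predicted genus x exposure means (days) with spatial effects removed.

    Continuous covariates are held at their data means; the ecoregion
    factor at its reference level; CIs are delta-method on the link.
    """
    names = fit.term_names
    means = {c: float(df[c.lower()].mean()) for c in ("dSST", "dKd490", "DfE")
             if c.lower() in df}
    rows = []
    for genus in sorted(df["genus"].unique()):
        for expo in ("Unlit", "Lit"):
            x = np.zeros(len(names))
            for j, nm in enumerate(names):
                if nm == "Intercept":
                    x[j] = 1.0
                elif nm == f"Genus[{genus}]":
                    x[j] = 1.0
                elif nm == "ALAN[Lit]":
                    x[j] = 1.0 if expo == "Lit" else 0.0
                elif nm == f"ALAN[Lit]:Genus[{genus}]":
                    x[j] = 1.0 if expo == "Lit" else 0.0
                elif nm in means:
                    x[j] = means[nm]
                elif nm.startswith("ALAN[Lit]:") and nm.split(":")[1] in means:
                    x[j] = means[nm.split(":")[1]] if expo == "Lit" else 0.0
            mu, lo, hi = fit.predict_mean(x, level=level)
            rows.append(dict(genus=genus, exposure=expo,
                             mean_days=float(mu[0]) + fit.offset,
                             ci_lo=float(lo[0]) + fit.offset,
                             ci_hi=float(hi[0]) + fit.offset))
    return pd.DataFrame(rows)
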