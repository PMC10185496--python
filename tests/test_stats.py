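"""Classification, covariates, filters, GLMM, model selection and contrasts."""

import numpy as np
import pandas as pd
import pytest

from moontrigger import (ModelSpec, apply_filters, buffer_mean, classify_exposure,
                         enumerate_nested, fit_glmm, genus_contrasts, lrt,
                         matern_correlation, positive_transform, select_model)
from moontrigger.glmm import GLMMFit
from moontrigger.io import Raster
from moontrigger.stats import build_design, genus_shift_table, median_trend


def _obs_table(rows):
    defaults = dict(site_id="S0", latitude=0.0, longitude=150.0, year=2010,
                    genus="Acropora", species="Acropora sp1", depth_m=np.nan,
                    dosrtnf=5, ecoregion="ER01", in_situ=True, o_n="in situ")
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestClassifyExposure:
    def test_critical_depth_rule(self):
        df = _obs_table([dict(depth_m=5.0), dict(depth_m=5.0), dict(depth_m=np.nan)])
        crit = np.array([10.0, 0.0, 4.0])
        out, audit = classify_exposure(df, crit, {"Acropora sp1": 3.0})
        assert list(out["exposure"]) == ["Lit", "Unlit", "Lit"]
        assert audit["no_depth_no_trait"] == 0

    def test_missing_depth_and_trait_excluded(self):
        df = _obs_table([dict(depth_m=np.nan, species="Unknown sp")])
        out, audit = classify_exposure(df, np.array([10.0]), {})
        assert len(out) == 0 and audit["no_depth_no_trait"] == 1

    def test_pure_function_under_row_permutation(self):
        rng = np.random.default_rng(0)
        df = _obs_table([dict(depth_m=float(d)) for d in rng.uniform(1, 12, 30)])
        crit = rng.uniform(0, 15, 30)
        out1, _ = classify_exposure(df, crit, {})
        perm = rng.permutation(30)
        out2, _ = classify_exposure(df.iloc[perm].reset_index(drop=True), crit[perm], {})
        assert list(out2["exposure"]) == [out1["exposure"].iloc[k] for k in perm]


class TestBufferMean:
    def _raster(self, data):
        return Raster(data=np.asarray(data, dtype=float), x_ll=149.0, y_ll=-1.0, cell=0.01)

    def test_constant_raster(self):
        r = self._raster(np.full((200, 200), 7.5))
        assert buffer_mean(r, 0.0, 150.0) == pytest.approx(7.5)

    def test_half_zero_half_two(self):
        data = np.zeros((200, 200))
        data[:, 100:] = 2.0  # east half
        r = self._raster(data)
        assert buffer_mean(r, 0.0, 150.0) == pytest.approx(1.0, abs=0.05)

    def test_point_outside_raster_raises(self):
        r = self._raster(np.zeros((10, 10)))
        with pytest.raises(ValueError, match="outside"):
            buffer_mean(r, 40.0, 150.0)

    def test_all_nodata_returns_nan(self):
        r = self._raster(np.full((200, 200), np.nan))
        assert np.isnan(buffer_mean(r, 0.0, 150.0))


class TestMedianTrend:
    def test_exact_line(self):
        years = np.arange(2003, 2023)
        assert median_trend(years, 2 * years + 1) == pytest.approx(2.0, abs=1e-6)

    def test_robust_to_gross_outlier(self):
        years = np.arange(2003, 2023).astype(float)
        vals = years.copy()
        vals[7] += 100.0
        slope = median_trend(years, vals)
        # brute-force L1 line search oracle over a slope grid
        grid = np.linspace(0.5, 1.5, 2001)
        best = min(grid, key=lambda s: np.abs(vals - (s * (years - years.mean())
                   + np.median(vals - s * (years - years.mean())))).sum())
        assert slope == pytest.approx(best, abs=0.05)
        assert abs(slope - 1.0) <= 0.05

    def test_constant_series_zero_slope(self):
        assert median_trend(range(2000, 2010), [4.2] * 10) == pytest.approx(0.0, abs=1e-8)

    def test_too_few_points(self):
        assert median_trend([2000, 2001], [1, 2]) is None


class TestFilters:
    def test_genus_below_six_per_exposure_dropped(self):
        rows = []
        for k in range(6):
            rows += [dict(genus="A", site_id=f"L{k}"), dict(genus="A", site_id=f"U{k}"),
                     dict(genus="B", site_id=f"L{k}"), dict(genus="B", site_id=f"U{k}")]
        df = _obs_table(rows)
        df["exposure"] = ["Lit", "Unlit"] * 12
        df = df.drop(df[(df.genus == "B") & (df.exposure == "Unlit")].index[:1])
        out, audit = apply_filters(df)
        assert set(out["genus"]) == {"A"}
        assert audit["genus_rule"] == 11

    def test_ex_situ_and_pre_2000_removed(self):
        df = _obs_table([dict(in_situ=False), dict(year=1999)]
                        + [dict(site_id=f"S{k}") for k in range(12)])
        df["exposure"] = (["Lit"] * 8 + ["Unlit"] * 6)
        out, audit = apply_filters(df)
        assert audit["ex_situ"] == 1 and audit["pre_2000"] == 1
        assert len(out) == 12

    def test_empty_result_raises_with_audit(self):
        df = _obs_table([dict(in_situ=False)])
        df["exposure"] = "Lit"
        with pytest.raises(ValueError, match="audit"):
            apply_filters(df)


class TestPositiveTransform:
    def test_shift_and_round_trip(self):
        y = np.array([-7, -2, 0, 4])
        yp, tr = positive_transform(y)
        assert tr.offset == -7 and yp.min() == 0
        assert np.array_equal(tr.backward(yp), y)

    def test_all_positive_input_shifted_to_zero_min(self):
        yp, tr = positive_transform([3, 5, 9])
        assert yp.min() == 0 and tr.offset == 3


class TestGlmm:
    def test_single_genus_intercept_only_matches_sample_mean(self):
        rng = np.random.default_rng(1)
        n = 400
        df = pd.DataFrame(dict(
            site_id=np.repeat([f"S{k}" for k in range(4)], n // 4),
            latitude=np.repeat([0.0, 5.0, 10.0, 15.0], n // 4),
            longitude=150.0, genus="Acropora", ecoregion="ER01",
            exposure="Unlit", dsst=0.0, dkd490=0.0, dfe=0.0,
            y=rng.poisson(6.0, n)))
        fit = fit_glmm(ModelSpec(fixed_terms=()), df)
        # with no spatial signal the intercept-only Poisson MLE is the sample mean
        assert np.exp(fit.beta[0]) == pytest.approx(df["y"].mean(), rel=1e-3)

    def test_matches_plain_glm_oracle_without_spatial_variance(self):
        import statsmodels.api as sm
        from moontrigger import GeneratorConfig, generate_dataset
        from moontrigger.synth import to_pipeline_frame
        # no spatial field and no regional intercepts: every site-level
        # structure is in the fixed terms, so sigma^2 must collapse to 0
        cfg = GeneratorConfig(seed=21, matern_sigma2=0.0, ecoregion_sd=0.0,
                              n_obs=1000, n_sites=25)
        sites, _, _, obs, _ = generate_dataset(cfg)
        df = to_pipeline_frame(obs, sites)
        df["y"], tr = positive_transform(df["dosrtnf"])
        spec = ModelSpec(fixed_terms=("ALAN", "Genus", "DfE", "ALAN:Genus"))
        fit = fit_glmm(spec, df, tr)
        X, _ = build_design(df, spec.fixed_terms)
        glm = sm.GLM(df["y"].to_numpy(), X, family=sm.families.Poisson()).fit()
        assert fit.sigma2 <= 0.05  # estimated variance collapses on null data
        assert np.all(np.abs(fit.beta - glm.params) < 2 * glm.bse)
        # with the spatial variance forced to zero the marginal likelihood
        # must coincide with the independently coded Poisson GLM
        fit0 = fit_glmm(spec, df, tr, fix_sigma2=0.0)
        assert abs(fit0.loglik - glm.llf) / abs(glm.llf) < 1e-4
        assert np.allclose(fit0.beta, glm.params, atol=1e-5)

    def test_matern_correlation_limits(self):
        d = np.array([[0.0, 100.0], [100.0, 0.0]])
        for nu in (0.5, 1.5, 2.5):
            R = matern_correlation(d, 200.0, nu)
            assert R[0, 0] == pytest.approx(1.0)
            assert 0 < R[0, 1] < 1
        # nu = 0.5 is exponential
        assert matern_correlation(np.array([[0.0, 50.0], [50.0, 0.0]]), 100.0, 0.5)[0, 1] \
            == pytest.approx(np.exp(-np.sqrt(2 * 0.5) * 50 / 100), rel=1e-9)


class TestModelSelection:
    def test_enumeration_count_matches_combinatorial_oracle(self):
        # independent count: without ALAN any subset of the 5 other mains (2^5);
        # with ALAN each of the 4 interacting covariates has 3 states
        # (absent / main only / main + interaction), Ecoregion has 2: 3^4 * 2
        assert len(enumerate_nested()) == 2**5 + 3**4 * 2  # 194

    def test_marginality_enforced(self):
        for sub in enumerate_nested():
            for t in sub:
                if ":" in t:
                    a, b = t.split(":")
                    assert a in sub and b in sub

    def test_without_marginality_count_grows(self):
        assert len(enumerate_nested(marginality=False)) == 2**10

    def test_aic_definition(self):
        fit = GLMMFit(beta=np.zeros(1), beta_se=np.zeros(1), beta_cov=np.eye(1),
                      term_names=["Intercept"], b=np.zeros(2), sigma2=0.1,
                      rho_km=100.0, nu=1.5, loglik=-100.0, n_fixed=1, n_obs=10,
                      dispersion=1.0, converged=True)
        assert fit.aic == 206.0  # -2*(-100) + 2*(1 fixed + 2 variance)

    def test_ranking_stable_under_transform_offset(self, pipeline_frame):
        df, tr, _ = pipeline_frame
        terms = ("ALAN", "Genus", "ALAN:Genus")
        ranks = []
        for extra in (0.0, 1.0):
            d2 = df.copy()
            d2["y"] = d2["y"] + extra  # offset convention shifted by one day
            tab = select_model(d2, global_terms=terms)
            ranks.append(tuple(tab["terms"].head(3)))
        assert ranks[0] == ranks[1]


class TestLrt:
    def _fit(self, ll, p, terms):
        return GLMMFit(beta=np.zeros(p), beta_se=np.zeros(p), beta_cov=np.eye(p),
                       term_names=[f"x{k}" for k in range(p)], b=np.zeros(2),
                       sigma2=0.1, rho_km=100.0, nu=1.5, loglik=ll, n_fixed=p,
                       n_obs=50, dispersion=1.0, converged=True,
                       meta={"fixed_terms": terms})

    def test_identical_models(self):
        f = self._fit(-100.0, 3, ("ALAN",))
        chi2, df, p = lrt(f, f)
        assert chi2 == 0.0 and p == 1.0

    def test_chi2_tail_value(self):
        nested = self._fit(-100.0, 1, ())
        full = self._fit(-95.0, 3, ("ALAN",))
        chi2, df, p = lrt(nested, full)
        assert chi2 == pytest.approx(10.0)
        assert df == 2
        assert p == pytest.approx(0.0067, abs=0.0005)

    def test_non_nested_rejected(self):
        a = self._fit(-100.0, 2, ("ALAN",))
        b = self._fit(-99.0, 2, ("Genus",))
        with pytest.raises(ValueError):
            lrt(a, b)


class TestGenusContrasts:
    def test_identical_arms_give_zero_difference(self):
        df = pd.DataFrame(dict(genus="Porites",
                               exposure=["Lit"] * 20 + ["Unlit"] * 20,
                               y=[4, 6] * 20))
        tab = genus_contrasts(df)
        assert tab["difference_days"].iloc[0] == pytest.approx(0.0, abs=1e-8)

    def test_recovers_two_day_shift(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(10):
            y = np.concatenate([rng.poisson(4.0, 200), rng.poisson(6.0, 200)])
            df = pd.DataFrame(dict(genus="Acropora",
                                   exposure=["Lit"] * 200 + ["Unlit"] * 200, y=y))
            d = genus_contrasts(df)["difference_days"].iloc[0]
            hits += -2.6 <= d <= -1.4
        assert hits >= 9

    def test_zero_shift_ci_covers_zero(self):
        rng = np.random.default_rng(3)
        cover = 0
        for _ in range(40):
            y = rng.poisson(5.0, 300)
            df = pd.DataFrame(dict(genus="Favites",
                                   exposure=rng.choice(["Lit", "Unlit"], 300), y=y))
            r = genus_contrasts(df).iloc[0]
            cover += r["ci95_lo"] <= 0 <= r["ci95_hi"]
        assert cover >= 33  # ~95% nominal

    def test_negative_binomial_switch_on_overdispersion(self):
        rng = np.random.default_rng(5)
        lam = rng.gamma(2.0, 3.0, 400)  # strongly overdispersed mixture
        df = pd.DataFrame(dict(genus="Galaxea",
                               exposure=rng.choice(["Lit", "Unlit"], 400),
                               y=rng.poisson(lam)))
        tab = genus_contrasts(df)
        assert tab["family"].iloc[0] == "negative_binomial"
        assert tab["dispersion"].iloc[0] > 1.5


class TestGenusShiftTable:
    def test_recovery_within_ci_on_default_conditions(self, pipeline_frame):
        df, tr, truth = pipeline_frame
        spec = ModelSpec(fixed_terms=("ALAN", "Genus", "DfE", "Ecoregion", "ALAN:Genus"))
        fit = fit_glmm(spec, df, tr)
        tab = genus_shift_table(fit, df)
        td = {g: v["delta_days"] for g, v in truth["genera"].items()}
        hits = sum(1 for _, r in tab.iterrows()
                   if r["ci95_lo"] <= td[r["genus"]] <= r["ci95_hi"])
        assert hits >= 10  # 12 genera, 95% CIs
        assert tab.loc[tab.genus == "Porites", "difference_days"].iloc[0] < -1.5
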