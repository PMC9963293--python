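"""Release regressions: standardization, effective release, CV coefficient
derivation, and small fitting checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from streamcom import (
    GeneratorConfig,
    RegressionSpec,
    derive_cv_coefficients,
    effective_release,
    fit_release_models,
    generate_regression_data,
    standardize,
)
from streamcom.release_regression import RegressionPosterior


class TestStandardize:
    def test_hand_example(self):
        out, rec = standardize(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        assert out["x"].tolist() == pytest.approx([-1.0, 0.0, 1.0])
        assert rec.loc[0, "mean"] == 2.0 and rec.loc[0, "sd"] == 1.0

    def test_idempotent(self):
        df = pd.DataFrame({"x": np.random.default_rng(0).normal(3, 2, 50)})
        once, _ = standardize(df)
        twice, _ = standardize(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_constant_column_named_in_error(self):
        with pytest.raises(ValueError, match="depth"):
            standardize(pd.DataFrame({"depth": [1.0, 1.0, 1.0]}))


class TestEffectiveRelease:
    def test_product_example(self):
        out = effective_release(np.array([0.5, 0.5]), 0.24)
        assert out == pytest.approx([0.12])

    def test_zero_release_watershed(self):
        out = effective_release(np.array([0.3, 0.3, 0.4]), 0.0)
        assert np.all(out == 0.0)

    def test_degenerate_single_site(self):
        assert effective_release(np.array([1.0, 0.0]), 0.15) == pytest.approx([0.15])

    def test_rejects_non_simplex(self):
        with pytest.raises(ValueError):
            effective_release(np.array([0.5, 0.2]), 1.0)
        with pytest.raises(ValueError):
            effective_release(np.array([1.5, -0.5]), 1.0)

    @settings(derandomize=True, max_examples=30)
    @given(n=st.integers(1, 8), seed=st.integers(0, 1000))
    def test_conserves_total(self, n, seed):
        rng = np.random.default_rng(seed)
        eta = rng.dirichlet(np.ones(n + 1))
        out = effective_release(eta, 0.2)
        assert out.sum() <= 0.2 + 1e-12  # unsurveyed slot absorbs the rest


class TestCvCoefficients:
    def _posterior(self, g_mu, g_sd):
        return RegressionPosterior(
            draws={"gamma_mu": g_mu, "gamma_sd": g_sd},
            coef_names=["release"],
            watersheds=[],
            sites=[],
        )

    def test_subtraction_and_cancellation(self):
        g_mu = np.array([[[-0.3], [0.2]]])
        g_sd = np.array([[[0.2], [0.2]]])
        cv = derive_cv_coefficients(self._posterior(g_mu, g_sd))
        assert cv["draws"][0, 0, 0] == pytest.approx(0.5)
        assert cv["draws"][0, 1, 0] == 0.0  # equal coefficients cancel exactly

    def test_exact_per_draw_difference(self, rng):
        g_mu = rng.normal(size=(2, 50, 4))
        g_sd = rng.normal(size=(2, 50, 4))
        post = RegressionPosterior(
            draws={"gamma_mu": g_mu, "gamma_sd": g_sd},
            coef_names=list("abcd"),
            watersheds=[],
            sites=[],
        )
        cv = derive_cv_coefficients(post)
        assert np.array_equal(cv["draws"], g_sd - g_mu)  # machine precision

    def test_misaligned_draws_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            derive_cv_coefficients(
                self._posterior(np.zeros((1, 3, 2)), np.zeros((1, 4, 2)))
            )


@pytest.fixture(scope="module")
def small_reg_fit():
    cfg = GeneratorConfig(n_watersheds=8, sites_per_watershed=3, seed=17)
    reg = generate_regression_data(cfg)
    spec = RegressionSpec(
        responses=("joint", "richness"),
        chains=2,
        n_warmup=400,
        n_iter=400,
        thin=4,
        seed=3,
    )
    return reg, fit_release_models(reg.site_table, reg.watershed_table, spec)


class TestFitting:
    def test_eta_draws_are_simplexes(self, small_reg_fit):
        _, post = small_reg_fit
        for w, arr in post.draws["eta_joint"].items():
            assert np.all(arr >= 0)
            assert np.allclose(arr.sum(axis=-1), 1.0)

    def test_sign_probabilities_bounded(self, small_reg_fit):
        _, post = small_reg_fit
        pr = post.sign_probability("gamma_mu")
        assert np.all((0 <= pr) & (pr <= 1))

    def test_standardization_invariance(self):
        """Doubling raw predictor scales leaves the posterior unchanged
        (predictors are standardized before fitting)."""
        cfg = GeneratorConfig(n_watersheds=5, sites_per_watershed=2, seed=23)
        reg = generate_regression_data(cfg)
        spec = RegressionSpec(
            responses=("joint",), chains=1, n_warmup=150, n_iter=150, thin=3, seed=5
        )
        post_a = fit_release_models(reg.site_table, reg.watershed_table, spec)
        scaled = reg.site_table.copy()
        for c in ("temperature", "precipitation", "forest_fraction"):
            scaled[c] = scaled[c] * 2.0 + 1.0
        post_b = fit_release_models(scaled, reg.watershed_table, spec)
        assert np.allclose(
            post_a.draws["gamma_mu"], post_b.draws["gamma_mu"], atol=1e-10
        )

    def test_richness_model_matches_glm_when_overdispersion_vanishes(self):
        """On zero-release data with almost no overdispersion or watershed
        scatter, the richness coefficients agree with an independent
        fixed-effects Poisson GLM."""
        import statsmodels.api as sm

        cfg = GeneratorConfig(
            n_watersheds=6,
            sites_per_watershed=5,
            frac_zero_release=1.0,
            sigma_lambda=0.01,
            sigma_gamma=0.01,
            gamma_prime={"richness": (0.0, 0.0), "mu": (0.0, 0.0), "sd": (0.0, 0.0)},
            seed=31,
        )
        reg = generate_regression_data(cfg)
        spec = RegressionSpec(
            responses=("richness",),
            chains=2,
            n_warmup=500,
            n_iter=500,
            thin=4,
            seed=7,
        )
        post = fit_release_models(reg.site_table, reg.watershed_table, spec)
        med = np.median(
            post.draws["gamma_richness"].reshape(-1, 6), axis=0
        )  # [release, 5 covariates]
        std_cols, _ = standardize(
            reg.site_table[
                [
                    "log_watershed_area",
                    "temperature",
                    "precipitation",
                    "forest_fraction",
                    "n_obs_years",
                ]
            ].copy()
        )
        X = sm.add_constant(std_cols)
        glm = sm.GLM(
            reg.site_table["richness"], X, family=sm.families.Poisson()
        ).fit()
        for k, name in enumerate(std_cols.columns):
            assert med[k + 1] == pytest.approx(glm.params[name], abs=0.08)

    def test_null_release_effect_has_symmetric_sign(self):
        cfg = GeneratorConfig(
            gamma1={"richness": 0.0, "mu": 0.0, "sd": 0.0},
            n_watersheds=10,
            sites_per_watershed=3,
            seed=37,
        )
        reg = generate_regression_data(cfg)
        spec = RegressionSpec(
            responses=("joint",), chains=2, n_warmup=400, n_iter=400, thin=4, seed=11
        )
        post = fit_release_models(reg.site_table, reg.watershed_table, spec)
        pr = post.sign_probability("gamma_mu")[0]
        assert 0.1 < pr < 0.9
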