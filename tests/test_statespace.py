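"""State-space density reconstruction: pure operations, likelihood oracle,
and small-scale fitting behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import poisson

from streamcom import (
    GeneratorConfig,
    StateSpaceSpec,
    bayesian_p_value,
    derive_site_summaries,
    fit_statespace,
    generate_statespace_data,
    geometric_lag_weights,
    log_likelihood,
)
from streamcom.statespace_density import StateSpacePosterior, _prepare_group_arrays


class TestGeometricLagWeights:
    @pytest.mark.parametrize(
        "tau,Q,expected",
        [
            (1.0, 3, [1 / 3, 1 / 3, 1 / 3]),
            (0.5, 3, [4 / 7, 2 / 7, 1 / 7]),
            (0.9, 1, [1.0]),
            (0.2, 1, [1.0]),
        ],
    )
    def test_examples(self, tau, Q, expected):
        assert geometric_lag_weights(tau, Q) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=40)
    @given(tau=st.floats(0.01, 1.0), Q=st.integers(1, 8))
    def test_simplex_and_monotone(self, tau, Q):
        w = geometric_lag_weights(tau, Q)
        assert w.sum() == pytest.approx(1.0)
        assert np.all(np.diff(w) <= 1e-12)
        assert np.all(w > 0)

    @pytest.mark.parametrize("tau", [0.0, -0.5, 1.5])
    def test_invalid_tau(self, tau):
        with pytest.raises(ValueError):
            geometric_lag_weights(tau, 3)


class TestLikelihood:
    def test_fry_term_composition(self):
        """lambda = n exp(eps) + beta * Fry evaluated by hand."""
        ll = log_likelihood(
            counts=np.array([[2.0]]),
            areas=np.array([[1.0]]),
            obs_mask=np.array([[True]]),
            log_density=np.array([[0.0]]),  # n = 1
            eps_obs=np.array([[0.0]]),
            fry=np.array([[0.5]]),
            beta=np.array([2.0]),
            psi=1,
        )
        assert ll == pytest.approx(poisson.logpmf(2, 2.0))

    def test_simple_poisson_case(self):
        ll = log_likelihood(
            counts=np.array([[100.0]]),
            areas=np.array([[100.0]]),
            obs_mask=np.array([[True]]),
            log_density=np.array([[0.0]]),
            eps_obs=np.array([[0.0]]),
        )
        assert ll == pytest.approx(poisson.logpmf(100, 100.0))

    def test_oracle_term_by_term(self, rng):
        """Vectorized total equals an independent loop over observations."""
        S, T = 2, 3
        U = rng.normal(-1.0, 0.5, (S, T))
        E = rng.normal(0.0, 0.2, (S, T))
        Y = rng.poisson(20.0, (S, T)).astype(float)
        A = rng.uniform(50, 200, (S, T))
        M = np.array([[True, False, True], [True, True, True]])
        fry = rng.uniform(0, 0.2, (S, T))
        beta = np.array([1.0, 0.5])
        total = log_likelihood(Y, A, M, U, E, fry, beta, psi=1)
        manual = 0.0
        for s in range(S):
            for t in range(T):
                if not M[s, t]:
                    continue
                lam = np.exp(U[s, t] + E[s, t]) + beta[s] * fry[s, t]
                manual += poisson.logpmf(Y[s, t], lam * A[s, t])
        assert total == pytest.approx(manual, rel=1e-12)

    def test_missing_years_contribute_nothing(self, rng):
        Y = np.array([[5.0, 99.0]])
        A = np.ones((1, 2)) * 10
        U = np.zeros((1, 2))
        E = np.zeros((1, 2))
        m1 = np.array([[True, False]])
        m2 = np.array([[True, True]])
        assert log_likelihood(Y, A, m1, U, E) != log_likelihood(Y, A, m2, U, E)
        assert log_likelihood(Y, A, m1, U, E) == pytest.approx(
            poisson.logpmf(5, 10.0)
        )


def _constant_posterior(sites, watersheds, years, dens, group):
    """Minimal posterior whose median density is constant per site."""
    S, T = len(sites), len(years)
    u = np.log(np.tile(np.asarray(dens)[:, None], (1, T)))
    draws = {"log_density": np.tile(u, (2, 5, 1, 1))}
    data = {"M": np.ones((S, T), dtype=bool), "Y": np.ones((S, T)), "A": np.ones((S, T)), "fry": np.zeros((S, T))}
    return StateSpacePosterior(
        draws=draws,
        sites=sites,
        watersheds=watersheds,
        years=years,
        group=group,
        spec=StateSpaceSpec(group=group),
        data=data,
        converged=True,
    )


class TestSiteSummaries:
    def test_constant_series_and_additivity(self):
        sites = ["a", "b"]
        ws = ["w1", "w1"]
        years = [2000, 2001, 2002]
        pe = _constant_posterior(sites, ws, years, [0.2, 0.4], "enhanced")
        pu = _constant_posterior(sites, ws, years, [0.6, 0.1], "unenhanced")
        out = derive_site_summaries(pe, pu)
        row = out.set_index("site").loc["a"]
        assert row["cv_whole"] == pytest.approx(0.0, abs=1e-12)
        assert row["mu_whole"] == pytest.approx(0.8)
        assert row["mu_whole"] == pytest.approx(
            row["mu_enhanced"] + row["mu_unenhanced"]
        )

    def test_mismatched_sites_warn_and_drop(self):
        years = [2000, 2001]
        pe = _constant_posterior(["a", "b"], ["w", "w"], years, [0.2, 0.3], "enhanced")
        pu = _constant_posterior(["a"], ["w"], years, [0.5], "unenhanced")
        with pytest.warns(UserWarning, match="missing"):
            out = derive_site_summaries(pe, pu)
        assert list(out["site"]) == ["a"]

    def test_refuses_unconverged(self):
        years = [2000, 2001]
        pe = _constant_posterior(["a"], ["w"], years, [0.2], "enhanced")
        pu = _constant_posterior(["a"], ["w"], years, [0.5], "unenhanced")
        pe.converged = False
        with pytest.raises(RuntimeError, match="not converged"):
            derive_site_summaries(pe, pu)


@pytest.fixture(scope="module")
def small_fit():
    cfg = GeneratorConfig(
        n_watersheds=3, sites_per_watershed=2, gap_probs=((1, 1.0),), seed=8
    )
    ds = generate_statespace_data(cfg)
    spec = StateSpaceSpec(
        group="enhanced", chains=2, n_warmup=400, n_iter=400, thin=4, seed=2
    )
    return ds, fit_statespace(ds, spec)


class TestFitting:
    def test_posterior_structure(self, small_fit):
        ds, post = small_fit
        assert post.draws["tau"].shape == (2, 100)
        assert np.all(post.draws["tau"] > 0) and np.all(post.draws["tau"] < 1)
        assert np.all(post.draws["beta"] >= 0)
        assert np.all(post.draws["sigma_state"] > 0)
        med = post.median_density()
        assert (med.to_numpy() > 0).all()
        assert list(med.columns) == post.years

    def test_bayesian_p_value_bounded_and_deterministic(self, small_fit):
        _, post = small_fit
        p1 = bayesian_p_value(post, seed=3)
        p2 = bayesian_p_value(post, seed=3)
        assert 0.0 <= p1 <= 1.0
        assert p1 == p2

    def test_misfit_detected_on_overdispersed_counts(self, small_fit):
        """Injecting gross overdispersion into the observed counts pushes
        the posterior-predictive P-value toward 0."""
        ds, post = small_fit
        rigged = {k: v for k, v in post.data.items()}
        rng = np.random.default_rng(0)
        Y = rigged["Y"].copy()
        Y[rigged["M"]] = Y[rigged["M"]] * rng.choice([0.2, 5.0], Y[rigged["M"]].size)
        rigged["Y"] = Y
        import dataclasses

        worse = dataclasses.replace(post, data=rigged)
        assert bayesian_p_value(worse, seed=1) < 0.05

    def test_requires_enough_observed_years(self, small_monitoring_dataset):
        ds = small_monitoring_dataset
        thin = ds.counts.copy()
        first_site = thin["site"].iloc[0]
        mask = (thin["site"] == first_site) & (thin["year"] > 2002)
        thin.loc[mask, "count"] = np.nan
        import dataclasses

        broken = dataclasses.replace(ds, counts=thin)
        with pytest.raises(ValueError, match="observed years"):
            fit_statespace(broken, StateSpaceSpec(group="enhanced"))

    def test_sparse_data_leaves_tau_vague(self):
        """With very few observed transitions the lag-decay parameter
        stays close to its flat prior (sd of Beta(1,1) is 0.289)."""
        cfg = GeneratorConfig(
            n_watersheds=2,
            sites_per_watershed=1,
            gap_probs=((3, 1.0),),
            seed=4,
        )
        ds = generate_statespace_data(cfg)
        spec = StateSpaceSpec(
            group="unenhanced", chains=2, n_warmup=300, n_iter=300, thin=3, seed=0
        )
        post = fit_statespace(ds, spec)
        assert post.draws["tau"].std() > 0.15

    def test_imputation_consistency(self):
        """Dropping 20% of observed years perturbs derived site CVs by a
        bounded amount (the posterior imputes the gaps)."""
        cfg = GeneratorConfig(
            n_watersheds=3, sites_per_watershed=2, gap_probs=((1, 1.0),), seed=13
        )
        ds = generate_statespace_data(cfg)

        def cv_of(dataset, seed):
            pe = fit_statespace(
                dataset,
                StateSpaceSpec(
                    group="enhanced", chains=2, n_warmup=400, n_iter=400, thin=4, seed=seed
                ),
            )
            pu = fit_statespace(
                dataset,
                StateSpaceSpec(
                    group="unenhanced", chains=2, n_warmup=400, n_iter=400, thin=4, seed=seed
                ),
            )
            out = derive_site_summaries(pe, pu, require_converged=False)
            return out.set_index("site")["cv_whole"]

        full = cv_of(ds, 1)
        rng = np.random.default_rng(2)
        thin = ds.counts.copy()
        obs_idx = thin.index[thin["count"].notna()]
        # drop 20% of observed site-years (both groups together)
        pairs = thin.loc[obs_idx, ["site", "year"]].drop_duplicates()
        drop = pairs.sample(frac=0.2, random_state=3)
        for _, row in drop.iterrows():
            m = (thin["site"] == row["site"]) & (thin["year"] == row["year"])
            thin.loc[m, "count"] = np.nan
        import dataclasses

        thinned = dataclasses.replace(ds, counts=thin)
        thin_cv = cv_of(thinned, 1)
        diff = (full - thin_cv).abs()
        assert diff.median() < 0.25
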