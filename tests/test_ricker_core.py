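"""Unit and property tests for the release-augmented Ricker dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from streamcom import (
    CommunityParams,
    ReleaseSchedule,
    SimProtocol,
    simulate,
    step_community,
    summarize_window,
)
from streamcom.ricker_core import _series_stats


class TestStep:
    def test_single_species_fixed_point(self, single_species):
        out = step_community(np.array([100.0]), single_species)
        assert out == pytest.approx([100.0])

    def test_single_species_below_K_grows(self, single_species):
        out = step_community(np.array([50.0]), single_species)
        assert out == pytest.approx([50.0 * np.exp(0.75)], rel=1e-12)

    def test_symmetric_two_species_equilibrium(self, symmetric_pair):
        # solving (I + alpha_off) N = K by hand gives N_i = K / (1 + a) = 80
        out = step_community(np.array([80.0, 80.0]), symmetric_pair)
        assert out == pytest.approx([80.0, 80.0])

    def test_zero_fitness_releases_never_reproduce(self):
        p = CommunityParams(r=[1.5], alpha=[[1.0]], K=[100.0], f_R=0.0)
        out = step_community(np.array([0.0]), p, R=100.0)
        assert out == pytest.approx([0.0])

    def test_release_enters_competition(self, single_species):
        # with f_R = 0 the release term only depresses growth
        p = CommunityParams(r=[1.5], alpha=[[1.0]], K=[100.0], f_R=0.0)
        no_rel = step_community(np.array([50.0]), p, R=0.0)
        for R in (10.0, 50.0, 200.0):
            with_rel = step_community(np.array([50.0]), p, R=R)
            assert with_rel < no_rel
            no_rel = with_rel  # strictly decreasing in R

    @pytest.mark.parametrize(
        "state,R",
        [(np.array([np.nan]), 0.0), (np.array([-1.0]), 0.0), (np.array([1.0]), -5.0)],
    )
    def test_invalid_inputs_rejected(self, single_species, state, R):
        with pytest.raises(ValueError):
            step_community(state, single_species, R=R)

    def test_fixed_point_for_any_r(self):
        for r in (0.3, 1.0, 2.7, 3.5):
            p = CommunityParams(r=[r], alpha=[[1.0]], K=[73.0])
            assert step_community(np.array([73.0]), p) == pytest.approx([73.0])


class TestSimulate:
    def test_deterministic_overyielding(self, symmetric_pair):
        proto = SimProtocol(T_total=300, T_init=50, T_burn=50, T_save=200)
        traj = simulate(symmetric_pair, ReleaseSchedule.constant(0.0, proto), proto)
        stats = summarize_window(traj)
        # equilibrium total 2K/(1+a) = 160 > K: overyielding
        assert stats.mu["whole"] == pytest.approx(160.0, rel=1e-6)
        assert stats.cv["whole"] == pytest.approx(0.0, abs=1e-9)
        assert stats.mu["whole"] > symmetric_pair.K[0]

    def test_oracle_naive_loop(self, rng):
        """Trajectories match an independently coded step-by-step loop."""
        S = 4
        alpha = rng.exponential(0.3, (S, S))
        np.fill_diagonal(alpha, 1.0)
        params = CommunityParams(
            r=rng.uniform(0.5, 2.5, S), alpha=alpha, K=np.full(S, 80.0)
        )
        proto = SimProtocol(
            T_total=10, T_init=3, T_burn=3, T_save=4, init_density=20.0
        )
        schedule = ReleaseSchedule.constant(40.0, proto)
        traj = simulate(params, schedule, proto, np.random.default_rng(5))

        # naive reimplementation of the map with the same noise stream
        g = np.random.default_rng(5)
        N = np.full(S, 20.0)
        for t in range(10):
            eps = np.zeros(S)  # sigma_eps = 0 in params
            R = schedule.R_t[t]
            phi = np.zeros(S)
            phi[0] = params.f_R
            nxt = np.empty(S)
            for i in range(S):
                crowd = alpha[i, 0] * R
                for j in range(S):
                    crowd += alpha[i, j] * N[j]
                nxt[i] = (N[i] + phi[i] * R) * np.exp(
                    params.r[i] * (1 - crowd / 80.0) + eps[i]
                )
            N = nxt
            assert traj.density[:, t + 1] == pytest.approx(N, rel=1e-12)

    def test_extinction_is_absorbing(self):
        p = CommunityParams(
            r=[0.5, 0.5], alpha=[[1.0, 0.9], [0.9, 1.0]], K=[100.0, 100.0]
        )
        proto = SimProtocol(
            T_total=200,
            T_init=50,
            T_burn=50,
            T_save=100,
            init_density=5.0,
            extinction_threshold=0.01,
        )
        # heavy release of species 1 drives species 2 down
        traj = simulate(p, ReleaseSchedule.constant(500.0, proto), proto)
        for i in range(2):
            if traj.extinct[i]:
                te = traj.extinction_time[i]
                assert np.all(traj.density[i, te:] == 0.0)

    def test_divergence_guard(self):
        # huge K removes density regulation; a massive release compounds
        # by exp(r) each step and crosses the divergence limit
        p = CommunityParams(r=[1.5], alpha=[[1.0]], K=[1e30])
        proto = SimProtocol(
            T_total=60, T_init=20, T_burn=20, T_save=20, init_density=50.0
        )
        traj = simulate(p, ReleaseSchedule.constant(1e11, proto), proto)
        assert traj.diverged
        assert np.all(np.isfinite(traj.density))

    def test_reseeding_occurs_during_init(self):
        p = CommunityParams(r=[0.01], alpha=[[1.0]], K=[100.0])
        proto = SimProtocol(
            T_total=40,
            T_init=30,
            T_burn=5,
            T_save=5,
            init_density=5.0,
            reseed_every=10,
            seed=3,
        )
        traj = simulate(p, ReleaseSchedule.constant(0.0, proto), proto)
        # jumps at reseeding steps: density after step 10 exceeds the map's
        # continuation because a Poisson(5) batch is added
        d = traj.density[0]
        assert d[10] > d[9] or d[20] > d[19]  # at least one visible reseed


class TestSummaries:
    def test_constant_series(self):
        cv, mu, sd = _series_stats(np.full(50, 160.0))
        assert (cv, mu, sd) == (0.0, 160.0, 0.0)

    def test_two_point_series(self):
        cv, mu, sd = _series_stats(np.array([100.0, 200.0]))
        assert mu == 150.0
        assert sd == pytest.approx(70.7107, abs=1e-3)
        assert cv == pytest.approx(0.4714, abs=1e-3)

    def test_zero_mean_cv_flagged(self, symmetric_pair):
        proto = SimProtocol(T_total=12, T_init=4, T_burn=4, T_save=4)
        traj = simulate(symmetric_pair, ReleaseSchedule.constant(0.0, proto), proto)
        traj.density[:, :] = 0.0
        stats = summarize_window(traj)
        assert stats.cv["whole"] is None
        assert stats.mu["whole"] == 0.0

    def test_persistence_threshold_strict(self, symmetric_pair):
        proto = SimProtocol(T_total=12, T_init=4, T_burn=4, T_save=4)
        traj = simulate(symmetric_pair, ReleaseSchedule.constant(0.0, proto), proto)
        traj.density[1, -2] = 0.005  # dips below 0.01 at one saved step
        stats = summarize_window(traj)
        assert stats.n_persist == 1

    @settings(derandomize=True, max_examples=30)
    @given(
        c=st.floats(0.01, 1e4),
        seed=st.integers(0, 2**16),
    )
    def test_cv_scale_invariance(self, c, seed):
        """Scaling a saved series by c > 0 leaves CV unchanged and scales
        mu and sd by c."""
        g = np.random.default_rng(seed)
        proto = SimProtocol(T_total=30, T_init=10, T_burn=10, T_save=10)
        p = CommunityParams(
            r=[1.5, 1.5],
            alpha=[[1.0, 0.25], [0.25, 1.0]],
            K=[100.0, 100.0],
            sigma_eps=0.5,
        )
        traj = simulate(p, ReleaseSchedule.constant(0.0, proto), proto, g)
        base = summarize_window(traj)
        traj.density *= c
        scaled = summarize_window(traj)
        assert scaled.cv["whole"] == pytest.approx(base.cv["whole"], rel=1e-9)
        assert scaled.mu["whole"] == pytest.approx(base.mu["whole"] * c, rel=1e-9)
        assert scaled.sd["whole"] == pytest.approx(base.sd["whole"] * c, rel=1e-9)

    def test_densities_never_negative(self, rng):
        for _ in range(5):
            S = 3
            alpha = rng.exponential(0.4, (S, S))
            np.fill_diagonal(alpha, 1.0)
            p = CommunityParams(
                r=rng.uniform(0.5, 3.0, S),
                alpha=alpha,
                K=np.full(S, 100.0),
                sigma_eps=0.5,
            )
            proto = SimProtocol(T_total=60, T_init=20, T_burn=20, T_save=20)
            traj = simulate(p, ReleaseSchedule.constant(100.0, proto), proto, rng)
            assert np.all(traj.density >= 0)
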