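import numpy as np
import pytest
from scipy.stats import expon, ks_2samp, uniform

import geogen as gg
from geogen.inference import (
    ModelConfig,
    block_names,
    free_block_indices,
    initial_state,
    log_likelihood,
    log_prior,
)


def make_cfg(priors, variant=2, n_iter=1000, thin=10):
    return ModelConfig(
        variant=variant, n_iter=n_iter, thin=thin,
        metric="euclidean", priors=priors,
    )


def reference_state(priors, K, w=None, alpha=(100.0, 1.0, 1.0)):
    return gg.MCMCState(
        alpha=np.array(alpha, dtype=float),
        eta=np.zeros(K),
        w=np.zeros(K) if w is None else np.asarray(w, dtype=float),
        G=priors.loc_centers.copy(),
        Gs=np.tile(priors.src_center, (K, 1)),
        zeta=np.zeros(3 + 4 * K),
    )


class TestLogPrior:
    def test_closed_form_oracle_at_prior_centers(self, planar_priors):
        """Hand-summed textbook log densities for a state sitting at every
        prior center (location terms vanish there)."""
        K = planar_priors.loc_centers.shape[0]
        cfg = make_cfg(planar_priors, variant=4)
        state = reference_state(planar_priors, K)
        expected = (
            expon(scale=100.0).logpdf(100.0)
            + expon(scale=1.0).logpdf(1.0)
            + uniform(0.1, 1.9).logpdf(1.0)
            + K * expon(scale=1.0).logpdf(0.0)
            # density of w at 0 when 2w ~ Beta(1, 100): 2 * 100
            + K * np.log(200.0)
        )
        assert log_prior(state, cfg) == pytest.approx(expected, rel=1e-12)

    def test_admixture_above_cap_excluded(self, planar_priors):
        K = planar_priors.loc_centers.shape[0]
        cfg = make_cfg(planar_priors, variant=4)
        state = reference_state(
            planar_priors, K, w=[0.6] + [0.0] * (K - 1)
        )
        assert log_prior(state, cfg) == -np.inf

    def test_shape_parameter_outside_uniform_support(self, planar_priors):
        K = planar_priors.loc_centers.shape[0]
        cfg = make_cfg(planar_priors, variant=4)
        state = reference_state(planar_priors, K, alpha=(100.0, 1.0, 2.5))
        assert log_prior(state, cfg) == -np.inf

    def test_restricted_to_variant_free_set(self, planar_priors):
        """Moving a fixed-parameter value must not change the prior of a
        variant in which it is fixed."""
        K = planar_priors.loc_centers.shape[0]
        cfg2 = make_cfg(planar_priors, variant=2)
        s1 = reference_state(planar_priors, K)
        s2 = reference_state(planar_priors, K)
        s2.Gs = s2.Gs + 5.0  # sources are fixed under variant 2
        assert log_prior(s1, cfg2) == log_prior(s2, cfg2)

    def test_location_term_is_gaussian_in_distance(self, planar_priors):
        K = planar_priors.loc_centers.shape[0]
        cfg = make_cfg(planar_priors, variant=2)
        s1 = reference_state(planar_priors, K)
        s2 = reference_state(planar_priors, K)
        s2.G = s2.G.copy()
        s2.G[0, 0] += 1.5
        expected_drop = -0.5 * 1.5**2 / planar_priors.loc_sd**2
        assert log_prior(s2, cfg) - log_prior(s1, cfg) == pytest.approx(
            expected_drop
        )


class TestProposals:
    def test_scalar_proposal_moments(self):
        rng = np.random.default_rng(0)
        zeta = -0.7
        draws = np.array(
            [gg.propose_scalar(3.0, zeta, rng) for _ in range(100_000)]
        )
        assert draws.mean() == pytest.approx(3.0, abs=0.02 * np.exp(zeta))
        assert draws.std() == pytest.approx(np.exp(zeta), rel=0.02)

    def test_spherical_proposal_lands_at_drawn_arc_distance(self):
        """The proposed point sits exactly the drawn arc length away,
        checked with an independently written haversine."""

        def haversine(a, b):
            lon1, lat1, lon2, lat2 = map(np.deg2rad, (*a, *b))
            h = (
                np.sin((lat2 - lat1) / 2) ** 2
                + np.cos(lat1) * np.cos(lat2)
                * np.sin((lon2 - lon1) / 2) ** 2
            )
            return 2 * np.arcsin(np.sqrt(h))

        for seed in range(25):
            rng = np.random.default_rng(seed)
            shadow = np.random.default_rng(seed)
            arc = abs(shadow.normal(0.0, np.exp(-1.0)))
            start = np.array([20.0, 45.0])
            prop = gg.propose_location(start, -1.0, rng, metric="sphere")
            assert haversine(start, prop) == pytest.approx(arc, abs=1e-10)

    def test_destination_due_north_along_meridian(self):
        from geogen._engine import destination_point

        lon, lat = destination_point(0.0, 0.0, 0.0, 0.1)
        assert np.rad2deg(lat) == pytest.approx(5.729577951, abs=1e-6)
        assert lon == pytest.approx(0.0, abs=1e-12)

    def test_zero_arc_returns_start(self):
        from geogen._engine import destination_point

        lon, lat = destination_point(0.3, -0.7, 1.234, 0.0)
        assert (lon, lat) == pytest.approx((0.3, -0.7))

    def test_longitude_wrapped(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            prop = gg.propose_location(
                np.array([179.5, 10.0]), 0.0, rng, metric="sphere"
            )
            assert -180.0 < prop[0] <= 180.0
            assert -90.0 <= prop[1] <= 90.0

    def test_planar_fallback_is_isotropic_jitter(self):
        rng = np.random.default_rng(4)
        draws = np.array(
            [
                gg.propose_location(
                    np.array([1.0, 2.0]), 0.0, rng, metric="euclidean"
                )
                for _ in range(20_000)
            ]
        )
        assert draws.mean(axis=0) == pytest.approx([1.0, 2.0], abs=0.03)
        assert draws.std(axis=0) == pytest.approx([1.0, 1.0], rel=0.05)


class TestAdaptTuning:
    def test_first_window_increment(self):
        assert gg.adapt_tuning(0.0, 0.5, 1) == pytest.approx(0.01)

    def test_late_window_uses_inverse_root(self):
        assert gg.adapt_tuning(0.0, 0.2, 40_000) == pytest.approx(-0.005)

    def test_tie_at_target_decreases(self):
        assert gg.adapt_tuning(0.0, 0.44, 1) == pytest.approx(-0.01)

    def test_clamped_to_cap(self):
        assert gg.adapt_tuning(10.0, 0.9, 1, cap=10.0) == 10.0
        assert gg.adapt_tuning(-10.0, 0.1, 1, cap=10.0) == -10.0


class TestMhStep:
    def test_degenerate_proposal_always_accepted(
        self, planar_mvn_data, planar_priors
    ):
        _, data = planar_mvn_data
        cfg = make_cfg(planar_priors, variant=2)
        rng = np.random.default_rng(0)
        state = initial_state(data, cfg, rng)
        state.zeta[:] = -30.0  # proposals indistinguishable from current
        for _ in range(100):
            state = gg.mh_step(state, data, cfg, rng)
        assert state.accept_counts.sum() == 100
        assert state.prop_counts.sum() == 100

    def test_out_of_support_proposals_rejected_but_counted(
        self, planar_mvn_data, planar_priors
    ):
        _, data = planar_mvn_data
        cfg = make_cfg(planar_priors, variant=2)
        rng = np.random.default_rng(1)
        state = initial_state(data, cfg, rng)
        # huge steps: alpha2 (uniform support) proposals almost surely leave
        # (0.1, 2]; other blocks may accept or reject, support violations
        # must leave the state unchanged while counting the proposal
        state.zeta[2] = 12.0
        a2 = state.alpha[2]
        for _ in range(200):
            state = gg.mh_step(state, data, cfg, rng)
        b = 2
        assert state.prop_counts[b] > 0
        if state.accept_counts[b] == 0:
            assert state.alpha[2] == a2
        assert 0.1 < state.alpha[2] <= 2.0

    def test_corrupted_state_rejected(self, planar_mvn_data, planar_priors):
        _, data = planar_mvn_data
        cfg = make_cfg(planar_priors, variant=2)
        rng = np.random.default_rng(2)
        state = initial_state(data, cfg, rng)
        state.log_lik = -np.inf
        with pytest.raises(ValueError, match="non-finite"):
            gg.mh_step(state, data, cfg, rng)


class TestRunMcmc:
    def test_trace_bookkeeping(self, planar_mvn_data, planar_priors):
        _, data = planar_mvn_data
        cfg = make_cfg(planar_priors, variant=2, n_iter=2500, thin=100)
        trace = gg.run_mcmc(data, cfg, seed=5)
        assert trace.n_samples == 25
        assert trace.iterations[0] == 100
        assert trace.iterations[-1] == 2500

    def test_reproducible_given_seed(self, planar_mvn_data, planar_priors):
        _, data = planar_mvn_data
        cfg = make_cfg(planar_priors, variant=2, n_iter=2000, thin=50)
        t1 = gg.run_mcmc(data, cfg, seed=11)
        t2 = gg.run_mcmc(data, cfg, seed=11)
        np.testing.assert_array_equal(t1.alpha, t2.alpha)
        np.testing.assert_array_equal(t1.G, t2.G)
        np.testing.assert_array_equal(t1.log_lik, t2.log_lik)

    def test_variant_fidelity_fixed_parameters_never_move(
        self, planar_mvn_data, planar_priors
    ):
        _, data = planar_mvn_data
        cfg = make_cfg(planar_priors, variant=2, n_iter=20_000, thin=100)
        trace = gg.run_mcmc(data, cfg, seed=6)
        assert np.all(trace.w == 0.0)  # admixture fixed at zero
        assert np.all(trace.Gs == trace.Gs[0])  # sources never updated
        cfg3 = make_cfg(planar_priors, variant=3, n_iter=20_000, thin=100)
        trace3 = gg.run_mcmc(data, cfg3, seed=6)
        assert np.all(trace3.G == trace3.G[0])  # locations fixed

    def test_stored_log_posterior_recomputable(
        self, planar_mvn_data, planar_priors
    ):
        """Every thinned sample's stored log prior/likelihood must match an
        independent Python recomputation (engine consistency check)."""
        _, data = planar_mvn_data
        cfg = make_cfg(planar_priors, variant=4, n_iter=10_000, thin=500)
        trace = gg.run_mcmc(data, cfg, seed=7)
        for i in range(trace.n_samples):
            st = trace.state_at(i)
            assert log_prior(st, cfg) == pytest.approx(
                trace.log_prior[i], abs=1e-6
            )
            assert log_likelihood(st, data, cfg) == pytest.approx(
                trace.log_lik[i], abs=1e-6, rel=1e-9
            )

    def test_python_engine_matches_contracts(
        self, planar_mvn_data, planar_priors
    ):
        _, data = planar_mvn_data
        cfg = make_cfg(planar_priors, variant=2, n_iter=1500, thin=50)
        trace = gg.run_mcmc(data, cfg, seed=8, engine="python")
        assert trace.n_samples == 30
        for i in (0, 15, 29):
            st = trace.state_at(i)
            assert log_prior(st, cfg) + log_likelihood(
                st, data, cfg
            ) == pytest.approx(trace.log_post[i], abs=1e-6, rel=1e-9)

    def test_update_blocks_override_restricts_moves(self):
        """An explicit update-block list freezes everything else."""
        rng = np.random.default_rng(42)
        K = 5
        coords = np.array(
            [[0.0, 0.0], [1.5, 0.3], [2.5, 1.8], [0.7, 2.2], [3.2, 3.0]]
        )
        locs = gg.LocationSet(coords, metric="euclidean")
        true = gg.ModelParams(
            cov=gg.CovParams(1.0, 0.8, 1.0),
            eta=np.full(K, 0.1),
            locations=locs,
            admixture=gg.AdmixtureParams(np.zeros(K), locs),
        )
        data = gg.simulate_mvn(true, np.full(K, 10.0), 1500, rng=rng)
        pri = gg.default_priors(locs)
        cfg = ModelConfig(
            variant=1, n_iter=5_000, thin=100, metric="euclidean",
            priors=pri,
        )
        init = gg.MCMCState(
            alpha=np.array([1.0, 0.5, 1.0]),
            eta=np.full(K, 0.1),
            w=np.zeros(K),
            G=coords.copy(),
            Gs=np.tile(pri.src_center, (K, 1)),
            zeta=np.zeros(3 + 4 * K),
        )
        cfg.update_blocks = np.array([1], dtype=np.int64)  # alpha1 only
        trace = gg.run_mcmc(data, cfg, init=init, seed=9)
        assert not np.all(trace.alpha[:, 1] == 0.5)  # alpha1 moves
        assert np.all(trace.alpha[:, 0] == 1.0)  # everything else frozen
        assert np.all(trace.alpha[:, 2] == 1.0)
        assert np.all(trace.eta == 0.1)


class TestProtocol:
    def test_single_short_run_degenerates_to_restart(
        self, planar_mvn_data, planar_priors
    ):
        _, data = planar_mvn_data
        cfg = make_cfg(planar_priors, variant=2, n_iter=2000, thin=100)
        trace = gg.run_protocol(
            data, cfg, n_short=1, short_len=1000, long_len=2000, seed=3
        )
        assert trace.extras["best_short_run"] == 0
        assert trace.n_samples == 20

    def test_long_run_thinned_to_prescribed_draw_count(
        self, planar_mvn_data, planar_priors
    ):
        _, data = planar_mvn_data
        cfg = make_cfg(planar_priors, variant=4, n_iter=10_000, thin=10)
        trace = gg.run_protocol(
            data, cfg, n_short=3, short_len=1000, long_len=10_000, seed=4
        )
        assert trace.n_samples == 1000

    def test_best_short_run_seeds_long_chain(
        self, planar_mvn_data, planar_priors
    ):
        _, data = planar_mvn_data
        cfg = make_cfg(planar_priors, variant=4, n_iter=3000, thin=100)
        trace = gg.run_protocol(
            data, cfg, n_short=4, short_len=2000, long_len=3000, seed=5
        )
        posts = np.asarray(trace.extras["short_final_log_posts"])
        assert trace.extras["best_short_run"] == int(np.argmax(posts))
        # admixture restarts from zero with sources at the origin
        assert posts.size == 4


class TestVariantBlocks:
    @pytest.mark.parametrize(
        "variant,n_expected",
        [(1, 3 + 8), (2, 3 + 2 * 8), (3, 3 + 3 * 8), (4, 3 + 4 * 8)],
    )
    def test_free_parameter_counts_per_variant(self, variant, n_expected):
        assert free_block_indices(variant, 8).size == n_expected

    def test_block_names_align_with_indices(self):
        names = block_names(["a", "b"])
        assert names[0] == "alpha0"
        assert names[3] == "eta_a"
        assert names[5] == "w_a"
        assert names[7] == "G_a"
        assert names[9] == "Gs_a"
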