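"""Collapsed Gibbs sampler: bookkeeping, determinism, prior recovery."""

import numpy as np
import pytest

from dcim import Concentrations, ConjugatePrior, ExpressionMatrix
from dcim.gibbs import ChainConfig, _Sampler, initialize_state, run_chain
from dcim.gibbs import _resample_dp_concentration


def _crp_expected_groups(n, conc):
    return sum(conc / (conc + i) for i in range(n))


def _batch_se(x, n_batches=20):
    """Monte-Carlo standard error of the mean via batch means."""
    x = np.asarray(x, dtype=float)
    batches = np.array_split(x, n_batches)
    means = np.array([b.mean() for b in batches])
    return means.std(ddof=1) / np.sqrt(len(means))


class TestInitialState:
    def test_singletons_one_context_identity(self, small_matrix):
        state = initialize_state(small_matrix, ChainConfig())
        assert np.array_equal(state.C, np.arange(8))
        assert np.array_equal(state.D, np.zeros(4, dtype=int))
        assert state.L.shape == (8, 1)
        assert np.array_equal(state.L[:, 0], np.arange(8))

    def test_fixed_contexts_used_verbatim(self, small_matrix):
        cfg = ChainConfig(fixed_contexts=np.array([0, 0, 1, 1]))
        state = initialize_state(small_matrix, cfg)
        assert np.array_equal(state.D, [0, 0, 1, 1])
        summary = run_chain(small_matrix, cfg.replace(n_burnin=5, n_keep=20))
        for draw_free in (summary.final_state,):
            assert np.array_equal(draw_free.D, [0, 0, 1, 1])

    def test_same_seed_identical(self, small_matrix):
        a = initialize_state(small_matrix, ChainConfig(seed=3))
        b = initialize_state(small_matrix, ChainConfig(seed=3))
        assert np.array_equal(a.C, b.C) and np.array_equal(a.D, b.D)


class TestDeterminism:
    @pytest.mark.parametrize("engine", ["numba", "numpy"])
    def test_same_seed_bit_identical_summary(self, small_matrix, engine):
        cfg = ChainConfig(n_burnin=20, n_keep=50, seed=9, engine=engine)
        s1 = run_chain(small_matrix, cfg)
        s2 = run_chain(small_matrix, cfg)
        assert np.array_equal(s1.co_gene_counts, s2.co_gene_counts)
        assert np.array_equal(s1.co_sample_counts, s2.co_sample_counts)
        assert np.array_equal(s1.final_state.C, s2.final_state.C)

    def test_count_matrix_contract(self, small_matrix):
        s = run_chain(small_matrix, ChainConfig(n_burnin=10, n_keep=30, seed=1))
        for m in (s.co_gene_counts, s.co_sample_counts):
            assert np.array_equal(m, m.T)
            assert np.all(np.diag(m) == s.n_kept)
            assert m.max() <= s.n_kept

    def test_thinning_keeps_requested_draws(self, small_matrix):
        s = run_chain(
            small_matrix,
            ChainConfig(n_burnin=5, n_keep=10, thin=3, seed=2, keep_draws=True),
        )
        assert s.n_kept == 10
        assert len(s.kept_draws) == 10


class TestSufficientStatistics:
    def test_incremental_stats_match_rebuild(self, two_block_matrix):
        cfg = ChainConfig(n_burnin=0, n_keep=1, seed=5)
        prior = ConjugatePrior.empirical(two_block_matrix)
        state = initialize_state(two_block_matrix, cfg)
        s = _Sampler(
            two_block_matrix, state, prior, Concentrations(), cfg,
            np.random.default_rng(5),
        )
        for _ in range(25):
            s.sweep()
        gn, gs1, gs2 = s.gn.copy(), s.gs1.copy(), s.gs2.copy()
        s._rebuild_global_stats()
        assert np.array_equal(gn, s.gn)
        np.testing.assert_allclose(gs1, s.gs1, atol=1e-8)
        np.testing.assert_allclose(gs2, s.gs2, atol=1e-8)

    def test_state_stays_consistent(self, two_block_matrix):
        cfg = ChainConfig(n_burnin=30, n_keep=30, seed=8, keep_draws=True)
        s = run_chain(two_block_matrix, cfg)
        for draw in s.kept_draws[::10]:
            draw.validate()


class TestPosteriorBehaviour:
    def test_identical_genes_co_cluster(self):
        """Two near-identical genes: local co-grouping is near-certain, and
        the (weakly identified) global co-clustering probability matches the
        exhaustive-posterior oracle.

        Global co-membership is not forced to 1 even for identical genes:
        with few contexts, separate global clusters merged into one local
        cluster give the same likelihood, so the global posterior is set
        largely by the CRP priors.
        """
        from _oracles import exact_cogrouping_posterior

        rng = np.random.default_rng(0)
        base = np.array([1.2, -0.8, 2.0])
        vals = np.vstack([base + rng.normal(0, 0.01, 3) for _ in range(2)])
        X = ExpressionMatrix(vals, ["a", "b"], ["s1", "s2", "s3"])
        prior = ConjugatePrior(m0=np.zeros(3), lam=1.0, a=2.0, tau=0.05)
        conc = Concentrations()
        exact_gene, _ = exact_cogrouping_posterior(vals, prior, conc)
        s = run_chain(
            X,
            ChainConfig(n_burnin=200, n_keep=2000, seed=4, track_local=True),
            prior=prior,
            conc=conc,
        )
        assert s.co_gene_counts[0, 1] / s.n_kept == pytest.approx(
            exact_gene[0, 1], abs=0.03
        )
        local = np.mean([c[0, 1] / s.n_kept for c in s.co_local_counts])
        assert local > 0.95

    def test_engines_agree_statistically(self, two_block_matrix):
        """The compiled kernel and the numpy reference target the same
        posterior: PPP estimates agree within Monte-Carlo error."""
        res = {}
        for engine in ("numba", "numpy"):
            s = run_chain(
                two_block_matrix,
                ChainConfig(n_burnin=200, n_keep=3000, seed=13, engine=engine),
            )
            res[engine] = s.co_gene_counts / s.n_kept
        assert np.abs(res["numba"] - res["numpy"]).max() < 0.05

    def test_prior_only_crp_group_counts(self, rng):
        """With the likelihood disabled the chain samples the CRP priors:
        mean cluster/context counts match the CRP expectation."""
        vals = rng.normal(size=(15, 6))
        X = ExpressionMatrix(
            vals, [f"g{i}" for i in range(15)], [f"s{j}" for j in range(6)]
        )
        conc = Concentrations(alpha=1.0, beta=1.0, phi=1.0)
        s = run_chain(
            X,
            ChainConfig(n_burnin=200, n_keep=2000, seed=6, prior_only=True,
                        keep_draws=True),
            conc=conc,
        )
        n_gene_clusters = [d.n_global for d in s.kept_draws]
        n_contexts = [d.n_contexts for d in s.kept_draws]
        for observed, n, c in (
            (n_gene_clusters, 15, conc.alpha),
            (n_contexts, 6, conc.beta),
        ):
            expected = _crp_expected_groups(n, c)
            se = max(_batch_se(observed), 1e-3)
            assert abs(np.mean(observed) - expected) < 3 * se + 0.05

    def test_single_global_cluster_forces_identity_local(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 0.05, size=(3, 4))  # all genes share one pattern
        X = ExpressionMatrix(vals, ["a", "b", "c"], [f"s{j}" for j in range(4)])
        s = run_chain(
            X, ChainConfig(n_burnin=100, n_keep=100, seed=2, keep_draws=True)
        )
        for draw in s.kept_draws:
            if draw.n_global == 1:
                assert np.all(draw.L == 0)


class TestConcentrationResampling:
    def test_disabled_returns_input(self, small_matrix):
        conc = Concentrations(alpha=1.5, beta=0.7, phi=2.0)
        s = run_chain(
            small_matrix, ChainConfig(n_burnin=5, n_keep=10, seed=3), conc=conc
        )
        f = s.final_concentrations
        assert (f.alpha, f.beta, f.phi) == (1.5, 0.7, 2.0)

    def test_enabled_stays_positive(self, small_matrix):
        s = run_chain(
            small_matrix,
            ChainConfig(n_burnin=50, n_keep=100, seed=3, resample_concentrations=True),
        )
        f = s.final_concentrations
        assert f.alpha > 0 and f.beta > 0 and f.phi > 0

    def test_one_big_group_favours_small_concentration(self):
        """Posterior draws of the concentration are stochastically smaller
        under K=1 group of n items than under n singletons."""
        rng1, rng2 = np.random.default_rng(0), np.random.default_rng(0)
        n = 50
        few = [_resample_dp_concentration(1.0, n, 1, rng1) for _ in range(2000)]
        many = [_resample_dp_concentration(1.0, n, n, rng2) for _ in range(2000)]
        assert np.mean(few) < np.mean(many) / 5
        assert min(min(few), min(many)) > 0


class TestInputValidation:
    def test_rejects_bad_fixed_contexts(self, small_matrix):
        with pytest.raises(ValueError):
            run_chain(
                small_matrix,
                ChainConfig(n_keep=5, fixed_contexts=np.array([0, 0, 1])),
            )

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ChainConfig(n_keep=0)
        with pytest.raises(ValueError):
            ChainConfig(thin=0)
        with pytest.raises(ValueError):
            ChainConfig(engine="fortran")
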