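"""Core types, CRP weights, and conjugate Gaussian marginals/predictives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from dcim import ExpressionMatrix, crp_weights
from dcim.model import (
    AllocationState,
    Concentrations,
    ConjugatePrior,
    nig_log_marginal,
    nig_log_marginal_stats,
    nig_log_predictive,
)


class TestExpressionMatrix:
    def test_valid_roundtrip(self, small_matrix):
        assert small_matrix.n_genes == 8
        assert small_matrix.n_samples == 4

    @pytest.mark.parametrize(
        "values, gene_ids, sample_ids",
        [
            (np.ones((2, 2)), ["a", "a"], ["s1", "s2"]),        # dup gene ids
            (np.ones((2, 2)), ["a", "b"], ["s", "s"]),          # dup sample ids
            (np.ones((2, 2)), ["a"], ["s1", "s2"]),             # length mismatch
            ([[1.0, np.nan], [0.0, 1.0]], ["a", "b"], ["s1", "s2"]),  # missing
        ],
    )
    def test_rejects_invalid(self, values, gene_ids, sample_ids):
        with pytest.raises(ValueError):
            ExpressionMatrix(np.asarray(values), gene_ids, sample_ids)

    def test_model_entry_needs_two_genes_and_samples(self):
        from dcim import ChainConfig, run_chain

        X = ExpressionMatrix(np.ones((1, 3)), ["g"], ["a", "b", "c"])
        with pytest.raises(ValueError, match="at least 2"):
            run_chain(X, ChainConfig(n_keep=2))

    def test_allocation_state_validate(self):
        state = AllocationState(C=[0, 1, 1], D=[0, 0], L=np.array([[0], [1]]))
        state.validate()
        bad = AllocationState(C=[0, 2, 2], D=[0, 0], L=np.array([[0], [1]]))
        with pytest.raises(ValueError):
            bad.validate()

    def test_positive_parameters_enforced(self):
        with pytest.raises(ValueError):
            ConjugatePrior(m0=[0.0], lam=-1.0)
        with pytest.raises(ValueError):
            Concentrations(alpha=0.0)


class TestCrpWeights:
    def test_direct_evaluation(self):
        np.testing.assert_allclose(crp_weights([3, 1], 1.0, 4), [0.6, 0.2, 0.2])

    def test_empty_system_forces_new_group(self):
        np.testing.assert_allclose(crp_weights([], 2.0, 0), [1.0])

    def test_small_concentration_limit(self):
        w = crp_weights([5], 1e-12, 5)
        assert w[0] == pytest.approx(1.0)
        assert w[1] == pytest.approx(0.0, abs=1e-12)

    @given(
        sizes=st.lists(st.integers(min_value=0, max_value=50), max_size=8),
        conc=st.floats(min_value=1e-3, max_value=50.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_sums_to_one(self, sizes, conc):
        w = crp_weights(sizes, conc)
        assert abs(w.sum() - 1.0) < 1e-12
        assert np.all(w >= 0)

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            crp_weights([-1, 2], 1.0)
        with pytest.raises(ValueError):
            crp_weights([1, 2], 0.0)
        with pytest.raises(ValueError):
            crp_weights([1, 2], 1.0, excluded_total=5)


def _quadrature_log_marginal(values, m0, lam, a, tau):
    def integrand(mu, s2):
        like = np.prod(stats.norm.pdf(values, mu, np.sqrt(s2)))
        prior = stats.norm.pdf(mu, m0, np.sqrt(s2 / lam)) * stats.invgamma.pdf(
            s2, a, scale=tau
        )
        return like * prior

    # sigma^2 integrated to infinity (inverse-gamma tail is heavy); the
    # Gaussian mu integral is safely truncated
    val, _ = integrate.dblquad(
        integrand, 0, np.inf, -30, 30, epsabs=1e-12, epsrel=1e-9
    )
    return np.log(val)


class TestNigMarginal:
    def test_empty_product(self):
        assert nig_log_marginal([], 0.0, 1.0, 2.0, 1.0) == 0.0

    @pytest.mark.parametrize(
        "values, m0, lam, a, tau",
        [
            ([0.7], 0.0, 1.0, 2.0, 1.0),
            ([0.7, -0.4, 1.1], 0.3, 1.2, 2.0, 0.8),
            ([2.0, 2.5], -1.0, 0.5, 3.0, 2.0),
        ],
    )
    def test_matches_quadrature(self, values, m0, lam, a, tau):
        expected = _quadrature_log_marginal(np.asarray(values), m0, lam, a, tau)
        assert nig_log_marginal(values, m0, lam, a, tau) == pytest.approx(
            expected, abs=1e-6
        )

    def test_shift_invariance(self, rng):
        vals = rng.normal(size=6)
        for c in (-3.0, 0.7, 12.0):
            assert nig_log_marginal(vals + c, 0.5 + c, 1.0, 2.0, 1.0) == pytest.approx(
                nig_log_marginal(vals, 0.5, 1.0, 2.0, 1.0), abs=1e-9
            )

    def test_permutation_invariance(self, rng):
        vals = rng.normal(size=7)
        ref = nig_log_marginal(vals, 0.0, 1.0, 2.0, 1.0)
        for _ in range(5):
            assert nig_log_marginal(
                rng.permutation(vals), 0.0, 1.0, 2.0, 1.0
            ) == pytest.approx(ref, abs=1e-12)


class TestNigPredictive:
    def test_prior_predictive_is_student_t(self):
        m0, lam, a, tau = 0.2, 1.5, 2.5, 0.9
        scale = np.sqrt(tau * (lam + 1) / (a * lam))
        for x in (-1.0, 0.0, 2.3):
            expected = stats.t.logpdf(x, df=2 * a, loc=m0, scale=scale)
            assert nig_log_predictive(x, 0, 0.0, 0.0, m0, lam, a, tau) == pytest.approx(
                expected, abs=1e-12
            )

    def test_chain_identity(self, rng):
        """marginal(S + x) - marginal(S) == predictive(x | S) to 1e-10."""
        m0, lam, a, tau = 0.1, 0.8, 2.0, 1.3
        for _ in range(20):
            s = rng.normal(size=rng.integers(0, 10))
            x = float(rng.normal())
            lhs = nig_log_marginal(np.append(s, x), m0, lam, a, tau) - nig_log_marginal(
                s, m0, lam, a, tau
            )
            rhs = nig_log_predictive(
                x, len(s), s.sum(), np.dot(s, s), m0, lam, a, tau
            )
            assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_large_n_concentrates_on_truth(self, rng):
        data = rng.normal(2.0, 0.5, size=20000)
        n, s1, s2 = len(data), data.sum(), np.dot(data, data)
        xs = np.linspace(-2, 6, 4001)
        logp = np.array(
            [nig_log_predictive(x, n, s1, s2, 0.0, 1.0, 2.0, 1.0) for x in xs]
        )
        p = np.exp(logp)
        p /= np.trapezoid(p, xs)
        mean = np.trapezoid(p * xs, xs)
        var = np.trapezoid(p * (xs - mean) ** 2, xs)
        assert mean == pytest.approx(2.0, abs=0.02)
        assert var == pytest.approx(0.25, abs=0.02)

    def test_stats_form_matches_values_form(self, rng):
        vals = rng.normal(size=5)
        direct = nig_log_marginal(vals, 0.0, 1.0, 2.0, 1.0)
        by_stats = float(
            nig_log_marginal_stats(
                len(vals), vals.sum(), np.dot(vals, vals), 0.0, 1.0, 2.0, 1.0
            )
        )
        assert by_stats == pytest.approx(direct, abs=1e-12)
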