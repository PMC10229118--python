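"""IVW estimation against independent numeric-minimizer and brute-force
oracles, plus the instrument-strength diagnostics."""

import numpy as np
import pytest
from scipy import optimize

from sparsemr.data import SnpExposureMatrix
from sparsemr.mr import (
    conditional_f,
    instrument_strength,
    ivw_mvmr,
    ivw_uvmr,
    mean_f,
    q_a_statistic,
)


def _qa_objective(beta, gamma, Gamma, se_Gamma):
    """The heterogeneity objective the IVW estimator minimises."""
    resid = Gamma - gamma @ np.atleast_1d(beta)
    return np.sum(resid**2 / se_Gamma**2)


class TestUvmr:
    def test_exact_fit(self):
        fit = ivw_uvmr([1.0, 1.0], [0.5, 0.5], [1.0, 1.0])
        assert fit.beta_hat[0] == pytest.approx(0.5, abs=1e-12)

    def test_zero_outcome_gives_zero_estimate_p_one(self):
        fit = ivw_uvmr([1.0, 2.0, 3.0], [0.0, 0.0, 0.0], [0.5, 0.5, 0.5])
        assert fit.beta_hat[0] == 0.0
        assert fit.p_values[0] == pytest.approx(1.0)

    def test_all_zero_gamma_is_error(self):
        with pytest.raises(ValueError, match="no instrument signal"):
            ivw_uvmr([0.0, 0.0], [0.1, 0.2], [1.0, 1.0])

    def test_matches_numeric_minimizer(self, rng):
        gamma = rng.normal(0.3, 0.1, 10)
        Gamma = 0.7 * gamma + rng.normal(0, 0.05, 10)
        se = rng.uniform(0.05, 0.2, 10)
        fit = ivw_uvmr(gamma, Gamma, se)
        res = optimize.minimize_scalar(
            lambda b: _qa_objective(b, gamma[:, None], Gamma, se),
            bounds=(-5, 5),
            method="bounded",
            options={"xatol": 1e-12},
        )
        assert fit.beta_hat[0] == pytest.approx(res.x, abs=1e-10)


class TestMvmr:
    def test_single_column_reduces_to_uvmr(self, rng):
        gamma = rng.normal(0.3, 0.1, 8)
        Gamma = 0.5 * gamma + rng.normal(0, 0.02, 8)
        se = rng.uniform(0.05, 0.2, 8)
        uv = ivw_uvmr(gamma, Gamma, se)
        mv = ivw_mvmr(gamma[:, None], Gamma, se)
        np.testing.assert_allclose(mv.beta_hat, uv.beta_hat, atol=1e-12)
        np.testing.assert_allclose(mv.se_beta, uv.se_beta, atol=1e-12)

    def test_orthogonal_columns_match_separate_uvmr(self):
        # two exposures instrumented by disjoint SNPs, unit weights
        gamma = np.zeros((6, 2))
        gamma[:3, 0] = [1.0, 2.0, 3.0]
        gamma[3:, 1] = [1.5, 2.5, 0.5]
        Gamma = gamma @ np.array([0.3, -0.2])
        se = np.ones(6)
        mv = ivw_mvmr(gamma, Gamma, se)
        uv0 = ivw_uvmr(gamma[:3, 0], Gamma[:3], se[:3])
        uv1 = ivw_uvmr(gamma[3:, 1], Gamma[3:], se[3:])
        assert mv.beta_hat[0] == pytest.approx(uv0.beta_hat[0], abs=1e-12)
        assert mv.beta_hat[1] == pytest.approx(uv1.beta_hat[0], abs=1e-12)

    def test_matches_numeric_minimizer(self, rng):
        p, K = 20, 3
        gamma = rng.normal(0.2, 0.15, (p, K))
        Gamma = gamma @ np.array([0.5, -0.3, 0.1]) + rng.normal(0, 0.05, p)
        se = rng.uniform(0.05, 0.3, p)
        fit = ivw_mvmr(gamma, Gamma, se)
        res = optimize.minimize(
            _qa_objective,
            np.zeros(K),
            args=(gamma, Gamma, se),
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000},
        )
        np.testing.assert_allclose(fit.beta_hat, res.x, atol=1e-8)

    def test_q_equals_weighted_rss_at_fit(self, rng):
        p, K = 15, 2
        gamma = rng.normal(0.2, 0.1, (p, K))
        Gamma = gamma @ np.array([0.4, 0.2]) + rng.normal(0, 0.1, p)
        se = rng.uniform(0.1, 0.3, p)
        fit = ivw_mvmr(gamma, Gamma, se)
        q = fit.q_statistic
        assert q.value == pytest.approx(
            _qa_objective(fit.beta_hat, gamma, Gamma, se), rel=1e-10
        )
        assert q.per_snp_contributions.sum() == pytest.approx(q.value)
        assert q.dof == p - K

    def test_rank_deficiency_raises_and_names_columns(self, rng):
        gamma = rng.normal(0.3, 0.1, (10, 2))
        gamma = np.column_stack([gamma, gamma[:, 0]])  # exact duplicate
        with pytest.raises(ValueError, match="rank deficient"):
            ivw_mvmr(gamma, rng.normal(size=10), np.full(10, 0.1))


class TestQaFullModel:
    def test_degenerate_variance_equals_simple_q(self, rng):
        p, K = 12, 2
        gamma = rng.normal(0.3, 0.1, (p, K))
        Gamma = gamma @ np.array([0.2, 0.1]) + rng.normal(0, 0.05, p)
        se_G = rng.uniform(0.1, 0.2, p)
        fit = ivw_mvmr(gamma, Gamma, se_G)
        q = q_a_statistic(fit, gamma, np.full((p, K), 1e-30), Gamma, se_G)
        assert q.value == pytest.approx(fit.q_statistic.value, rel=1e-6)

    def test_zero_beta_gives_weighted_outcome_ssq(self, rng):
        p, K = 8, 2
        gamma = rng.normal(0.3, 0.1, (p, K))
        Gamma = rng.normal(0, 0.3, p)
        se_G = rng.uniform(0.1, 0.2, p)
        fit = ivw_mvmr(gamma, Gamma, se_G)
        fit.beta_hat = np.zeros(K)
        q = q_a_statistic(fit, gamma, np.full((p, K), 0.05), Gamma, se_G)
        assert q.value == pytest.approx(np.sum(Gamma**2 / se_G**2), rel=1e-12)

    def test_matches_brute_force_summation(self, rng):
        p, K = 9, 3
        gamma = rng.normal(0.2, 0.1, (p, K))
        se_gamma = rng.uniform(0.02, 0.1, (p, K))
        Gamma = rng.normal(0, 0.3, p)
        se_G = rng.uniform(0.1, 0.2, p)
        cov = np.zeros((p, K, K))
        for j in range(p):  # valid covariance: scaled outer product
            a = rng.uniform(0.1, 0.5, K) * se_gamma[j]
            cov[j] = 0.3 * np.outer(a, a)
            np.fill_diagonal(cov[j], se_gamma[j] ** 2)
        fit = ivw_mvmr(gamma, Gamma, se_G)
        beta = fit.beta_hat
        expected = 0.0
        for j in range(p):
            var = se_G[j] ** 2 + sum(
                beta[k] ** 2 * se_gamma[j, k] ** 2 for k in range(K)
            )
            for k in range(K):
                for l in range(K):
                    if l != k:
                        var += beta[l] * beta[k] * cov[j, l, k]
            expected += (Gamma[j] - gamma[j] @ beta) ** 2 / var
        q = q_a_statistic(fit, gamma, se_gamma, Gamma, se_G, covariances=cov)
        assert q.value == pytest.approx(expected, rel=1e-10)


class TestMeanF:
    def test_constant_ratio(self):
        assert mean_f([3.0, 3.0, 3.0], [1.0, 1.0, 1.0]) == pytest.approx(9.0)

    def test_direct_arithmetic(self):
        assert mean_f([1.0, 2.0], [1.0, 1.0]) == pytest.approx(2.5)

    def test_matches_elementwise_oracle_and_scale_invariance(self, rng):
        gamma = rng.normal(0, 0.3, 25)
        se = rng.uniform(0.01, 0.1, 25)
        expected = sum((g / s) ** 2 for g, s in zip(gamma, se)) / 25
        assert mean_f(gamma, se) == pytest.approx(expected, rel=1e-12)
        assert mean_f(3.7 * gamma, 3.7 * se) == pytest.approx(expected, rel=1e-12)


class TestConditionalF:
    def test_duplicate_columns_give_near_zero_cfs(self, rng):
        p = 10
        col = rng.normal(0.4, 0.1, p)
        gamma = np.column_stack([col, col])
        se = np.full((p, 2), 0.05)
        ex = SnpExposureMatrix(
            [f"s{i}" for i in range(p)], ["a", "b"], gamma, se
        )
        cfs, q_x, delta = conditional_f(ex, 0)
        assert delta[0] == pytest.approx(1.0, abs=1e-8)
        assert cfs == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_column_closed_form(self):
        # column 0 orthogonal to column 1, unit SEs: delta = 0 and
        # CFS = sum gamma^2 / (p - K + 1)
        gamma = np.zeros((6, 2))
        gamma[:3, 0] = [1.0, 2.0, 2.0]
        gamma[3:, 1] = [1.0, 1.0, 1.0]
        se = np.ones((6, 2))
        ex = SnpExposureMatrix([f"s{i}" for i in range(6)], ["a", "b"], gamma, se)
        cfs, _, delta = conditional_f(ex, 0)
        assert delta[0] == pytest.approx(0.0, abs=1e-12)
        assert cfs == pytest.approx((1 + 4 + 4) / (6 - 1), rel=1e-12)

    def test_matches_brute_force(self, rng):
        p, K = 12, 3
        gamma = rng.normal(0.3, 0.15, (p, K))
        se = rng.uniform(0.02, 0.1, (p, K))
        ex = SnpExposureMatrix(
            [f"s{i}" for i in range(p)], ["a", "b", "c"], gamma, se
        )
        k = 1
        others = [0, 2]
        delta = np.linalg.lstsq(gamma[:, others], gamma[:, k], rcond=None)[0]
        expected = 0.0
        for j in range(p):
            resid = gamma[j, k] - sum(
                delta[i] * gamma[j, m] for i, m in enumerate(others)
            )
            var = se[j, k] ** 2 + sum(
                delta[i] ** 2 * se[j, m] ** 2 for i, m in enumerate(others)
            )
            expected += resid**2 / var
        cfs, q_x, _ = conditional_f(ex, k)
        assert q_x == pytest.approx(expected, rel=1e-10)
        assert cfs == pytest.approx(expected / (p - (K - 1)), rel=1e-10)

    def test_undefined_when_too_few_snps(self, rng):
        gamma = rng.normal(0.3, 0.1, (3, 4))
        se = np.full((3, 4), 0.05)
        ex = SnpExposureMatrix(["a", "b", "c"], list("wxyz"), gamma, se)
        with pytest.raises(ValueError, match="CFS undefined"):
            conditional_f(ex, 0)

    def test_cfs_decreases_as_columns_align(self, rng):
        """CFS is monotone decreasing toward 0 along a one-parameter family
        of increasingly collinear two-column matrices."""
        p = 30
        base = rng.normal(0.4, 0.05, p)
        noise = rng.normal(0, 1.0, p)
        values = []
        for mix in (0.8, 0.4, 0.2, 0.05):
            gamma = np.column_stack([base + mix * noise, base])
            se = np.full((p, 2), 0.05)
            ex = SnpExposureMatrix(
                [f"s{i}" for i in range(p)], ["a", "b"], gamma, se
            )
            values.append(conditional_f(ex, 0)[0])
        assert all(a > b for a, b in zip(values, values[1:]))
        assert values[-1] < values[0] / 10


def test_instrument_strength_table(small_exposures):
    st = instrument_strength(small_exposures)
    assert st.mean_f.shape == (3,)
    assert np.all(st.mean_f >= 0)
    assert np.all(st.q_x >= 0)
    frame = st.to_frame()
    assert list(frame.columns) == ["exposure", "mean_F", "CFS", "Q_X"]


class TestIvwProperties:
    """Algebraic invariants checked over generated instances."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    def _instance(seed, p):
        r = np.random.default_rng(seed)
        gamma = r.uniform(0.1, 1.0, p) * r.choice([-1, 1], p)
        Gamma = r.normal(0, 1.0, p)
        se = r.uniform(0.05, 0.5, p)
        return gamma, Gamma, se

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 30))
    def test_uvmr_estimate_is_convex_combination_of_wald_ratios(self, seed, p):
        """With nonzero instrument effects the IVW slope is a weighted mean
        of the per-SNP Wald ratios, hence bounded by their extremes."""
        gamma, Gamma, se = self._instance(seed, p)
        fit = ivw_uvmr(gamma, Gamma, se)
        ratios = Gamma / gamma
        assert ratios.min() - 1e-9 <= fit.beta_hat[0] <= ratios.max() + 1e-9

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 30), st.floats(0.1, 10.0))
    def test_mean_f_invariant_to_common_rescaling(self, seed, p, c):
        gamma, _, se = self._instance(seed, p)
        assert mean_f(c * gamma, c * se) == pytest.approx(
            mean_f(gamma, se), rel=1e-9
        )
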