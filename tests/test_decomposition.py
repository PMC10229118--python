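"""Factorization oracles: eigen-decomposition cross-checks, penalty limits,
best-subset enumeration for sparse loadings, and rotation invariants."""

from itertools import combinations

import numpy as np
import pytest

from sparsemr.data import SnpExposureMatrix
from sparsemr.decomposition import (
    PrincipalComponents,
    SparseComponentAnalysis,
    SparseConfig,
    ZouSparsePCA,
    pca,
    sca,
    spca_zou,
)


def _as_exposures(gamma, se=0.05):
    p, K = gamma.shape
    return SnpExposureMatrix(
        [f"s{i}" for i in range(p)],
        [f"x{k}" for k in range(K)],
        gamma,
        np.full((p, K), se),
    )


class TestPca:
    def test_already_diagonal_case(self):
        gamma = np.zeros((4, 2))
        gamma[:2, 0] = [2.0 / np.sqrt(2)] * 2  # column norm 2
        gamma[2:, 1] = [1.0 / np.sqrt(2)] * 2  # column norm 1
        dec = pca(_as_exposures(gamma), 2)
        np.testing.assert_allclose(np.abs(dec.loadings), np.eye(2), atol=1e-12)
        est = PrincipalComponents(n_components=2).fit(gamma)
        np.testing.assert_allclose(est.singular_values_, [2.0, 1.0], rtol=1e-12)

    def test_frobenius_conservation(self, rng):
        gamma = rng.normal(size=(9, 4))
        est = PrincipalComponents(n_components=4).fit(gamma)
        assert np.sum(est.singular_values_**2) == pytest.approx(
            np.sum(gamma**2), rel=1e-10
        )

    def test_matches_eigh_oracle(self, rng):
        gamma = rng.normal(size=(20, 5))
        dec = pca(_as_exposures(gamma), 5)
        w, v = np.linalg.eigh(gamma.T @ gamma)
        order = np.argsort(w)[::-1]
        v = v[:, order]
        for k in range(5):
            cos = abs(v[:, k] @ dec.loadings[:, k])
            assert cos == pytest.approx(1.0, abs=1e-10)

    def test_score_columns_orthogonal(self, rng):
        gamma = rng.normal(size=(30, 6))
        dec = pca(_as_exposures(gamma), 4)
        g = dec.scores.T @ dec.scores
        off = g - np.diag(np.diag(g))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.abs(g))

    def test_m_out_of_range(self, rng):
        gamma = rng.normal(size=(6, 3))
        with pytest.raises(ValueError):
            pca(_as_exposures(gamma), 4)
        with pytest.raises(ValueError):
            pca(_as_exposures(gamma), 0)


class TestZouSparsePCA:
    def test_penalty_free_limit_equals_pca(self, rng):
        gamma = rng.normal(size=(15, 5))
        dec_pca = pca(_as_exposures(gamma), 3)
        cfg = SparseConfig(lambda1=0.0, lambda2=0.0, n_components_requested=3)
        dec_sp = spca_zou(_as_exposures(gamma), cfg)
        for k in range(3):
            cos = abs(dec_pca.loadings[:, k] @ dec_sp.loadings[:, k])
            assert cos == pytest.approx(1.0, abs=1e-6)

    def test_total_shrinkage_under_huge_lambda1(self, rng):
        gamma = rng.normal(size=(10, 4))
        lam = 1e6 * np.max(np.linalg.norm(gamma, axis=0))
        cfg = SparseConfig(lambda1=lam, n_components_requested=2)
        with pytest.warns(UserWarning, match="zero"):
            dec = spca_zou(_as_exposures(gamma), cfg)
        assert np.all(dec.loadings == 0.0)

    def test_cardinality_concentrates_in_blocks_vs_best_subset(self, rng):
        # two-block 12 x 6 matrix: each component should pick one block, and
        # its 3-variable subset should explain nearly the best-subset variance
        gamma = rng.normal(0, 0.05, size=(12, 6))
        gamma[:6, :3] += rng.normal(1.0, 0.1, size=(6, 3))
        gamma[6:, 3:] += rng.normal(1.0, 0.1, size=(6, 3))
        cfg = SparseConfig(per_component_cardinality=3, n_components_requested=2)
        dec = spca_zou(_as_exposures(gamma), cfg)
        for k in range(2):
            nz = np.nonzero(dec.loadings[:, k])[0]
            assert len(nz) <= 3
            assert set(nz) <= {0, 1, 2} or set(nz) <= {3, 4, 5}
        # exhaustive best-subset oracle for cardinality-3 single components
        def best_subset_variance():
            best = 0.0
            for subset in combinations(range(6), 3):
                sub = gamma[:, subset]
                s = np.linalg.svd(sub, compute_uv=False)
                best = max(best, s[0] ** 2)
            return best

        explained = max(
            np.sum((gamma @ dec.loadings[:, k]) ** 2) for k in range(2)
        )
        assert explained >= 0.95 * best_subset_variance()

    def test_objective_non_increasing(self, rng):
        gamma = rng.normal(size=(20, 6))
        est = ZouSparsePCA(n_components=3, lambda1=0.5, lambda2=0.1).fit(gamma)
        path = est.objective_path_
        assert np.all(np.diff(path) <= 1e-8 * np.abs(path[:-1]) + 1e-10)

    def test_deterministic(self, rng):
        gamma = rng.normal(size=(12, 5))
        cfg = SparseConfig(per_component_cardinality=2, n_components_requested=2)
        d1 = spca_zou(_as_exposures(gamma), cfg)
        d2 = spca_zou(_as_exposures(gamma), cfg)
        np.testing.assert_array_equal(d1.loadings, d2.loadings)


class TestSca:
    def test_block_separation(self, two_block_exposures):
        dec = sca(two_block_exposures, 2)
        for k in range(2):
            nz = set(np.nonzero(dec.loadings[:, k])[0])
            assert nz <= {0, 1, 2} or nz <= {3, 4, 5}
        assert dec.sparsity_fraction >= 0.5

    def test_zero_threshold_spans_pca_subspace(self, rng):
        gamma = rng.normal(size=(25, 6))
        dec = sca(_as_exposures(gamma), 3, threshold=0.0)
        _, _, vt = np.linalg.svd(gamma, full_matrices=False)
        # principal angles between the two 3-dim subspaces
        s = np.linalg.svd(vt[:3] @ dec.loadings, compute_uv=False)
        assert np.min(s) == pytest.approx(1.0, abs=1e-8)

    def test_subspace_variance_conserved(self, rng):
        gamma = rng.normal(size=(30, 8))
        est = SparseComponentAnalysis(n_components=3).fit(gamma)
        s = np.linalg.svd(gamma, compute_uv=False)
        assert est.subspace_variance_ == pytest.approx(
            np.sum(s[:3] ** 2), rel=1e-10
        )
        assert np.mean(est.components_ == 0) > 0.0

    def test_excessive_threshold_is_error(self, rng):
        gamma = rng.normal(size=(10, 4))
        with pytest.raises(ValueError, match="threshold"):
            sca(_as_exposures(gamma), 2, threshold=10.0)


class TestCrossMethodProperties:
    @pytest.mark.parametrize("method", ["pca", "spca", "sca"])
    def test_scores_equal_gamma_times_loadings(self, method, two_block_exposures):
        if method == "pca":
            dec = pca(two_block_exposures, 2)
        elif method == "spca":
            dec = spca_zou(
                two_block_exposures,
                SparseConfig(per_component_cardinality=3, n_components_requested=2),
            )
        else:
            dec = sca(two_block_exposures, 2)
        np.testing.assert_allclose(
            dec.scores, two_block_exposures.gamma @ dec.loadings, atol=1e-12
        )

    @pytest.mark.parametrize("method", ["spca", "sca"])
    def test_two_block_dominant_loading_structure(self, method, two_block_exposures):
        """Each exposure loads dominantly on exactly one of the two leading
        sparse components."""
        if method == "spca":
            dec = spca_zou(
                two_block_exposures,
                SparseConfig(per_component_cardinality=3, n_components_requested=2),
            )
        else:
            dec = sca(two_block_exposures, 2)
        dominant = np.argmax(np.abs(dec.loadings), axis=1)
        assert len(set(dominant[:3])) == 1
        assert len(set(dominant[3:])) == 1
        assert dominant[0] != dominant[3]

    def test_sign_convention(self, rng):
        gamma = rng.normal(size=(14, 4))
        for dec in (pca(_as_exposures(gamma), 3), sca(_as_exposures(gamma), 3)):
            for k in range(dec.n_components):
                col = dec.loadings[:, k]
                if np.any(col):
                    assert col[np.argmax(np.abs(col))] > 0
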