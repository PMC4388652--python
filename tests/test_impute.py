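"""Neighbor weighting, imputation, and the induced covariance structure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from depimpute import (
    PairedExpressionSet,
    ValidationError,
    choose_k,
    impute,
    induced_sigma,
    knn_impute_paired,
    neighbor_weights,
)


def make_distance(n, rng=None, missing=()):
    """Random symmetric zero-diagonal distance matrix."""
    rng = rng or np.random.default_rng(0)
    D = rng.uniform(0.05, 1.0, size=(n, n))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    mask = np.zeros(n, bool)
    mask[list(missing)] = True
    return D, mask


class TestNeighborWeights:
    def test_k1_weight_is_one(self, rng):
        D, mask = make_distance(6, rng, missing=[0])
        nw = neighbor_weights(D, mask, k=1)
        assert nw.a[0].tolist() == [1.0]

    def test_hand_example_quarter_weights(self):
        # distances to observed subjects (1, 3, 4); k=2 -> w = (1-1/4, 1-3/4)
        D = np.zeros((4, 4))
        D[0, 1:] = D[1:, 0] = [1.0, 3.0, 4.0]
        D[1, 2] = D[2, 1] = D[1, 3] = D[3, 1] = D[2, 3] = D[3, 2] = 2.0
        mask = np.array([True, False, False, False])
        nw = neighbor_weights(D, mask, k=2)
        np.testing.assert_allclose(nw.raw_w[0], [0.75, 0.25])
        np.testing.assert_allclose(nw.a[0], [0.75, 0.25])
        assert nw.neighbors[0].tolist() == [1, 2]

    def test_equidistant_neighbors_share_weight(self):
        D = np.zeros((4, 4))
        D[0, 1:] = D[1:, 0] = [2.0, 2.0, 5.0]
        mask = np.array([True, False, False, False])
        nw = neighbor_weights(D, mask, k=2)
        np.testing.assert_allclose(nw.a[0], [0.5, 0.5])

    def test_farthest_neighbor_gets_zero_weight_when_k_equals_all(self):
        D = np.zeros((4, 4))
        D[0, 1:] = D[1:, 0] = [1.0, 2.0, 4.0]
        mask = np.array([True, False, False, False])
        nw = neighbor_weights(D, mask, k=3)
        assert nw.raw_w[0][-1] == 0.0
        assert nw.a[0][-1] == 0.0
        np.testing.assert_allclose(nw.a[0].sum(), 1.0, atol=1e-12)

    def test_k_larger_than_observed_rejected(self):
        D, mask = make_distance(5, missing=[0, 1])
        with pytest.raises(ValidationError, match="k=4"):
            neighbor_weights(D, mask, k=4)

    def test_zero_distance_everywhere_gives_uniform_weights(self):
        D = np.zeros((4, 4))
        mask = np.array([True, False, False, False])
        nw = neighbor_weights(D, mask, k=3)
        np.testing.assert_allclose(nw.a[0], [1 / 3] * 3)

    def test_tie_at_k_boundary_keeps_stable_subject_order(self):
        D = np.zeros((5, 5))
        D[0, 1:] = D[1:, 0] = [1.0, 2.0, 2.0, 3.0]
        mask = np.array([True, False, False, False, False])
        nw = neighbor_weights(D, mask, k=2)
        assert nw.neighbors[0].tolist() == [1, 2]  # subject 2 kept over tied subject 3

    @given(st.integers(1, 9), st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_weights_always_convex(self, k, seed):
        rng = np.random.default_rng(seed)
        D, mask = make_distance(12, rng, missing=[0, 5])
        nw = neighbor_weights(D, mask, k=k)
        assert (nw.a >= 0).all()
        np.testing.assert_allclose(nw.a.sum(axis=1), 1.0, atol=1e-12)

    def test_choose_k_rounds_sqrt_to_nearest_odd(self):
        assert choose_k(100) == 9  # sqrt 10 -> nearest odd 9 or 11; 10-9 < 11-10
        assert choose_k(9) == 3
        assert choose_k(2) == 1
        assert choose_k(170) == 13


def _paired(normal, missing):
    normal = np.asarray(normal, float)
    n, g = normal.shape
    masked = normal.copy()
    masked[list(missing)] = np.nan
    return PairedExpressionSet.from_matrices(
        masked, np.zeros((n, g)), [f"s{i}" for i in range(n)], [f"g{j}" for j in range(g)]
    )


class TestImpute:
    def test_constant_neighbors_reproduce_value(self):
        pes = _paired(np.full((4, 3), 7.0), missing=[1])
        D, mask = make_distance(4, missing=[1])
        nw = neighbor_weights(D, pes.missing_mask, k=2)
        res = impute(pes, nw)
        np.testing.assert_allclose(res.completed_normal[1], 7.0)

    def test_hand_arithmetic(self):
        normal = np.array([[10.0], [0.0], [20.0], [5.0]])
        pes = _paired(normal, missing=[1])
        D = np.zeros((4, 4))
        D[1, [0, 2, 3]] = D[[0, 2, 3], 1] = [1.0, 3.0, 4.0]
        nw = neighbor_weights(D, pes.missing_mask, k=2)
        res = impute(pes, nw)  # weights (0.75, 0.25) on values (10, 20)
        assert res.completed_normal[1, 0] == pytest.approx(12.5)

    def test_loop_equals_matrix_form(self, rng):
        normal = rng.normal(2, 1.25, size=(8, 5))
        pes = _paired(normal, missing=[2, 6])
        D, _ = make_distance(8, rng)
        nw = neighbor_weights(D, pes.missing_mask, k=3)
        res = impute(pes, nw)
        X_obs = normal[pes.observed_idx]
        np.testing.assert_allclose(
            res.completed_normal[pes.missing_idx], res.A.T @ X_obs, atol=1e-10
        )

    def test_observed_rows_bit_identical(self, rng):
        normal = rng.normal(size=(6, 4))
        pes = _paired(normal, missing=[0])
        D, _ = make_distance(6, rng)
        res = impute(pes, neighbor_weights(D, pes.missing_mask, k=2))
        np.testing.assert_array_equal(res.completed_normal[1:], normal[1:])

    def test_imputed_values_within_neighbor_range(self, rng):
        normal = rng.normal(size=(10, 6))
        pes = _paired(normal, missing=[3])
        D, _ = make_distance(10, rng)
        nw = neighbor_weights(D, pes.missing_mask, k=4)
        res = impute(pes, nw)
        vals = normal[nw.neighbors[0]]
        assert (res.completed_normal[3] >= vals.min(axis=0) - 1e-12).all()
        assert (res.completed_normal[3] <= vals.max(axis=0) + 1e-12).all()

    def test_permutation_equivariance(self, rng):
        normal = rng.normal(size=(9, 4))
        tumor = rng.normal(size=(9, 4))
        missing = [1, 7]
        masked = normal.copy()
        masked[missing] = np.nan
        ids = [f"s{i}" for i in range(9)]
        feats = [f"g{j}" for j in range(4)]
        cont = rng.normal(size=(9, 3))
        binary = rng.integers(0, 2, size=(9, 2)).astype(float)
        from depimpute import CovariateTable

        def run(perm):
            pes = PairedExpressionSet.from_matrices(
                masked[perm], tumor[perm], [ids[i] for i in perm], feats
            )
            cov = CovariateTable(cont[perm], binary[perm], ["a", "b", "c"], ["x", "y"],
                                 [ids[i] for i in perm])
            return knn_impute_paired(pes, cov, k=3).completed_normal

        base = run(np.arange(9))
        perm = rng.permutation(9)
        permuted = run(perm)
        inv = np.argsort(perm)
        np.testing.assert_allclose(permuted[inv], base, atol=1e-10)


class TestInducedSigma:
    def test_no_missingness_gives_identity(self):
        D, mask = make_distance(5)
        nw = neighbor_weights(D, mask, k=2)
        sigma, order = induced_sigma(nw, 5)
        np.testing.assert_array_equal(sigma, np.eye(5))
        assert order.tolist() == [0, 1, 2, 3, 4]

    def test_hand_block_example(self):
        # S=1 of N=3, weights (0.6, 0.4) at the two observed subjects
        D = np.zeros((3, 3))
        D[2, :2] = D[:2, 2] = [1.0, 3.0]  # Dmax 3 -> w=(2/3, 0); force via custom a
        mask = np.array([False, False, True])
        nw = neighbor_weights(D, mask, k=2)
        nw.a[0] = [0.6, 0.4]
        sigma, order = induced_sigma(nw, 3)
        np.testing.assert_allclose(sigma[:2, :2], np.eye(2))
        np.testing.assert_allclose(sigma[:2, 2], [0.6, 0.4])
        np.testing.assert_allclose(sigma[2, 2], 0.36 + 0.16)
        assert order.tolist() == [0, 1, 2]

    def test_gram_block_psd_and_diag_bounded(self, rng):
        for seed in range(20):
            r = np.random.default_rng(seed)
            D, mask = make_distance(12, r, missing=[0, 4, 9])
            nw = neighbor_weights(D, mask, k=4)
            sigma, _ = induced_sigma(nw, 12)
            np.testing.assert_allclose(sigma, sigma.T, atol=1e-12)
            gram = sigma[9:, 9:]
            assert np.linalg.eigvalsh(gram).min() >= -1e-10
            assert (np.diag(gram) <= 1 + 1e-12).all()

    def test_column_sums_of_A_exactly_one(self, rng):
        D, mask = make_distance(10, rng, missing=[2, 3])
        nw = neighbor_weights(D, mask, k=5)
        pes = _paired(rng.normal(size=(10, 3)), missing=[2, 3])
        res = impute(pes, nw)
        np.testing.assert_allclose(res.A.sum(axis=0), 1.0, atol=1e-12)
        assert all((res.A[:, j] > 0).sum() <= nw.k for j in range(res.A.shape[1]))
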