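"""Kernel construction: worked toy matrices, algebraic identities, guards."""

import numpy as np
import pandas as pd
import pytest

from rumenblup import (
    RelationshipMatrix,
    assign_clusters,
    build_grm,
    build_mrm,
    build_mrm_multipop,
    hadamard_interaction,
    log_relative_abundance,
    tune,
)
from rumenblup.kernels import is_psd

from conftest import random_psd


class TestGRM:
    def test_single_snp_toy(self):
        # dosages [0,1,2]: p=0.5, denominator 2*0.25=0.5
        G = build_grm(np.array([[0], [1], [2]]))
        np.testing.assert_allclose(
            G.values, [[2, 0, -2], [0, 0, 0], [-2, 0, 2]], atol=1e-12
        )

    def test_row_sums_zero(self, small_study):
        G = build_grm(small_study.genotypes)
        assert np.abs(G.values.sum(axis=1)).max() < 1e-10

    def test_duplicated_animals_symmetric(self, rng):
        Q = rng.binomial(2, 0.3, size=(5, 40))
        Q[1] = Q[0]
        G = build_grm(Q).values
        np.testing.assert_allclose(G[0], G[1], atol=1e-12)
        assert G[0, 0] == pytest.approx(G[1, 1])

    def test_monomorphic_only_errors(self):
        with pytest.raises(ZeroDivisionError):
            build_grm(np.zeros((4, 3)))

    def test_missing_dosages_refused(self):
        Q = np.array([[0.0, np.nan], [1.0, 2.0]])
        with pytest.raises(ValueError, match="missing"):
            build_grm(Q)


class TestLogRelativeAbundance:
    def test_all_zero_row_uniform(self):
        S = log_relative_abundance(np.zeros((1, 10), dtype=int))
        np.testing.assert_allclose(S.to_numpy(), np.log10(1 / 10), atol=1e-12)

    def test_worked_row(self):
        S = log_relative_abundance(np.array([[9, 0, 0]]))
        expected = np.log10(np.array([10, 1, 1]) / 12.0)
        np.testing.assert_allclose(S.to_numpy()[0], expected, atol=1e-12)

    def test_rows_back_transform_to_one(self, small_study):
        S = log_relative_abundance(small_study.orf_counts)
        sums = np.power(10.0, S.to_numpy()).sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)
        assert (S.to_numpy() <= 0).all()

    def test_negative_counts_refused(self):
        with pytest.raises(ValueError):
            log_relative_abundance(np.array([[1, -1]]))


class TestMRM:
    def test_method2_toy(self, toy_S):
        M2 = build_mrm(toy_S, 2)
        np.testing.assert_allclose(
            M2.values, [[1, 0, -1], [0, 0, 0], [-1, 0, 1]], atol=1e-12
        )
        assert np.trace(M2.values) == pytest.approx(2.0)  # n - 1

    def test_method1_toy(self, toy_S):
        M1 = build_mrm(toy_S, 1)
        np.testing.assert_allclose(
            M1.values, [[1, 0, -1], [0, 0, 0], [-1, 0, 1]], atol=1e-12
        )

    def test_unit_weights_match_unweighted(self, rng):
        S = rng.standard_normal((12, 30))
        M = build_mrm(S, 1).values
        MW = build_mrm(S, 1, weights=np.ones(30)).values
        np.testing.assert_allclose(M, MW, atol=1e-12)

    def test_methods_agree_under_equal_variances(self, rng):
        # scale columns to a common sample variance: M1 == M2 exactly
        S = rng.standard_normal((15, 25))
        S = (S - S.mean(axis=0)) / S.std(axis=0, ddof=1)
        np.testing.assert_allclose(
            build_mrm(S, 1).values, build_mrm(S, 2).values, atol=1e-10
        )

    @pytest.mark.parametrize("method", [1, 2])
    def test_trace_and_psd_invariants(self, small_study, method):
        from rumenblup import log_relative_abundance

        S = log_relative_abundance(small_study.orf_counts)
        M = build_mrm(S, method)
        n = M.n
        assert np.trace(M.values) == pytest.approx(n - 1, rel=1e-10)
        assert is_psd(M.values)
        if method == 1:
            assert np.abs(M.values.sum(axis=1)).max() < 1e-9

    def test_zero_variance_column_method2_errors(self):
        S = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with pytest.raises(ZeroDivisionError):
            build_mrm(S, 2)
        build_mrm(S, 1)  # method 1 tolerates it

    def test_permutation_equivariance(self, rng):
        S = rng.standard_normal((10, 20))
        perm = rng.permutation(10)
        M = build_mrm(S, 2).values
        Mp = build_mrm(S[perm], 2).values
        np.testing.assert_allclose(Mp, M[np.ix_(perm, perm)], atol=1e-10)


class TestClustersAndMultipop:
    def test_well_separated_blobs_recovered(self, rng):
        S = rng.standard_normal((20, 40))
        S[10:, :20] += 10.0  # 10-SD separation on half the ORFs
        labels = assign_clusters(S, k=2, seed=0)
        truth = np.repeat([1, 2], 10)
        agree = max(
            (labels == truth).mean(), (labels == (3 - truth)).mean()
        )
        assert agree == 1.0

    def test_k_one_degenerate(self, rng):
        labels = assign_clusters(rng.standard_normal((8, 10)), k=1, seed=0)
        assert (labels == 1).all()

    def test_deterministic_under_seed(self, rng):
        S = rng.standard_normal((30, 15))
        a = assign_clusters(S, k=2, seed=7)
        b = assign_clusters(S, k=2, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_k_exceeding_n_errors(self, rng):
        with pytest.raises(ValueError):
            assign_clusters(rng.standard_normal((3, 5)), k=5, seed=0)

    @pytest.mark.parametrize("method", [1, 2])
    def test_single_cluster_reduces_to_single_population(self, rng, method):
        S = rng.standard_normal((12, 30))
        labels = np.ones(12, dtype=int)
        M = build_mrm(S, method).values
        MP = build_mrm_multipop(S, method, labels).values
        np.testing.assert_allclose(MP, M, atol=1e-10)

    def test_method2_diagonal_blocks_trace(self, rng):
        S = rng.standard_normal((20, 50))
        labels = np.repeat([1, 2], 10)
        MP = build_mrm_multipop(S, 2, labels).values
        for idx in (slice(0, 10), slice(10, 20)):
            assert np.trace(MP[idx, idx]) == pytest.approx(9, rel=1e-10)  # n_c - 1

    def test_identical_distributions_cross_block_consistency(self, rng):
        # two clusters drawn from the same distribution: cross blocks
        # approximate the single-population values at large n
        S = rng.standard_normal((400, 60))
        labels = np.repeat([1, 2], 200)
        MP = build_mrm_multipop(S, 1, labels).values
        M = build_mrm(S, 1).values
        cross_err = np.abs(MP[:200, 200:] - M[:200, 200:]).mean()
        scale = np.abs(M[:200, 200:]).mean()
        assert cross_err < 0.2 * max(scale, 0.01) + 0.005

    def test_animal_order_preserved(self, rng):
        S = rng.standard_normal((10, 20))
        labels = np.array([1, 2, 1, 2, 1, 2, 1, 2, 1, 2])
        MP = build_mrm_multipop(S, 2, labels).values
        # permuting animals permutes the kernel identically
        perm = rng.permutation(10)
        MPp = build_mrm_multipop(S[perm], 2, labels[perm]).values
        np.testing.assert_allclose(MPp, MP[np.ix_(perm, perm)], atol=1e-10)

    def test_singleton_cluster_errors(self, rng):
        S = rng.standard_normal((5, 10))
        with pytest.raises(ValueError, match="fewer than 2"):
            build_mrm_multipop(S, 1, np.array([1, 1, 1, 1, 2]))


class TestHadamardAndTune:
    def test_worked_toy_product(self, toy_S):
        G = build_grm(np.array([[0], [1], [2]]))
        M = build_mrm(toy_S, 1)
        J = hadamard_interaction(G, M)
        np.testing.assert_allclose(
            J.values, [[2, 0, 2], [0, 0, 0], [2, 0, 2]], atol=1e-12
        )

    def test_identity_masks_offdiagonal(self, rng):
        G = RelationshipMatrix(random_psd(6, rng), kind="G")
        M = RelationshipMatrix(np.eye(6), kind="M1")
        J = hadamard_interaction(G, M)
        np.testing.assert_allclose(J.values, np.diag(np.diag(G.values)))

    def test_schur_product_stays_psd(self, rng):
        A = random_psd(15, rng)
        B = random_psd(15, rng)
        J = A * B
        assert np.linalg.eigvalsh(J).min() >= -1e-8

    def test_tuned_inputs_refused(self, rng):
        G = RelationshipMatrix(random_psd(5, rng), kind="G")
        M = RelationshipMatrix(random_psd(5, rng), kind="M1")
        with pytest.raises(ValueError, match="untuned"):
            hadamard_interaction(tune(G), M)

    def test_tune_adds_epsilon(self):
        A = RelationshipMatrix(np.eye(2), kind="G")
        T = tune(A, 0.001)
        np.testing.assert_allclose(np.diag(T.values), 1.001)
        assert T.tuned

    def test_tune_makes_singular_toy_invertible(self, toy_S):
        M = build_mrm(toy_S, 1)
        assert np.linalg.det(M.values) == pytest.approx(0.0, abs=1e-12)
        T = tune(M)
        assert np.linalg.det(T.values) > 0

    def test_double_tuning_refused(self):
        A = tune(RelationshipMatrix(np.eye(3), kind="G"))
        with pytest.raises(ValueError, match="already tuned"):
            tune(A)

    def test_nonpositive_epsilon_refused(self):
        with pytest.raises(ValueError):
            tune(RelationshipMatrix(np.eye(3), kind="G"), epsilon=0.0)
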