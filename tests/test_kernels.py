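import numpy as np
import pytest

from lmmgmm.io import split_train_test
from lmmgmm.kernels import (
    KernelConfig,
    Standardizer,
    _make_kernel,
    build_cross_kernels,
    build_kernel_set,
    interaction_kernel,
    linear_kernel,
)
from conftest import random_psd


class TestLinearKernel:
    def test_identity_rows_no_standardization(self):
        K = linear_kernel(np.eye(2), standardize=False).matrix
        np.testing.assert_allclose(K, 0.5 * np.eye(2))

    def test_all_ones_no_standardization(self):
        K = linear_kernel(np.ones((3, 30)), standardize=False).matrix
        np.testing.assert_allclose(K, np.ones((3, 3)))

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 4))
        K = linear_kernel(X).matrix
        Xs = (X - X.mean(0)) / X.std(0)
        expected = np.empty((6, 6))
        for i in range(6):
            for j in range(6):
                expected[i, j] = sum(Xs[i, k] * Xs[j, k] for k in range(4)) / 4
        np.testing.assert_allclose(K, expected, atol=1e-12)

    def test_constant_column_centered_only(self):
        X = np.column_stack([np.full(5, 3.0), np.arange(5.0)])
        K = linear_kernel(X).matrix  # constant column contributes zero after centering
        Xs = np.column_stack([np.zeros(5), (np.arange(5.0) - 2.0) / np.std(np.arange(5.0))])
        np.testing.assert_allclose(K, Xs @ Xs.T / 2, atol=1e-12)

    def test_empty_feature_matrix_errors(self):
        with pytest.raises(ValueError):
            linear_kernel(np.empty((4, 0)))

    def test_diag_mean_near_one_after_standardization(self):
        rng = np.random.default_rng(8)
        K = linear_kernel(rng.normal(size=(50, 20))).matrix
        assert abs(np.trace(K) / 50 - 1.0) < 1e-10  # population std => exactly n


class TestInteractionKernel:
    def test_hadamard_identity_with_ones(self):
        rng = np.random.default_rng(1)
        Kg = linear_kernel(rng.normal(size=(5, 3)))
        ones = _make_kernel(np.ones((5, 2)), KernelConfig(standardize=False),
                            layer="methylation", region_id="")
        out = interaction_kernel(Kg, ones)
        np.testing.assert_allclose(out.matrix, Kg.matrix)

    def test_psd_preserved(self):
        rng = np.random.default_rng(2)
        from lmmgmm.kernels import Kernel

        Kg = Kernel(random_psd(rng, 8), "genomic", "r")
        Km = Kernel(random_psd(rng, 8), "methylation", "r")
        out = interaction_kernel(Kg, Km)
        w = np.linalg.eigvalsh(out.matrix)
        assert w[0] >= -1e-8 * w[-1]

    def test_dimension_mismatch_errors(self):
        from lmmgmm.kernels import Kernel

        with pytest.raises(ValueError):
            interaction_kernel(Kernel(np.eye(3), "genomic", "r"),
                               Kernel(np.eye(4), "methylation", "r"))


class TestKernelSet:
    def test_counts_and_order(self, small_sim):
        _, ds, _ = small_sim
        ks = build_kernel_set(ds, KernelConfig(interactions=True))
        assert len(ks) == 3 * 4  # 4 regions x (genomic, methylation, interaction)
        layers = [k.layer for k in ks.kernels]
        assert layers == ["genomic"] * 4 + ["methylation"] * 4 + ["interaction"] * 4

    def test_interactions_off(self, small_sim):
        _, ds, _ = small_sim
        ks = build_kernel_set(ds, KernelConfig(interactions=False))
        assert len(ks) == 8

    def test_linear_kernel_matches_standardized_product(self, small_sim):
        _, ds, _ = small_sim
        ks = build_kernel_set(ds)
        k0 = ks.kernels[0]
        X = ds.G_blocks[k0.region_id]
        Xs = Standardizer.fit(X).transform(X)
        np.testing.assert_allclose(k0.matrix, Xs @ Xs.T / X.shape[1], atol=1e-12)

    def test_feature_order_invariance(self, small_sim):
        _, ds, _ = small_sim
        import copy

        ds2 = copy.deepcopy(ds)
        r = next(iter(ds2.G_blocks))
        ds2.G_blocks[r] = ds2.G_blocks[r][:, ::-1]
        a = build_kernel_set(ds).kernels[0].matrix
        b = build_kernel_set(ds2).kernels[0].matrix
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_all_kernels_symmetric_psd(self, small_sim):
        _, ds, _ = small_sim
        for k in build_kernel_set(ds, KernelConfig(interactions=True)).kernels:
            k.check()


class TestGaussianKernel:
    def test_large_bandwidth_limit_is_all_ones(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 5))
        K = _make_kernel(X, KernelConfig(family="gaussian", bandwidth=1e8)).matrix
        np.testing.assert_allclose(K, np.ones((6, 6)), atol=1e-6)


class TestCrossKernels:
    def test_test_equals_train_duplicates_kernel(self, small_sim):
        _, ds, _ = small_sim
        ks = build_kernel_set(ds, KernelConfig(interactions=True))
        K_po, K_pp = build_cross_kernels(ds, ds, ks)
        for k, po, pp in zip(ks.kernels, K_po, K_pp):
            np.testing.assert_allclose(po, k.matrix, atol=1e-10)
            np.testing.assert_allclose(pp, k.matrix, atol=1e-10)

    def test_stacked_then_sliced_oracle(self, small_sim):
        """Blockwise cross-kernels equal computing the kernel on stacked
        (test, train) rows with train standardization and slicing."""
        _, ds, _ = small_sim
        tr, te = split_train_test(ds, 0.7, seed=2)
        ks = build_kernel_set(tr, KernelConfig(interactions=True))
        K_po, K_pp = build_cross_kernels(tr, te, ks)
        for k, po, pp in zip(ks.kernels, K_po, K_pp):
            if k.layer == "interaction":
                continue
            blocks = tr.G_blocks if k.layer == "genomic" else tr.M_blocks
            blocks_te = te.G_blocks if k.layer == "genomic" else te.M_blocks
            std = ks.standardizers[(k.layer, k.region_id)]
            stacked = std.transform(
                np.vstack([blocks_te[k.region_id], blocks[k.region_id]])
            )
            full = stacked @ stacked.T / stacked.shape[1]
            np.testing.assert_allclose(po, full[: te.n, te.n:], atol=1e-12)
            np.testing.assert_allclose(pp, full[: te.n, : te.n], atol=1e-12)

    def test_feature_mismatch_errors(self, small_sim):
        _, ds, _ = small_sim
        tr, te = split_train_test(ds, 0.7, seed=2)
        ks = build_kernel_set(tr)
        r = next(iter(te.G_blocks))
        te.G_blocks[r] = te.G_blocks[r][:, :-1]
        with pytest.raises(ValueError, match=r):
            build_cross_kernels(tr, te, ks)
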