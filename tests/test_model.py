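import numpy as np
import pytest

from lmmgmm.gls import FixedEffects
from lmmgmm.gmm import VarianceComponents
from lmmgmm.io import OmicsDataset, RegionMap, split_train_test
from lmmgmm.kernels import KernelConfig, build_kernel_set
from lmmgmm.model import FitConfig, MultiKernelLMM, fit, load_model, predict, save_model, select_lambdas
from lmmgmm.simulate import SimulationConfig, simulate_dataset


def genomic_only_dataset(n=12, p=6, seed=0):
    rng = np.random.default_rng(seed)
    G = rng.normal(size=(n, p))
    rm = RegionMap([(f"snp{j}", "genomic", "r1") for j in range(p)])
    return OmicsDataset(
        sample_ids=[f"s{i}" for i in range(n)],
        Y=rng.normal(size=n),
        X_d=np.empty((n, 0)),
        covariate_names=[],
        E=np.empty((n, 0)),
        expression_regions=[],
        G_blocks={"r1": G},
        M_blocks={},
        region_map=rm,
    )


def manual_model(train, sigma0_sq, sigma_sq=1.0, center=True):
    ks = build_kernel_set(train, KernelConfig())
    K = ks.kernels[0].matrix
    Sigma = sigma_sq * K + sigma0_sq * np.eye(train.n)
    # intercept absorbs the mean: the centered kernel spans only mean-zero modes
    mu = float(train.Y.mean()) if center else 0.0
    fixed = FixedEffects(
        beta_d=np.array([mu]), gamma=np.empty(0), residual=train.Y - mu
    )
    return MultiKernelLMM(
        variance=VarianceComponents(sigma0_sq=sigma0_sq, sigma_sq=np.array([sigma_sq])),
        fixed=fixed,
        kernel_set=ks,
        Sigma=Sigma,
        e_standardizer=None,
        train=train,
        lambdas=(0.0, 0.0),
    )


class TestPredict:
    def test_no_random_effects_gives_fixed_part(self, small_sim):
        _, ds, _ = small_sim
        tr, te = split_train_test(ds, 0.7, seed=0)
        model = fit(tr, None, FitConfig(lambda1_grid=[1e12], lambda2_grid=[1e12],
                                        selection_rule="fixed", seed=1))
        assert model.variance.support.size == 0
        pred = predict(model, te)
        fixed_part = np.full(te.n, model.fixed.beta_d[0])
        np.testing.assert_allclose(pred, fixed_part, atol=1e-10)

    def test_blup_interpolation_limit(self):
        """With sigma0 -> 0 and a duplicated sample, the conditional mean
        reproduces the duplicated training outcome (kriging interpolation)."""
        train = genomic_only_dataset(n=10, p=40, seed=3)
        model = manual_model(train, sigma0_sq=1e-8)
        test = train.subset(np.array([4]))
        pred = predict(model, test)
        assert pred[0] == pytest.approx(train.Y[4], abs=1e-5)

    def test_three_sample_hand_oracle(self):
        train = genomic_only_dataset(n=3, p=4, seed=5)
        model = manual_model(train, sigma0_sq=0.5, sigma_sq=2.0, center=False)
        test = genomic_only_dataset(n=2, p=4, seed=6)
        from lmmgmm.kernels import build_cross_kernels

        K_po, _ = build_cross_kernels(train, test, model.kernel_set)
        expected = 2.0 * K_po[0] @ np.linalg.solve(model.Sigma, train.Y)
        pred = predict(model, test)
        np.testing.assert_allclose(pred, expected, atol=1e-10)

    def test_missing_region_in_test_errors(self):
        train = genomic_only_dataset(n=10, p=5)
        model = manual_model(train, sigma0_sq=1.0)
        test = genomic_only_dataset(n=4, p=5, seed=9)
        test.G_blocks = {}
        with pytest.raises(ValueError, match="r1"):
            predict(model, test)


class TestFit:
    def test_null_data_selects_nothing(self):
        config = SimulationConfig(
            n=100, R=3, n_assoc=1, p_g=6, p_m=6, disease_model="independent_EGM",
            gamma_expr=1.0, sigma_g_sq=0.3, sigma_m_sq=0.3, sigma0_sq=1.0, seed=21,
        )
        ds, _ = simulate_dataset(config)
        rng = np.random.default_rng(0)
        ds.Y = rng.normal(0.0, 2.0, size=ds.n)  # overwrite with pure noise
        # adequate penalties (the data-derived maxima) null every term exactly
        model = fit(ds, None, FitConfig(seed=2, selection_rule="fixed"))
        assert model.variance.support.size == 0
        assert np.all(model.fixed.gamma == 0.0)
        assert model.variance.sigma0_sq == pytest.approx(np.var(ds.Y), rel=0.15)

    def test_signal_region_recovered(self):
        config = SimulationConfig(
            n=200, R=4, n_assoc=1, p_g=10, p_m=10, disease_model="S2_G",
            sigma_g_sq=3.0, sigma0_sq=1.0, seed=7,
        )
        ds, truth = simulate_dataset(config)
        model = fit(ds, None, FitConfig(seed=3))
        assert truth.associative_regions <= model.selected_regions["genomic"]

    def test_sigma_reconstruction_invariant(self, small_sim):
        _, ds, _ = small_sim
        model = fit(ds, None, FitConfig(seed=4))
        recon = model.variance.sigma0_sq * np.eye(ds.n)
        for k, kern in zip(model.variance.sigma_sq, model.kernel_set.kernels):
            recon += k * kern.matrix
        np.testing.assert_allclose(model.Sigma, recon, atol=1e-10)

    def test_in_sample_smoother_never_hurts(self, small_sim):
        _, ds, _ = small_sim
        model = fit(ds, None, FitConfig(seed=5))
        pred = predict(model, ds)
        X_full = np.column_stack([np.ones(ds.n), ds.X_d])
        fixed_part = X_full @ model.fixed.beta_d + ds.E @ model.fixed.gamma
        assert np.mean((ds.Y - pred) ** 2) <= np.mean((ds.Y - fixed_part) ** 2) + 1e-10

    def test_bitwise_determinism(self, small_sim):
        _, ds, _ = small_sim
        a = fit(ds, None, FitConfig(seed=6))
        b = fit(ds, None, FitConfig(seed=6))
        assert a.lambdas == b.lambdas
        np.testing.assert_array_equal(a.fixed.beta_d, b.fixed.beta_d)
        np.testing.assert_array_equal(a.fixed.gamma, b.fixed.gamma)
        np.testing.assert_array_equal(a.variance.sigma_sq, b.variance.sigma_sq)

    def test_empty_model_errors(self):
        ds = genomic_only_dataset()
        ds.G_blocks = {}
        with pytest.raises(ValueError, match="nothing to fit"):
            fit(ds, None, FitConfig(seed=0))


class TestSelectLambdas:
    def test_single_pair_grid_returned(self, small_sim):
        _, ds, _ = small_sim
        lam1, lam2, table = select_lambdas(
            ds, None, FitConfig(lambda1_grid=[0.7], lambda2_grid=[0.3], seed=1)
        )
        assert (lam1, lam2) == (0.7, 0.3)
        assert len(table) == 1

    def test_chosen_pair_is_table_argmin(self, small_sim):
        _, ds, _ = small_sim
        fc = FitConfig(seed=2, n_lambda=3)
        lam1, lam2, table = select_lambdas(ds, None, fc)
        best = table.loc[table.val_mse.idxmin()]
        assert table.val_mse.min() == table[
            (table.lambda1 == lam1) & (table.lambda2 == lam2)
        ].val_mse.iloc[0]
        assert best.val_mse == table.val_mse.min()


class TestSerialization:
    def test_save_load_round_trip_predictions(self, small_sim, tmp_path):
        _, ds, _ = small_sim
        tr, te = split_train_test(ds, 0.7, seed=1)
        model = fit(tr, KernelConfig(interactions=True), FitConfig(seed=7))
        path = str(tmp_path / "model.npz")
        save_model(model, path)
        loaded = load_model(path)
        np.testing.assert_allclose(predict(loaded, te), predict(model, te), atol=1e-10)
        assert loaded.lambdas == model.lambdas
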