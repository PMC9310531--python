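import numpy as np
import pytest

from lmmgmm.gmm import solve_gmm
from lmmgmm.kernels import KernelConfig, KernelSet, build_kernel_set
from lmmgmm.simulate import (
    ACTIVE_LAYERS,
    SimulationConfig,
    load_default_effects,
    scenario_grid,
    simulate_dataset,
    simulate_genotypes,
)


class TestSimulateGenotypes:
    def test_shapes_values_polymorphic(self):
        rng = np.random.default_rng(0)
        G = simulate_genotypes(500, 30, (0.05, 0.5), rng)
        assert G.shape == (500, 30)
        assert set(np.unique(G)) <= {0.0, 1.0, 2.0}
        assert np.all(G.min(axis=0) != G.max(axis=0))

    def test_symmetric_maf_mean_near_one(self):
        rng = np.random.default_rng(1)
        G = simulate_genotypes(2000, 10, (0.5, 0.5), rng)
        se = np.sqrt(0.5 * 0.5 / (2 * 2000))
        assert np.all(np.abs(G.mean(axis=0) - 1.0) < 2 * 3 * se)

    def test_allele_frequency_recovers_maf(self):
        rng = np.random.default_rng(2)
        n = 10_000
        G = simulate_genotypes(n, 20, (0.3, 0.3), rng)
        se = np.sqrt(0.3 * 0.7 / (2 * n))
        assert np.all(np.abs(G.mean(axis=0) / 2 - 0.3) < 3 * se + 1e-12)

    def test_extreme_maf_exhausts_retries(self):
        rng = np.random.default_rng(3)
        with pytest.raises(RuntimeError, match="polymorphic"):
            simulate_genotypes(2, 5, (1e-9, 1e-9), rng, max_retries=3)


class TestSimulateDataset:
    def test_dimensions_and_truth(self):
        config = SimulationConfig(
            n=60, R=10, disease_model="independent_EGM",
            gamma_expr=2.0, sigma_g_sq=0.275, sigma_m_sq=0.275, sigma0_sq=2.0, seed=5,
        )
        ds, truth = simulate_dataset(config)
        assert ds.n == 60
        assert ds.E.shape == (60, 10)
        assert len(ds.G_blocks) == 10 and all(m.shape[1] == 30 for m in ds.G_blocks.values())
        assert len(ds.M_blocks) == 10 and all(m.shape[1] == 30 for m in ds.M_blocks.values())
        assert truth.associative_regions == {"region_01", "region_02", "region_03"}

    def test_seed_determinism(self):
        config = SimulationConfig(
            n=30, R=3, n_assoc=1, p_g=5, p_m=5, disease_model="S2_G",
            sigma_g_sq=1.0, sigma0_sq=1.0, seed=11,
        )
        a, _ = simulate_dataset(config)
        b, _ = simulate_dataset(config)
        np.testing.assert_array_equal(a.Y, b.Y)
        np.testing.assert_array_equal(a.E, b.E)
        np.testing.assert_array_equal(a.G_blocks["region_1"], b.G_blocks["region_1"])

    def test_standardized_residual_is_white(self):
        """Y - mean, whitened by the documented covariance reconstructed
        independently in the test, must be iid standard normal."""
        from lmmgmm.kernels import Standardizer

        zs = []
        for seed in range(300):
            config = SimulationConfig(
                n=12, R=2, n_assoc=1, p_g=5, p_m=5, disease_model="S5_G_plus_M",
                sigma_g_sq=0.8, sigma_m_sq=0.6, sigma0_sq=0.5, seed=seed,
            )
            ds, _ = simulate_dataset(config)
            cov = 0.5 * np.eye(12)
            for blocks, s2 in ((ds.G_blocks, 0.8), (ds.M_blocks, 0.6)):
                X = blocks["region_1"]
                Xs = Standardizer.fit(X).transform(X)
                cov += s2 * (Xs @ Xs.T) / X.shape[1]
            L = np.linalg.cholesky(cov + 1e-12 * np.eye(12))
            zs.append(np.linalg.solve(L, ds.Y))
        z = np.concatenate(zs)
        assert abs(z.mean()) < 3 / np.sqrt(z.size)
        assert abs(z.var() - 1.0) < 3 * np.sqrt(2.0 / z.size)

    def test_total_variance_matches_budget(self):
        config = SimulationConfig(
            n=3000, R=3, disease_model="independent_EGM",
            gamma_expr=2.0, sigma_g_sq=0.275, sigma_m_sq=0.275, sigma0_sq=2.0, seed=13,
        )
        ds, truth = simulate_dataset(config)
        target = 3 * 4 / 12 + 3 * 2 * 0.275 + 2.0
        assert np.var(ds.Y) == pytest.approx(target, rel=0.1)
        assert sum(truth.variance_fractions.values()) == pytest.approx(1.0)

    def test_interaction_only_model_has_no_marginal_main_effects(self):
        """Main-effect kernels absorb far less of the S4 covariance than the
        interaction kernels themselves (unpenalized moment fit comparison)."""
        config = SimulationConfig(
            n=250, R=2, n_assoc=2, p_g=10, p_m=10, disease_model="S4_GM",
            sigma_gm_sq=3.0, sigma0_sq=0.5, seed=17,
        )
        ds, _ = simulate_dataset(config)
        Z = ds.Y - ds.Y.mean()
        S = np.outer(Z, Z)
        full = build_kernel_set(ds, KernelConfig(interactions=True))
        mains = KernelSet(kernels=[k for k in full.kernels if k.layer != "interaction"])
        inters = KernelSet(kernels=[k for k in full.kernels if k.layer == "interaction"])
        fit_main = solve_gmm(S, mains, lambda1=0.0)
        fit_inter = solve_gmm(S, inters, lambda1=0.0)
        assert fit_inter.sigma_sq.sum() > 2 * fit_main.sigma_sq.sum()

    def test_zero_budget_for_active_layer_rejected(self):
        with pytest.raises(ValueError, match="sigma_m_sq"):
            SimulationConfig(n=10, R=2, n_assoc=1, disease_model="S3_M",
                             sigma_m_sq=0.0, sigma0_sq=1.0)


class TestScenarioGrid:
    def test_scenario_one_region_counts(self):
        configs = scenario_grid("I", n=500)
        assert [c.R for c in configs] == [10, 25, 50, 75, 100]
        assert all(c.n_assoc == 3 for c in configs)
        assert all(c.disease_model == "independent_EGM" for c in configs)

    def test_scenario_two_has_seven_models(self):
        configs = scenario_grid("II", n=500)
        assert len(configs) == 7
        assert all(c.R == 50 for c in configs)
        assert [c.disease_model for c in configs] == [
            "S1_E", "S2_G", "S3_M", "S4_GM", "S5_G_plus_M", "S6_E_plus_G", "S7_E_plus_M"
        ]

    def test_every_config_validates_and_budget_is_constant(self):
        effects = load_default_effects()
        total = effects["signal_variance"]
        for c in scenario_grid("II"):
            active = ACTIVE_LAYERS[c.disease_model]
            s = 0.0
            if "expression" in active:
                s += c.n_assoc * c.gamma_expr**2 / 12
            if "genomic" in active:
                s += c.n_assoc * c.sigma_g_sq
            if "methylation" in active:
                s += c.n_assoc * c.sigma_m_sq
            if "interaction" in active:
                s += c.n_assoc * c.sigma_gm_sq
            assert s == pytest.approx(total, rel=1e-3)
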