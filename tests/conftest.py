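import numpy as np
import pandas as pd
import pytest

from lmmgmm.io import OmicsDataset, RegionMap
from lmmgmm.simulate import SimulationConfig, simulate_dataset


def write_toy_files(tmp_path, drop_sample_from=None, corrupt_genotype=False):
    """5-sample toy cohort: 2 regions x 3 SNPs, 2 regions x 2 CpGs, 2 genes."""
    rng = np.random.default_rng(17)
    ids = [f"s{i}" for i in range(1, 6)]
    idx = pd.Index(ids, name="sample_id")
    files = {}

    files["outcome"] = pd.DataFrame({"Y": rng.normal(size=5)}, index=idx)
    files["covariates"] = pd.DataFrame({"age": rng.uniform(40, 80, 5)}, index=idx)
    snps = [f"r{r}_snp{j}" for r in (1, 2) for j in (1, 2, 3)]
    files["genotype"] = pd.DataFrame(
        rng.integers(0, 3, size=(5, 6)).astype(float), index=idx, columns=snps
    )
    cpgs = [f"r{r}_cpg{j}" for r in (1, 2) for j in (1, 2)]
    files["methylation"] = pd.DataFrame(
        rng.uniform(size=(5, 4)), index=idx, columns=cpgs
    )
    files["expression"] = pd.DataFrame(
        rng.uniform(size=(5, 2)), index=idx, columns=["gene1", "gene2"]
    )
    entries = (
        [(s, "genomic", f"r{s[1]}") for s in snps]
        + [(c, "methylation", f"r{c[1]}") for c in cpgs]
        + [("gene1", "expression", "r1"), ("gene2", "expression", "r2")]
    )
    region_map = pd.DataFrame(entries, columns=["feature_id", "layer", "region_id"])

    if drop_sample_from is not None:
        files[drop_sample_from] = files[drop_sample_from].iloc[1:]
    if corrupt_genotype:
        g = files["genotype"].astype(object)
        g.iloc[2, 3] = "NA"
        files["genotype"] = g

    paths = {}
    for name, df in files.items():
        p = tmp_path / f"{name}.tsv"
        df.to_csv(p, sep="\t")
        paths[name] = p
    p = tmp_path / "region_map.tsv"
    region_map.to_csv(p, sep="\t", index=False)
    paths["region_map"] = p
    return paths


@pytest.fixture
def toy_paths(tmp_path):
    return write_toy_files(tmp_path)


@pytest.fixture
def small_sim():
    """Small simulated cohort with all three layers active (fast)."""
    config = SimulationConfig(
        n=80, R=4, n_assoc=2, p_g=8, p_m=8, disease_model="independent_EGM",
        gamma_expr=2.0, sigma_g_sq=0.5, sigma_m_sq=0.5, sigma0_sq=1.0, seed=99,
    )
    dataset, truth = simulate_dataset(config)
    return config, dataset, truth


def random_psd(rng, n, rank=None):
    A = rng.normal(size=(n, rank or n))
    K = A @ A.T / (rank or n)
    return 0.5 * (K + K.T)
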