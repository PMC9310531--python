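"""Synthetic multi-omics data with known ground truth.

Generates cohorts with the statistical structure used to evaluate the model:
``R`` regions, each carrying ``p_g`` biallelic genotype dosages (binomial
under Hardy-Weinberg equilibrium with per-SNP MAF drawn uniformly from
``maf_range``), ``p_m`` methylation levels and one expression value, the
latter two uniform on (0, 1).  The first ``n_assoc`` regions are associative;
the rest are noise.

Outcomes are drawn from the multivariate normal that the mixed model
implies,

    Y ~ N( sum_i E_i gamma_i,  sum_i sum_j K_{j,i} sigma_{j,i}^2 + sigma0^2 I ),

with the sums over associative regions and the components j activated by the
chosen disease model (seven single- and multi-layer models plus the
independent three-layer model).  Kernels use the same standardized linear
convention as the estimator; the interaction-only model draws directly from
the Hadamard-kernel covariance, so it has no marginal main-effect variance.

Genotype columns are i.i.d. (no linkage disequilibrium); the outcome model
conditions on the realized kernels, so this affects only the kernels'
spectra, not the outcome law given them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np

from .io import OmicsDataset, RegionMap
from .kernels import KernelConfig, Standardizer, _make_kernel, interaction_kernel

DISEASE_MODELS = (
    "S1_E", "S2_G", "S3_M", "S4_GM", "S5_G_plus_M", "S6_E_plus_G", "S7_E_plus_M",
    "independent_EGM",
)

#: layers activated by each disease model
ACTIVE_LAYERS: dict[str, frozenset[str]] = {
    "S1_E": frozenset({"expression"}),
    "S2_G": frozenset({"genomic"}),
    "S3_M": frozenset({"methylation"}),
    "S4_GM": frozenset({"interaction"}),
    "S5_G_plus_M": frozenset({"genomic", "methylation"}),
    "S6_E_plus_G": frozenset({"expression", "genomic"}),
    "S7_E_plus_M": frozenset({"expression", "methylation"}),
    "independent_EGM": frozenset({"expression", "genomic", "methylation"}),
}

_LAYER_PARAM = {
    "expression": "gamma_expr",
    "genomic": "sigma_g_sq",
    "methylation": "sigma_m_sq",
    "interaction": "sigma_gm_sq",
}


def load_default_effects() -> dict:
    """Packaged default effect sizes (variance budgets per disease model)."""
    with resources.files("lmmgmm.data").joinpath("scenario_effects.json").open() as fh:
        return json.load(fh)


@dataclass
class SimulationConfig:
    """One synthetic-cohort recipe.

    Effect parameters are per associative region: ``gamma_expr`` is the fixed
    expression effect, the ``sigma_*_sq`` are the variance components of the
    genomic, methylation and genomic-x-methylation interaction kernels, and
    ``sigma0_sq`` is the residual variance.
    """

    n: int
    R: int
    disease_model: str
    n_assoc: int = 3
    p_g: int = 30
    p_m: int = 30
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_expr: float = 0.0
    sigma_g_sq: float = 0.0
    sigma_m_sq: float = 0.0
    sigma_gm_sq: float = 0.0
    sigma0_sq: float = 1.0
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.disease_model not in DISEASE_MODELS:
            raise ValueError(
                f"unknown disease model {self.disease_model!r}; expected one of {DISEASE_MODELS}"
            )
        if not 1 <= self.n_assoc <= self.R:
            raise ValueError(f"need 1 <= n_assoc <= R, got {self.n_assoc} of {self.R}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        for name in ("sigma_g_sq", "sigma_m_sq", "sigma_gm_sq", "sigma0_sq"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for layer in ACTIVE_LAYERS[self.disease_model]:
            param = _LAYER_PARAM[layer]
            if getattr(self, param) == 0.0:
                raise ValueError(
                    f"disease model {self.disease_model} activates layer {layer!r} "
                    f"but {param} is 0"
                )

    @property
    def region_ids(self) -> list[str]:
        width = len(str(self.R))
        return [f"region_{i + 1:0{width}d}" for i in range(self.R)]


@dataclass
class SimulatedTruth:
    """Ground-truth labels for selection metrics."""

    associative_regions: set[str]
    active_layers: frozenset[str]
    variance_fractions: dict[str, float] = field(default_factory=dict)

    def layer_active(self, layer: str) -> bool:
        return layer in self.active_layers


def simulate_genotypes(
    n: int, p: int, maf_range: tuple[float, float], rng: np.random.Generator,
    max_retries: int = 100,
) -> np.ndarray:
    """Biallelic dosages in {0, 1, 2}: Binomial(2, MAF_j) per column.

    MAF_j ~ Uniform(maf_range); monomorphic columns are redrawn (bounded
    retries) so every column is polymorphic.
    """
    if p < 1:
        raise ValueError(f"need p >= 1 SNPs, got {p}")
    G = np.empty((n, p))
    for j in range(p):
        for attempt in range(max_retries + 1):
            maf = rng.uniform(*maf_range)
            col = rng.binomial(2, maf, size=n)
            if col.min() != col.max():
                break
        else:
            raise RuntimeError(
                f"could not draw a polymorphic SNP column in {max_retries} retries; "
                f"maf_range {maf_range} is too extreme for n={n}"
            )
        G[:, j] = col
    return G


def _region_map_for(config: SimulationConfig) -> RegionMap:
    entries: list[tuple[str, str, str]] = []
    for region in config.region_ids:
        for j in range(config.p_g):
            entries.append((f"{region}_snp{j + 1:02d}", "genomic", region))
    for region in config.region_ids:
        for j in range(config.p_m):
            entries.append((f"{region}_cpg{j + 1:02d}", "methylation", region))
    for region in config.region_ids:
        entries.append((f"{region}_expr", "expression", region))
    return RegionMap(entries)


def simulate_dataset(config: SimulationConfig) -> tuple[OmicsDataset, SimulatedTruth]:
    """Draw one cohort and its ground truth from the configured disease model."""
    rng = np.random.default_rng(config.seed)
    n, R = config.n, config.R
    regions = config.region_ids
    assoc = regions[: config.n_assoc]
    active = ACTIVE_LAYERS[config.disease_model]

    G_blocks = {
        r: simulate_genotypes(n, config.p_g, config.maf_range, rng) for r in regions
    }
    M_blocks = {r: rng.uniform(0.0, 1.0, size=(n, config.p_m)) for r in regions}
    E = rng.uniform(0.0, 1.0, size=(n, R))

    mean = np.zeros(n)
    if "expression" in active:
        mean = E[:, : config.n_assoc] @ np.full(config.n_assoc, config.gamma_expr)

    kc = KernelConfig(family="linear", standardize=True)
    cov = config.sigma0_sq * np.eye(n)
    contrib = {"expression": 0.0, "genomic": 0.0, "methylation": 0.0, "interaction": 0.0}
    if "expression" in active:
        contrib["expression"] = config.n_assoc * config.gamma_expr**2 / 12.0
    for r in assoc:
        Kg = Km = None
        if "genomic" in active or "interaction" in active:
            Kg = _make_kernel(G_blocks[r], kc, layer="genomic", region_id=r)
        if "methylation" in active or "interaction" in active:
            Km = _make_kernel(M_blocks[r], kc, layer="methylation", region_id=r)
        if "genomic" in active:
            cov += config.sigma_g_sq * Kg.matrix
            contrib["genomic"] += config.sigma_g_sq * np.trace(Kg.matrix) / n
        if "methylation" in active:
            cov += config.sigma_m_sq * Km.matrix
            contrib["methylation"] += config.sigma_m_sq * np.trace(Km.matrix) / n
        if "interaction" in active:
            Ki = interaction_kernel(Kg, Km)
            cov += config.sigma_gm_sq * Ki.matrix
            contrib["interaction"] += config.sigma_gm_sq * np.trace(Ki.matrix) / n

    L = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
    Y = mean + L @ rng.standard_normal(n)

    ds = OmicsDataset(
        sample_ids=[f"sample_{i + 1:05d}" for i in range(n)],
        Y=Y,
        X_d=np.empty((n, 0)),
        covariate_names=[],
        E=E,
        expression_regions=list(regions),
        G_blocks=G_blocks,
        M_blocks=M_blocks,
        region_map=_region_map_for(config),
    )
    ds.validate()
    total = sum(contrib.values()) + config.sigma0_sq
    fractions = {k: v / total for k, v in contrib.items()}
    fractions["residual"] = config.sigma0_sq / total
    truth = SimulatedTruth(
        associative_regions=set(assoc),
        active_layers=active,
        variance_fractions=fractions,
    )
    return ds, truth


def scenario_grid(scenario: str, n: int = 500, effects: dict | None = None) -> list[SimulationConfig]:
    """Study designs of the two simulation scenarios.

    Scenario ``"I"``: the three-layer independent model at region counts
    R in {10, 25, 50, 75, 100} (3 associative + growing noise).
    Scenario ``"II"``: the seven disease models S1-S7 at R = 50.
    """
    effects = effects or load_default_effects()
    configs: list[SimulationConfig] = []
    if scenario == "I":
        params = effects["scenario_I"]
        for R in (10, 25, 50, 75, 100):
            configs.append(
                SimulationConfig(
                    n=n, R=R, disease_model="independent_EGM",
                    sigma0_sq=effects["sigma0_sq"], label=f"scenario_I_R{R}",
                    **params,
                )
            )
    elif scenario == "II":
        for model in DISEASE_MODELS[:7]:
            params = effects["scenario_II"][model]
            configs.append(
                SimulationConfig(
                    n=n, R=50, disease_model=model,
                    sigma0_sq=effects["sigma0_sq"], label=f"scenario_II_{model}",
                    **params,
                )
            )
    else:
        raise ValueError(f"unknown scenario {scenario!r}; expected 'I' or 'II'")
    return configs


def write_truth(truth: SimulatedTruth, path: str) -> None:
    """Truth labels as a small TSV (region_id, associative flag)."""
    import pandas as pd

    rows = [{"region_id": r, "associative": 1} for r in sorted(truth.associative_regions)]
    df = pd.DataFrame(rows)
    df["active_layers"] = ",".join(sorted(truth.active_layers))
    df.to_csv(path, sep="\t", index=False)


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
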