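"""Per-region similarity (kernel) matrices for each omics layer.

Each region of each layer yields one n x n positive semidefinite kernel.
The default is the linear kernel K = Xs Xs^T / p on column-standardized
features — the gBLUP convention, which makes variance components comparable
across regions of different feature counts.  Gaussian and polynomial kernels
are available for nonlinear effects.  Layer-pair interactions are modelled by
the Hadamard (elementwise) product of the two layer kernels, PSD by the Schur
product theorem.

Standardization parameters are learned on training data and reused verbatim
for test samples, so cross-kernels between test and training samples are the
off-diagonal blocks of the kernel computed on the stacked rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import OmicsDataset

KERNEL_FAMILIES = ("linear", "gaussian", "polynomial")


@dataclass(frozen=True)
class Standardizer:
    """Per-column (mean, scale); constant columns get scale 1 (centered only)."""

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        return cls(mean=mean, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != self.mean.shape[0]:
            raise ValueError(
                f"feature count {X.shape[1]} does not match standardizer ({self.mean.shape[0]})"
            )
        return (X - self.mean) / self.scale


@dataclass
class Kernel:
    """One region's similarity matrix with its provenance.

    Linear kernels also carry a low-rank factor F with K = F F^T (the
    standardized features scaled by 1/sqrt(p)); interaction kernels carry
    the factor pair of their parents.  Solvers exploit these to evaluate
    quadratic forms without touching the n x n matrix.
    """

    matrix: np.ndarray
    layer: str  # genomic | methylation | interaction
    region_id: str
    family: str = "linear"
    factor: np.ndarray | None = None
    factor_pair: tuple[np.ndarray, np.ndarray] | None = None

    def check(self, sym_tol: float = 1e-10, psd_tol: float = 1e-8) -> None:
        K = self.matrix
        if np.abs(K - K.T).max() > sym_tol:
            raise ValueError(f"kernel {self.layer}/{self.region_id} not symmetric")
        w = np.linalg.eigvalsh(K)
        if w[0] < -psd_tol * max(w[-1], 1e-300):
            raise ValueError(
                f"kernel {self.layer}/{self.region_id} not PSD (min eig {w[0]:.3e})"
            )


@dataclass
class KernelConfig:
    family: str = "linear"
    bandwidth: float = 1.0  # Gaussian: exp(-||x - x'||^2 / (p * h))
    degree: int = 2  # polynomial: (1 + <x, x'>/p)^degree
    interactions: bool = False
    standardize: bool = True


@dataclass
class KernelSet:
    """Ordered kernels plus the train-learned standardization parameters.

    Order is deterministic: genomic regions in region-map order, then
    methylation regions, then interactions for regions present in both layers.
    """

    kernels: list[Kernel]
    standardizers: dict[tuple[str, str], Standardizer] = field(default_factory=dict)
    config: KernelConfig = field(default_factory=KernelConfig)

    @property
    def n(self) -> int:
        return self.kernels[0].matrix.shape[0] if self.kernels else 0

    def __len__(self) -> int:
        return len(self.kernels)

    def labels(self) -> list[tuple[str, str]]:
        return [(k.layer, k.region_id) for k in self.kernels]


def _pairwise_sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    aa = (A * A).sum(axis=1)[:, None]
    bb = (B * B).sum(axis=1)[None, :]
    return np.maximum(aa + bb - 2.0 * A @ B.T, 0.0)


def _kernel_block(A: np.ndarray, B: np.ndarray, config: KernelConfig) -> np.ndarray:
    """Kernel evaluated between row sets A and B of standardized features."""
    p = A.shape[1]
    if config.family == "linear":
        return A @ B.T / p
    if config.family == "gaussian":
        return np.exp(-_pairwise_sq_dists(A, B) / (p * config.bandwidth))
    if config.family == "polynomial":
        return (1.0 + A @ B.T / p) ** config.degree
    raise ValueError(f"unknown kernel family {config.family!r}")


def linear_kernel(
    X: np.ndarray,
    standardizer: Standardizer | None = None,
    standardize: bool = True,
) -> Kernel:
    """Linear kernel Xs Xs^T / p on (optionally) standardized columns."""
    return _make_kernel(X, KernelConfig(family="linear", standardize=standardize),
                        standardizer)


def _make_kernel(
    X: np.ndarray,
    config: KernelConfig,
    standardizer: Standardizer | None = None,
    layer: str = "genomic",
    region_id: str = "",
) -> Kernel:
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError(f"need an n x p matrix with p >= 1, got shape {X.shape}")
    if config.standardize:
        std = standardizer or Standardizer.fit(X)
        Xs = std.transform(X)
    else:
        Xs = np.asarray(X, dtype=float)
    K = _kernel_block(Xs, Xs, config)
    K = 0.5 * (K + K.T)
    factor = Xs / np.sqrt(Xs.shape[1]) if config.family == "linear" else None
    return Kernel(
        matrix=K, layer=layer, region_id=region_id, family=config.family, factor=factor
    )


def interaction_kernel(Kg: Kernel, Km: Kernel) -> Kernel:
    """Hadamard-product kernel modelling genomic x methylation interaction."""
    if Kg.matrix.shape != Km.matrix.shape:
        raise ValueError(
            f"kernel dimension mismatch: {Kg.matrix.shape} vs {Km.matrix.shape}"
        )
    if Kg.region_id != Km.region_id:
        raise ValueError(
            f"interaction requires matching regions, got {Kg.region_id!r} vs {Km.region_id!r}"
        )
    pair = None
    if Kg.factor is not None and Km.factor is not None:
        pair = (Kg.factor, Km.factor)
    return Kernel(
        matrix=Kg.matrix * Km.matrix,
        layer="interaction",
        region_id=Kg.region_id,
        family=Kg.family,
        factor_pair=pair,
    )


def build_kernel_set(dataset: OmicsDataset, config: KernelConfig | None = None) -> KernelSet:
    """One kernel per genomic region, one per methylation region, and (if
    enabled) one interaction kernel per region present in both layers."""
    config = config or KernelConfig()
    kernels: list[Kernel] = []
    standardizers: dict[tuple[str, str], Standardizer] = {}
    by_key: dict[tuple[str, str], Kernel] = {}

    for layer, blocks in (("genomic", dataset.G_blocks), ("methylation", dataset.M_blocks)):
        for region in dataset.region_map.regions(layer):
            if region not in blocks:
                continue
            X = blocks[region]
            std = Standardizer.fit(X) if config.standardize else None
            k = _make_kernel(X, config, std, layer=layer, region_id=region)
            kernels.append(k)
            by_key[(layer, region)] = k
            if std is not None:
                standardizers[(layer, region)] = std

    if config.interactions:
        if not dataset.G_blocks or not dataset.M_blocks:
            raise ValueError("interaction kernels require both genomic and methylation layers")
        for region in dataset.region_map.regions("genomic"):
            if ("genomic", region) in by_key and ("methylation", region) in by_key:
                kernels.append(
                    interaction_kernel(by_key[("genomic", region)],
                                       by_key[("methylation", region)])
                )
    return KernelSet(kernels=kernels, standardizers=standardizers, config=config)


def export_kernel_tsv(kernel: Kernel, sample_ids: list[str], path: str) -> None:
    """Write a kernel matrix as TSV with sample-id row/column headers."""
    import pandas as pd

    pd.DataFrame(kernel.matrix, index=sample_ids, columns=sample_ids).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def _standardized_block(
    dataset: OmicsDataset, kernel_set: KernelSet, layer: str, region: str
) -> np.ndarray:
    blocks = dataset.G_blocks if layer == "genomic" else dataset.M_blocks
    if region not in blocks:
        raise ValueError(f"region {region!r} missing from {layer} layer of dataset")
    X = blocks[region]
    std = kernel_set.standardizers.get((layer, region))
    if std is not None:
        if X.shape[1] != std.mean.shape[0]:
            raise ValueError(
                f"{layer} region {region!r}: test has {X.shape[1]} features, "
                f"training had {std.mean.shape[0]}"
            )
        return std.transform(X)
    return np.asarray(X, dtype=float)


def build_cross_kernels(
    train: OmicsDataset, test: OmicsDataset, kernel_set: KernelSet
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Test x train (K_po) and test x test (K_pp) blocks for every kernel.

    Equivalent to computing each kernel on the stacked (test, train) rows and
    slicing; training standardization parameters are reused for test features.
    """
    config = kernel_set.config
    K_po: list[np.ndarray] = []
    K_pp: list[np.ndarray] = []
    cache: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}

    def blocks_for(layer: str, region: str) -> tuple[np.ndarray, np.ndarray]:
        key = (layer, region)
        if key not in cache:
            A = _standardized_block(test, kernel_set, layer, region)
            B = _standardized_block(train, kernel_set, layer, region)
            cache[key] = (
                _kernel_block(A, B, config),
                _kernel_block(A, A, config),
            )
        return cache[key]

    for kern in kernel_set.kernels:
        if kern.layer == "interaction":
            g_po, g_pp = blocks_for("genomic", kern.region_id)
            m_po, m_pp = blocks_for("methylation", kern.region_id)
            K_po.append(g_po * m_po)
            K_pp.append(g_pp * m_pp)
        else:
            po, pp = blocks_for(kern.layer, kern.region_id)
            K_po.append(po)
            K_pp.append(pp)
    return K_po, K_pp
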