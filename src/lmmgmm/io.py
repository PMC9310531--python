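"""Reading, validation and partitioning of multi-omics matrices.

All delimited inputs are tab-separated with samples in rows and features in
columns; the first column is the sample identifier.  Feature columns of the
genomic and methylation layers are grouped into regions (genes or pathways)
through a three-column region map (``feature_id``, ``layer``, ``region_id``).
Expression is summarised per region: exactly one column per region, modelled
downstream as a fixed effect.

Samples are aligned across files by identifier intersection; dropped samples
are logged, never silently imputed.  Missing or non-numeric cells are hard
errors.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LAYERS = ("genomic", "methylation", "expression")


class DataValidationError(ValueError):
    """Raised when an input matrix or annotation violates the format contract."""


@dataclass(frozen=True)
class RegionMap:
    """Assignment of feature columns to regions within each omics layer.

    ``entries`` is an ordered list of ``(feature_id, layer, region_id)``
    triples.  The order of first appearance of each region defines the
    canonical region order used for kernels and variance components.
    """

    entries: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        expr_regions: dict[str, str] = {}
        for feat, layer, region in self.entries:
            if layer not in LAYERS:
                raise DataValidationError(
                    f"unknown layer {layer!r} for feature {feat!r}; "
                    f"expected one of {LAYERS}"
                )
            key = (feat, layer)
            if key in seen:
                raise DataValidationError(
                    f"duplicate region-map entry for feature {feat!r} in layer {layer!r}"
                )
            seen.add(key)
            if layer == "expression":
                if region in expr_regions.values() and feat not in expr_regions:
                    raise DataValidationError(
                        f"expression region {region!r} mapped by more than one feature; "
                        "expression must be one column per region"
                    )
                expr_regions[feat] = region

    def regions(self, layer: str) -> list[str]:
        """Region ids of ``layer`` in order of first appearance."""
        out: list[str] = []
        for _, lay, region in self.entries:
            if lay == layer and region not in out:
                out.append(region)
        return out

    def features(self, layer: str, region_id: str) -> list[str]:
        return [f for f, lay, r in self.entries if lay == layer and r == region_id]

    def feature_region(self, layer: str) -> dict[str, str]:
        return {f: r for f, lay, r in self.entries if lay == layer}


@dataclass
class OmicsDataset:
    """Aligned multi-omics data for one cohort.

    Attributes
    ----------
    sample_ids : list of str
        Row order shared by every matrix.
    Y : (n,) ndarray
        Continuous outcome.
    X_d : (n, P_d) ndarray
        Demographic covariates (may have zero columns); no intercept column.
    E : (n, R_e) ndarray
        Per-region expression values, one column per region.
    expression_regions : list of str
        Region id of each expression column.
    G_blocks, M_blocks : dict of region_id -> (n, p_i) ndarray
        Genotype dosages / methylation levels partitioned by region, in the
        region map's canonical order.
    """

    sample_ids: list[str]
    Y: np.ndarray
    X_d: np.ndarray
    covariate_names: list[str]
    E: np.ndarray
    expression_regions: list[str]
    G_blocks: dict[str, np.ndarray]
    M_blocks: dict[str, np.ndarray]
    region_map: RegionMap
    dropped_samples: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def validate(self) -> None:
        n = self.n
        if self.Y.shape != (n,):
            raise DataValidationError(f"outcome length {self.Y.shape} != n={n}")
        mats: list[tuple[str, np.ndarray]] = [("covariates", self.X_d), ("expression", self.E)]
        mats += [(f"genotype block {r!r}", m) for r, m in self.G_blocks.items()]
        mats += [(f"methylation block {r!r}", m) for r, m in self.M_blocks.items()]
        for name, mat in mats:
            if mat.ndim != 2 or mat.shape[0] != n:
                raise DataValidationError(f"{name} has shape {mat.shape}, expected ({n}, *)")
            if not np.isfinite(mat).all():
                i, j = np.argwhere(~np.isfinite(mat))[0]
                raise DataValidationError(
                    f"{name} contains a non-finite value at row {self.sample_ids[i]}, column index {j}"
                )
        if not np.isfinite(self.Y).all():
            bad = [self.sample_ids[i] for i in np.flatnonzero(~np.isfinite(self.Y))]
            raise DataValidationError(f"outcome contains non-finite values for samples {bad[:10]}")
        if self.E.shape[1] != len(self.expression_regions):
            raise DataValidationError("expression column count != expression region labels")
        for layer, blocks in (("genomic", self.G_blocks), ("methylation", self.M_blocks)):
            mapped = set(self.region_map.regions(layer))
            for region in blocks:
                if region not in mapped:
                    raise DataValidationError(f"{layer} block {region!r} not in region map")
        if len(set(self.sample_ids)) != n:
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise DataValidationError(f"duplicate sample ids: {dupes[:10]}")

    def subset(self, idx: np.ndarray) -> "OmicsDataset":
        """Row subset preserving region structure (``idx`` are row positions)."""
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in idx],
            Y=self.Y[idx],
            X_d=self.X_d[idx],
            E=self.E[idx],
            G_blocks={r: m[idx] for r, m in self.G_blocks.items()},
            M_blocks={r: m[idx] for r, m in self.M_blocks.items()},
            dropped_samples=[],
        )


def read_region_map(path: str | os.PathLike) -> RegionMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["feature_id", "layer", "region_id"]
    if list(df.columns[:3]) != required:
        raise DataValidationError(
            f"region map must have columns {required}, got {list(df.columns)}"
        )
    return RegionMap(entries=[tuple(row) for row in df[required].itertuples(index=False)])


def _read_matrix(path: str | os.PathLike, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df = df.set_index(df.columns[0])
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise DataValidationError(f"{what} file {path}: duplicate sample ids {dupes[:10]}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = df.index[np.flatnonzero(bad.to_numpy())[0]]
            raise DataValidationError(
                f"{what} file {path}: non-numeric or missing value at sample {row!r}, column {col!r}"
            )
        df[col] = coerced
    return df.astype(float)


def _partition_blocks(
    df: pd.DataFrame, region_map: RegionMap, layer: str, what: str
) -> dict[str, np.ndarray]:
    feat_region = region_map.feature_region(layer)
    unmapped = [c for c in df.columns if c not in feat_region]
    if unmapped:
        raise DataValidationError(
            f"{what}: {len(unmapped)} columns missing from region map, first 10: {unmapped[:10]}"
        )
    blocks: dict[str, np.ndarray] = {}
    for region in region_map.regions(layer):
        feats = [f for f in region_map.features(layer, region) if f in df.columns]
        if feats:
            blocks[region] = df[feats].to_numpy()
    return blocks


def read_dataset(
    outcome_path: str | os.PathLike,
    region_map_path: str | os.PathLike,
    covariates_path: str | os.PathLike | None = None,
    expression_path: str | os.PathLike | None = None,
    genotype_path: str | os.PathLike | None = None,
    methylation_path: str | os.PathLike | None = None,
) -> OmicsDataset:
    """Read, align and validate a multi-omics dataset from delimited files.

    Rows are aligned on the intersection of sample ids across all provided
    files, in the outcome file's order; dropped samples are logged and listed
    in ``dataset.dropped_samples``.
    """
    region_map = read_region_map(region_map_path)
    outcome = _read_matrix(outcome_path, "outcome")
    if outcome.shape[1] != 1:
        raise DataValidationError(
            f"outcome file must have exactly one value column, got {outcome.shape[1]}"
        )
    frames: dict[str, pd.DataFrame] = {"outcome": outcome}
    if covariates_path is not None:
        frames["covariates"] = _read_matrix(covariates_path, "covariates")
    if expression_path is not None:
        frames["expression"] = _read_matrix(expression_path, "expression")
    if genotype_path is not None:
        frames["genotype"] = _read_matrix(genotype_path, "genotype")
    if methylation_path is not None:
        frames["methylation"] = _read_matrix(methylation_path, "methylation")

    common = set(outcome.index)
    for df in frames.values():
        common &= set(df.index)
    ids = [s for s in outcome.index if s in common]
    if not ids:
        raise DataValidationError("no samples shared by all input files")
    dropped = sorted(set().union(*(set(df.index) for df in frames.values())) - common)
    if dropped:
        logger.info("dropped %d samples absent from at least one file: %s",
                    len(dropped), dropped[:10])

    aligned = {k: df.loc[ids] for k, df in frames.items()}

    cov = aligned.get("covariates")
    X_d = cov.to_numpy() if cov is not None else np.empty((len(ids), 0))
    cov_names = list(cov.columns) if cov is not None else []

    expr = aligned.get("expression")
    if expr is not None:
        feat_region = region_map.feature_region("expression")
        unmapped = [c for c in expr.columns if c not in feat_region]
        if unmapped:
            raise DataValidationError(
                f"expression: columns missing from region map, first 10: {unmapped[:10]}"
            )
        E = expr.to_numpy()
        expr_regions = [feat_region[c] for c in expr.columns]
        if len(set(expr_regions)) != len(expr_regions):
            raise DataValidationError("multiple expression columns map to one region")
    else:
        E = np.empty((len(ids), 0))
        expr_regions = []

    G_blocks = (
        _partition_blocks(aligned["genotype"], region_map, "genomic", "genotype")
        if "genotype" in aligned else {}
    )
    M_blocks = (
        _partition_blocks(aligned["methylation"], region_map, "methylation", "methylation")
        if "methylation" in aligned else {}
    )

    ds = OmicsDataset(
        sample_ids=list(ids),
        Y=aligned["outcome"].to_numpy()[:, 0],
        X_d=X_d,
        covariate_names=cov_names,
        E=E,
        expression_regions=expr_regions,
        G_blocks=G_blocks,
        M_blocks=M_blocks,
        region_map=region_map,
        dropped_samples=list(dropped),
    )
    ds.validate()
    return ds


def write_dataset(dataset: OmicsDataset, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write a dataset back to the delimited formats; returns the file paths."""
    os.makedirs(out_dir, exist_ok=True)
    idx = pd.Index(dataset.sample_ids, name="sample_id")
    paths: dict[str, str] = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        path = os.path.join(out_dir, f"{name}.tsv")
        df.to_csv(path, sep="\t")
        paths[name] = path

    _write("outcome", pd.DataFrame({"Y": dataset.Y}, index=idx))
    if dataset.X_d.shape[1]:
        _write("covariates", pd.DataFrame(dataset.X_d, index=idx, columns=dataset.covariate_names))
    feat_region = dataset.region_map.feature_region("expression")
    region_feat = {r: f for f, r in feat_region.items()}
    if dataset.E.shape[1]:
        cols = [region_feat.get(r, f"expr_{r}") for r in dataset.expression_regions]
        _write("expression", pd.DataFrame(dataset.E, index=idx, columns=cols))
    for name, layer, blocks in (
        ("genotype", "genomic", dataset.G_blocks),
        ("methylation", "methylation", dataset.M_blocks),
    ):
        if blocks:
            cols: list[str] = []
            arrs: list[np.ndarray] = []
            for region, mat in blocks.items():
                feats = dataset.region_map.features(layer, region)
                cols.extend(feats[: mat.shape[1]])
                arrs.append(mat)
            _write(name, pd.DataFrame(np.hstack(arrs), index=idx, columns=cols))
    rm = pd.DataFrame(dataset.region_map.entries, columns=["feature_id", "layer", "region_id"])
    path = os.path.join(out_dir, "region_map.tsv")
    rm.to_csv(path, sep="\t", index=False)
    paths["region_map"] = path
    return paths


def split_train_test(
    dataset: OmicsDataset, train_fraction: float, seed: int
) -> tuple[OmicsDataset, OmicsDataset]:
    """Disjoint train/test row partition, reproducible and keyed on sample ids.

    The shuffle operates on the canonically sorted id list, so permuting the
    dataset's rows does not change which samples land in which partition.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n = dataset.n
    if n < 2:
        raise ValueError(f"need at least 2 samples to split, got {n}")
    n_train = int(round(n * train_fraction))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(sorted(dataset.sample_ids))
    train_ids = set(order[:n_train])
    pos = {s: i for i, s in enumerate(dataset.sample_ids)}
    train_idx = np.array([pos[s] for s in dataset.sample_ids if s in train_ids])
    test_idx = np.array([pos[s] for s in dataset.sample_ids if s not in train_ids])
    return dataset.subset(train_idx), dataset.subset(test_idx)
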