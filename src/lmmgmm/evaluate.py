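"""Evaluation: prediction metrics, selection metrics, the kriging baseline
and a replicated-scenario experiment runner.

The baseline is single-component multi-layer kriging: one whole-layer linear
kernel per omics layer (all features pooled, no regions), combined with
fixed weights into S = sum_l w_l S_l, outcome model
Y ~ N(mu 1, tau^2 (S + delta I)) with (tau^2, delta) estimated by profile
likelihood on a 1-D grid in delta, and predictions
mu + S_po (S_oo + delta I)^{-1} (Y - mu).  It performs no variable
selection.  This is a from-scratch reimplementation of the standard
multi-omic kriging recipe, documented in the methods note.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import OmicsDataset, split_train_test
from .kernels import KernelConfig, Standardizer
from .model import FitConfig, MultiKernelLMM, fit, predict
from .simulate import SimulatedTruth, SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

METRIC_LAYERS = ("expression", "genomic", "methylation")


def pearson_and_mse(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    """Sample Pearson correlation and mean squared error."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size < 2:
        raise ValueError("need two equal-length vectors with at least 2 entries")
    mse = float(np.mean((y_true - y_pred) ** 2))
    if np.std(y_true) == 0.0:
        warnings.warn("constant y_true: Pearson correlation undefined", RuntimeWarning)
        return np.nan, mse
    if np.std(y_pred) == 0.0:
        return np.nan, mse
    r = float(np.corrcoef(y_true, y_pred)[0, 1])
    return r, mse


def selection_metrics(
    selected: dict[str, set[str]],
    truth: SimulatedTruth,
    region_ids: list[str],
    layer_active: dict[str, bool] | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-layer (sensitivity, specificity) of region selection.

    sensitivity = |selected ∩ associative| / |associative| within the layer,
    reported as NaN when the layer carries no associative regions (printed as
    "-" in summary tables); specificity = |noise \\ selected| / |noise|.
    """
    assoc = truth.associative_regions
    noise = [r for r in region_ids if r not in assoc]
    out: dict[str, tuple[float, float]] = {}
    for layer in METRIC_LAYERS:
        sel = {r for r in selected.get(layer, set()) if r in region_ids}
        active = (
            layer_active[layer] if layer_active is not None else truth.layer_active(layer)
        )
        if active and assoc:
            sens = len(sel & assoc) / len(assoc)
        else:
            sens = np.nan
        spec = len([r for r in noise if r not in sel]) / len(noise) if noise else np.nan
        out[layer] = (sens, spec)
    return out


def _layer_matrices(dataset: OmicsDataset) -> dict[str, np.ndarray]:
    layers: dict[str, np.ndarray] = {}
    if dataset.E.shape[1]:
        layers["expression"] = dataset.E
    if dataset.G_blocks:
        layers["genomic"] = np.hstack(list(dataset.G_blocks.values()))
    if dataset.M_blocks:
        layers["methylation"] = np.hstack(list(dataset.M_blocks.values()))
    return layers


def kriging_baseline(
    train: OmicsDataset,
    test: OmicsDataset,
    weights: dict[str, float] | None = None,
    delta_grid: np.ndarray | None = None,
) -> np.ndarray:
    """Whole-layer kriging predictions (no variable selection).

    ``weights`` are per-layer mixing weights summing to 1 (default equal over
    the layers present); ``delta_grid`` is the noise-to-signal ratio grid for
    the profile-likelihood estimate of (tau^2, delta).
    """
    train_layers = _layer_matrices(train)
    test_layers = _layer_matrices(test)
    if not train_layers:
        raise ValueError("kriging baseline needs at least one omics layer")
    if weights is None:
        weights = {l: 1.0 / len(train_layers) for l in train_layers}
    if abs(sum(weights.values()) - 1.0) > 1e-8:
        raise ValueError("layer weights must sum to 1")

    n, n_p = train.n, test.n
    S_oo = np.zeros((n, n))
    S_po = np.zeros((n_p, n))
    for layer, X in train_layers.items():
        std = Standardizer.fit(X)
        Xs = std.transform(X)
        Xt = std.transform(test_layers[layer])
        p = X.shape[1]
        S_oo += weights[layer] * (Xs @ Xs.T) / p
        S_po += weights[layer] * (Xt @ Xs.T) / p
    S_oo = 0.5 * (S_oo + S_oo.T)

    if delta_grid is None:
        delta_grid = np.geomspace(1e-4, 1e4, 41)
    lam, U = np.linalg.eigh(S_oo)
    lam = np.clip(lam, 0.0, None)
    u1 = U.T @ np.ones(n)
    uy = U.T @ train.Y

    best = None
    for delta in delta_grid:
        d = lam + delta
        if np.any(d <= 0) or not np.all(np.isfinite(d)):
            continue
        denom = float(np.sum(u1**2 / d))
        mu = float(np.sum(u1 * uy / d)) / denom
        resid = uy - mu * u1
        q = float(np.sum(resid**2 / d))
        tau2 = q / n
        loglik = -0.5 * n * np.log(max(tau2, 1e-300)) - 0.5 * float(np.sum(np.log(d)))
        if best is None or loglik > best[0]:
            best = (loglik, delta, mu)
    if best is None:
        raise np.linalg.LinAlgError("kriging covariance singular at every grid point")
    _, delta, mu = best
    alpha = U @ ((U.T @ (train.Y - mu)) / (lam + delta))
    return mu + S_po @ alpha


@dataclass
class ReplicateResult:
    method: str
    config_label: str
    replicate: int
    seed: int
    pearson: float
    mse: float
    selection: dict[str, tuple[float, float]] = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "method": self.method,
            "config": self.config_label,
            "replicate": self.replicate,
            "seed": self.seed,
            "pearson": self.pearson,
            "mse": self.mse,
        }
        for layer, (sens, spec) in self.selection.items():
            row[f"sens_{layer}"] = sens
            row[f"spec_{layer}"] = spec
        return row


@dataclass
class ScenarioSummary:
    """Mean and Monte-Carlo standard error of every metric, per method."""

    config_label: str
    n_replicates: int
    table: pd.DataFrame  # index: method; columns: metric means and SEs
    n_failures: int = 0


def model_selection_sets(model: MultiKernelLMM) -> dict[str, set[str]]:
    """Layer-attributed selected regions; interaction components count toward
    both of their constituent layers."""
    sel = model.selected_regions
    out = {
        "expression": set(sel["expression"]),
        "genomic": set(sel["genomic"]) | set(sel["interaction"]),
        "methylation": set(sel["methylation"]) | set(sel["interaction"]),
    }
    return out


def _derive_seed(base_seed: int, *keys: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), *map(int, keys)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_replicate(
    config: SimulationConfig,
    seed: int,
    methods: tuple[str, ...] = ("lmmgmm", "kriging"),
    kernel_config: KernelConfig | None = None,
    fit_config: FitConfig | None = None,
    train_fraction: float = 0.7,
    replicate: int = 0,
) -> list[ReplicateResult]:
    """Simulate one cohort, split 70/30, fit each method, score on the test set."""
    from dataclasses import replace as dc_replace

    config = dc_replace(config, seed=_derive_seed(seed, 1))
    dataset, truth = simulate_dataset(config)
    train, test = split_train_test(dataset, train_fraction, seed=_derive_seed(seed, 2))
    region_ids = config.region_ids

    layer_active = {
        "expression": truth.layer_active("expression"),
        "genomic": truth.layer_active("genomic") or truth.layer_active("interaction"),
        "methylation": truth.layer_active("methylation") or truth.layer_active("interaction"),
    }

    results: list[ReplicateResult] = []
    for method in methods:
        if method == "lmmgmm":
            fc = fit_config or FitConfig()
            fc = dc_replace(fc, seed=_derive_seed(seed, 3))
            model = fit(train, kernel_config, fc)
            pred = predict(model, test)
            r, mse = pearson_and_mse(test.Y, pred)
            selection = selection_metrics(
                model_selection_sets(model), truth, region_ids, layer_active
            )
            results.append(
                ReplicateResult(method, config.label, replicate, seed, r, mse, selection)
            )
        elif method == "kriging":
            pred = kriging_baseline(train, test)
            r, mse = pearson_and_mse(test.Y, pred)
            results.append(
                ReplicateResult(method, config.label, replicate, seed, r, mse, {})
            )
        else:
            raise ValueError(f"unknown method {method!r}")
    return results


def summarize(rows: list[ReplicateResult], config_label: str) -> ScenarioSummary:
    df = pd.DataFrame([r.as_row() for r in rows])
    metric_cols = [c for c in df.columns if c not in ("method", "config", "replicate", "seed")]
    means = df.groupby("method")[metric_cols].mean()
    ses = df.groupby("method")[metric_cols].apply(
        lambda g: g.std(ddof=1) / np.sqrt(g.notna().sum())
    )
    ses.columns = [f"{c}_se" for c in ses.columns]
    table = pd.concat([means, ses], axis=1)
    n_reps = int(df.groupby("method")["replicate"].nunique().max())
    return ScenarioSummary(config_label=config_label, n_replicates=n_reps, table=table)


def run_scenario(
    configs: list[SimulationConfig],
    n_replicates: int,
    base_seed: int,
    methods: tuple[str, ...] = ("lmmgmm", "kriging"),
    kernel_config: KernelConfig | None = None,
    fit_config: FitConfig | None = None,
    train_fraction: float = 0.7,
    out_dir: str | None = None,
) -> tuple[list[ScenarioSummary], pd.DataFrame]:
    """Replicated simulate/fit/evaluate loop with deterministic per-replicate seeds.

    A failing replicate is logged, excluded from the means and counted in the
    summary's failure column.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    summaries: list[ScenarioSummary] = []
    all_rows: list[ReplicateResult] = []
    for ci, config in enumerate(configs):
        rows: list[ReplicateResult] = []
        failures = 0
        for rep in range(n_replicates):
            seed = _derive_seed(base_seed, ci, rep)
            try:
                rows.extend(
                    run_replicate(
                        config, seed, methods, kernel_config, fit_config,
                        train_fraction, replicate=rep,
                    )
                )
            except Exception:
                failures += 1
                logger.exception(
                    "replicate %d of %s failed", rep, config.label or f"config {ci}"
                )
        summary = summarize(rows, config.label or f"config_{ci}")
        summary.n_failures = failures
        summaries.append(summary)
        all_rows.extend(rows)
    per_replicate = pd.DataFrame([r.as_row() for r in all_rows])
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        per_replicate.to_csv(os.path.join(out_dir, "replicates.tsv"), sep="\t", index=False)
        pd.concat(
            {s.config_label: s.table for s in summaries}, names=["config"]
        ).to_csv(os.path.join(out_dir, "summary.tsv"), sep="\t")
    return summaries, per_replicate


def format_summary_table(summaries: list[ScenarioSummary]) -> str:
    """Render selection summaries with '-' for undefined sensitivities."""
    frames = []
    for s in summaries:
        t = s.table.copy()
        t.insert(0, "config", s.config_label)
        frames.append(t)
    df = pd.concat(frames)
    return df.round(3).fillna("-").to_string()
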