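"""Penalized multi-kernel linear mixed model: fitting and prediction.

The outcome model is

    Y = X_d beta_d + sum_i E_i gamma_i + sum_i sum_j u_{j,i} + eps,

with one Gaussian random effect u_{j,i} ~ N(0, K_{j,i} sigma_{j,i}^2) per
region i and layer j (genomic, methylation, optionally their Hadamard
interaction) and eps ~ N(0, sigma0^2 I).  Estimation alternates:

1. variance components by penalized method-of-moments (:mod:`lmmgmm.gmm`)
   on the residual outer product, L1 penalty lambda1;
2. fixed effects by L1-penalized generalized least squares
   (:mod:`lmmgmm.gls`) under the assembled covariance, penalty lambda2;

until the maximum relative parameter change falls below ``outer_tol``.
Prediction for new samples is the conditional (BLUP/kriging) mean

    Y_p = X_{d,p} beta_d + E_p gamma + Sigma_po Sigma_oo^{-1} Z,

where Sigma_po is assembled from the cross-kernels of the strictly positive
variance components only.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg

from .gls import FixedEffects, solve_penalized_gls
from .gmm import GmmWorkspace, VarianceComponents, make_workspace, moment_vector, solve_gmm
from .io import OmicsDataset, split_train_test
from .kernels import KernelConfig, KernelSet, Standardizer, build_cross_kernels, build_kernel_set

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
SIGMA0_FLOOR_FRACTION = 1e-6  # times var(Y), keeps Sigma SPD on noiseless fits


@dataclass
class FitConfig:
    """Penalty grids, convergence control and tuning rule.

    Grids default to 7 log-spaced points from a data-derived maximum down to
    ``lambda_min_ratio`` times it.  ``internal_validation`` holds out
    ``validation_fraction`` of the training samples, scores every grid pair
    by validation MSE and refits the winner on the full training set; ties
    break toward the larger (sparser) pair.
    """

    lambda1_grid: np.ndarray | None = None
    lambda2_grid: np.ndarray | None = None
    n_lambda: int = 7
    lambda_min_ratio: float = 1e-3
    outer_tol: float = 1e-4
    outer_max_iter: int = 50
    selection_rule: str = "internal_validation"  # or "fixed"
    validation_fraction: float = 0.2
    seed: int = 0
    gmm_tol: float = 1e-8
    gls_tol: float = 1e-10
    # grid-selection fits only rank validation MSEs, so they may run at a
    # looser outer tolerance than the final refit
    selection_outer_tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.selection_rule not in ("internal_validation", "fixed"):
            raise ValueError(f"unknown selection rule {self.selection_rule!r}")
        if self.selection_rule == "internal_validation" and not (
            0.0 < self.validation_fraction < 1.0
        ):
            raise ValueError("validation_fraction must be in (0, 1)")
        for name in ("lambda1_grid", "lambda2_grid"):
            grid = getattr(self, name)
            if grid is not None:
                grid = np.atleast_1d(np.asarray(grid, dtype=float))
                if grid.size == 0 or (grid < 0).any():
                    raise ValueError(f"{name} must be nonempty and non-negative")
                setattr(self, name, np.sort(grid)[::-1])


@dataclass
class MultiKernelLMM:
    """Fitted model state sufficient for out-of-sample prediction."""

    variance: VarianceComponents
    fixed: FixedEffects
    kernel_set: KernelSet
    Sigma: np.ndarray
    e_standardizer: Standardizer | None
    train: OmicsDataset
    lambdas: tuple[float, float]
    n_outer_iter: int = 0
    final_change: float = np.nan
    converged: bool = True
    score_table: pd.DataFrame | None = None

    @property
    def selected_regions(self) -> dict[str, set[str]]:
        """Strictly-positive support per layer (expression = nonzero gamma)."""
        out: dict[str, set[str]] = {
            "expression": set(), "genomic": set(), "methylation": set(), "interaction": set()
        }
        for region, g in zip(self.train.expression_regions, self.fixed.gamma):
            if g != 0.0:
                out["expression"].add(region)
        labels = self.kernel_set.labels()
        for k in self.variance.support:
            layer, region = labels[k]
            out[layer].add(region)
        return out

    @property
    def training_ids(self) -> list[str]:
        return self.train.sample_ids


def _assemble_sigma(
    workspace: GmmWorkspace, sigma_sq: np.ndarray, sigma0_sq: float, n: int
) -> np.ndarray:
    active = np.flatnonzero(sigma_sq > 0)
    Sigma = sigma0_sq * np.eye(n)
    if active.size and workspace.stacked is not None:
        Sigma += np.tensordot(sigma_sq[active], workspace.stacked[active], axes=1)
    return Sigma


def _fit_single(
    dataset: OmicsDataset,
    kernel_set: KernelSet,
    workspace: GmmWorkspace,
    e_std: Standardizer | None,
    lambda1: float,
    lambda2: float,
    config: FitConfig,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[VarianceComponents, FixedEffects, np.ndarray, int, float, bool]:
    """One alternating fit at fixed penalties; returns state + diagnostics."""
    Y, X_d, E = dataset.Y, dataset.X_d, dataset.E
    n = dataset.n
    floor = SIGMA0_FLOOR_FRACTION * max(float(np.var(Y)), 1e-300)

    X_full = np.column_stack([np.ones(n), X_d])
    beta, *_ = np.linalg.lstsq(X_full, Y, rcond=None)
    gamma_std = np.zeros(E.shape[1])
    sigma_init: np.ndarray | None = None
    if warm is not None:
        sigma_init, gamma_std = warm[0].copy(), warm[1].copy()
    fixed = None
    residual = Y - X_full @ beta

    theta_prev: np.ndarray | None = None
    change = np.inf
    converged = False
    it = 0
    variance = VarianceComponents(sigma0_sq=float(np.var(Y)), sigma_sq=np.zeros(len(kernel_set)))
    for it in range(1, config.outer_max_iter + 1):
        b = moment_vector(workspace, residual)
        variance = solve_gmm(
            S=None, kernels=kernel_set, lambda1=lambda1, tol=config.gmm_tol,
            workspace=workspace, b=b,
            init=sigma_init,
        )
        sigma_init = variance.as_vector()
        sigma0 = max(variance.sigma0_sq, floor)
        Sigma = _assemble_sigma(workspace, variance.sigma_sq, sigma0, n)
        fixed = solve_penalized_gls(
            Y, X_d, E, Sigma, lambda2, tol=config.gls_tol,
            e_standardizer=e_std, init_gamma=gamma_std,
        )
        gamma_std = fixed.gamma_std
        residual = fixed.residual
        theta = np.concatenate([sigma_init, fixed.beta_d, fixed.gamma])
        if theta_prev is not None and theta.shape == theta_prev.shape:
            change = float(np.max(np.abs(theta - theta_prev) / (1.0 + np.abs(theta_prev))))
            if change < config.outer_tol:
                converged = True
                break
        theta_prev = theta
    variance = replace(variance, sigma0_sq=max(variance.sigma0_sq, floor))
    Sigma = _assemble_sigma(workspace, variance.sigma_sq, variance.sigma0_sq, n)
    return variance, fixed, Sigma, it, change, converged


def _default_grids(
    dataset: OmicsDataset, kernel_set: KernelSet, workspace: GmmWorkspace,
    e_std: Standardizer | None, config: FitConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Data-derived log-spaced penalty grids (largest value kills all terms)."""
    Y, X_d, E = dataset.Y, dataset.X_d, dataset.E
    n = dataset.n
    X_full = np.column_stack([np.ones(n), X_d])
    beta, *_ = np.linalg.lstsq(X_full, Y, rcond=None)
    Z = Y - X_full @ beta
    b = moment_vector(workspace, Z)
    sigma0_null = b[0] / n
    lam1_max = float(np.max(b[1:] - workspace.C[0, 1:] * sigma0_null, initial=0.0))
    if lam1_max <= 0:
        lam1_max = 1.0
    if E.shape[1] and e_std is not None:
        Es = e_std.transform(E)
        lam2_max = float(np.max(np.abs(Es.T @ Z)) / max(sigma0_null, 1e-300))
    else:
        lam2_max = 1.0
    if lam2_max <= 0:
        lam2_max = 1.0
    g1 = np.geomspace(lam1_max, lam1_max * config.lambda_min_ratio, config.n_lambda)
    g2 = np.geomspace(lam2_max, lam2_max * config.lambda_min_ratio, config.n_lambda)
    return g1, g2


def select_lambdas(
    train: OmicsDataset,
    kernel_config: KernelConfig | None = None,
    fit_config: FitConfig | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Choose (lambda1, lambda2) by seeded internal validation.

    Fits every grid pair on a sub-training split, scores MSE on the held-out
    internal validation split, and returns the argmin pair together with the
    full score table.  Ties break toward larger penalties (sparser models).
    """
    fit_config = fit_config or FitConfig()
    kernel_config = kernel_config or KernelConfig()
    from dataclasses import replace as dc_replace

    sel_config = dc_replace(fit_config, outer_tol=fit_config.selection_outer_tol)
    sub, val = split_train_test(
        train, 1.0 - fit_config.validation_fraction, seed=fit_config.seed
    )
    kernel_set = build_kernel_set(sub, kernel_config)
    workspace = make_workspace(kernel_set, n=sub.n)
    e_std = Standardizer.fit(sub.E) if sub.E.shape[1] else None
    g1, g2 = _grids_for(sub, kernel_set, workspace, e_std, fit_config)
    K_po, _ = build_cross_kernels(sub, val, kernel_set)
    stacked_po = np.stack(K_po) if K_po else None
    X_val = np.column_stack([np.ones(val.n), val.X_d])

    rows = []
    best: tuple[float, float] | None = None
    best_mse = np.inf
    warm_row: tuple[np.ndarray, np.ndarray] | None = None
    for lam1 in g1:
        warm = warm_row
        for j, lam2 in enumerate(g2):
            try:
                variance, fixed, Sigma, it, change, conv = _fit_single(
                    sub, kernel_set, workspace, e_std, lam1, lam2, sel_config, warm=warm
                )
            except linalg.LinAlgError as exc:  # scored as +inf, logged
                logger.warning("grid pair (%g, %g) failed: %s", lam1, lam2, exc)
                rows.append({"lambda1": lam1, "lambda2": lam2, "val_mse": np.inf,
                             "converged": False})
                continue
            warm = (variance.as_vector(), fixed.gamma_std)
            if j == 0:
                warm_row = warm
            pred = X_val @ fixed.beta_d + val.E @ fixed.gamma
            active = variance.support
            if active.size and stacked_po is not None:
                Sigma_po = np.tensordot(
                    variance.sigma_sq[active], stacked_po[active], axes=1
                )
                pred = pred + Sigma_po @ linalg.solve(Sigma, fixed.residual, assume_a="pos")
            mse = float(np.mean((val.Y - pred) ** 2))
            rows.append({"lambda1": lam1, "lambda2": lam2, "val_mse": mse,
                         "converged": conv})
            if mse < best_mse:  # grids descend, so ties keep the larger pair
                best_mse = mse
                best = (float(lam1), float(lam2))
    table = pd.DataFrame(rows)
    if best is None:
        raise RuntimeError("no penalty pair produced a finite validation score")
    return best[0], best[1], table


def _grids_for(dataset, kernel_set, workspace, e_std, fit_config):
    g1 = fit_config.lambda1_grid
    g2 = fit_config.lambda2_grid
    if g1 is None or g2 is None:
        d1, d2 = _default_grids(dataset, kernel_set, workspace, e_std, fit_config)
        g1 = d1 if g1 is None else g1
        g2 = d2 if g2 is None else g2
    return np.sort(np.atleast_1d(g1))[::-1], np.sort(np.atleast_1d(g2))[::-1]


def fit(
    train: OmicsDataset,
    kernel_config: KernelConfig | None = None,
    fit_config: FitConfig | None = None,
) -> MultiKernelLMM:
    """Fit the penalized multi-kernel LMM on a training dataset.

    Selects penalties by internal validation (unless the grids are single
    points or ``selection_rule == 'fixed'``, in which case the largest grid
    values are used directly), then runs the alternating updates on the full
    training data.
    """
    fit_config = fit_config or FitConfig()
    kernel_config = kernel_config or KernelConfig()
    if train.n <= train.X_d.shape[1] + 1:
        raise ValueError("need n > number of covariates + 1")
    kernel_set = build_kernel_set(train, kernel_config)
    if not len(kernel_set) and train.E.shape[1] == 0:
        raise ValueError("nothing to fit: no kernels and no expression columns")
    workspace = make_workspace(kernel_set, n=train.n)
    e_std = Standardizer.fit(train.E) if train.E.shape[1] else None

    score_table = None
    g1, g2 = _grids_for(train, kernel_set, workspace, e_std, fit_config)
    if fit_config.selection_rule == "internal_validation" and (len(g1) > 1 or len(g2) > 1):
        lam1, lam2, score_table = select_lambdas(train, kernel_config, fit_config)
    else:
        lam1, lam2 = float(g1[0]), float(g2[0])

    variance, fixed, Sigma, it, change, converged = _fit_single(
        train, kernel_set, workspace, e_std, lam1, lam2, fit_config
    )
    if not converged:
        warnings.warn(
            f"outer loop did not converge in {fit_config.outer_max_iter} iterations "
            f"(last relative change {change:.2e})",
            RuntimeWarning,
        )
    return MultiKernelLMM(
        variance=variance,
        fixed=fixed,
        kernel_set=kernel_set,
        Sigma=Sigma,
        e_standardizer=e_std,
        train=train,
        lambdas=(lam1, lam2),
        n_outer_iter=it,
        final_change=change,
        converged=converged,
        score_table=score_table,
    )


def predict(model: MultiKernelLMM, test: OmicsDataset) -> np.ndarray:
    """Conditional-mean (BLUP) predictions for new samples.

    Only kernels with strictly positive variance components contribute to
    the covariance between test and training samples.
    """
    X_test = np.column_stack([np.ones(test.n), test.X_d])
    if X_test.shape[1] != model.fixed.beta_d.shape[0]:
        raise ValueError("test covariates do not match the fitted model")
    pred = X_test @ model.fixed.beta_d
    if model.fixed.gamma.size:
        if test.E.shape[1] != model.fixed.gamma.size:
            raise ValueError("test expression columns do not match the fitted model")
        pred = pred + test.E @ model.fixed.gamma
    active = model.variance.support
    if active.size == 0:
        return pred
    labels = model.kernel_set.labels()
    for k in active:
        layer, region = labels[k]
        blocks = {"genomic": test.G_blocks, "methylation": test.M_blocks}
        need = [layer] if layer != "interaction" else ["genomic", "methylation"]
        for lay in need:
            if region not in blocks[lay]:
                raise ValueError(
                    f"test data lacks {lay} region {region!r} required by the fitted model"
                )
    K_po, _ = build_cross_kernels(model.train, test, model.kernel_set)
    Sigma_po = np.zeros((test.n, model.train.n))
    for k in active:
        Sigma_po += model.variance.sigma_sq[k] * K_po[k]
    alpha = linalg.solve(model.Sigma, model.fixed.residual, assume_a="pos")
    return pred + Sigma_po @ alpha


def save_model(model: MultiKernelLMM, path: str) -> None:
    """Serialize a fitted model to a single ``.npz`` archive (schema v1)."""
    meta = {
        "schema_version": SCHEMA_VERSION,
        "lambdas": list(model.lambdas),
        "n_outer_iter": model.n_outer_iter,
        "converged": bool(model.converged),
        "kernel_labels": model.kernel_set.labels(),
        "kernel_config": vars(model.kernel_set.config),
        "sample_ids": model.train.sample_ids,
        "covariate_names": model.train.covariate_names,
        "expression_regions": model.train.expression_regions,
        "region_map": model.train.region_map.entries,
        "g_regions": list(model.train.G_blocks),
        "m_regions": list(model.train.M_blocks),
    }
    arrays: dict[str, np.ndarray] = {
        "sigma0_sq": np.array(model.variance.sigma0_sq),
        "sigma_sq": model.variance.sigma_sq,
        "beta_d": model.fixed.beta_d,
        "gamma": model.fixed.gamma,
        "residual": model.fixed.residual,
        "Sigma": model.Sigma,
        "Y": model.train.Y,
        "X_d": model.train.X_d,
        "E": model.train.E,
    }
    if model.e_standardizer is not None:
        arrays["e_mean"] = model.e_standardizer.mean
        arrays["e_scale"] = model.e_standardizer.scale
    for region, mat in model.train.G_blocks.items():
        arrays[f"G::{region}"] = mat
    for region, mat in model.train.M_blocks.items():
        arrays[f"M::{region}"] = mat
    for (layer, region), std in model.kernel_set.standardizers.items():
        arrays[f"std_mean::{layer}::{region}"] = std.mean
        arrays[f"std_scale::{layer}::{region}"] = std.scale
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path: str) -> MultiKernelLMM:
    from .io import RegionMap

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        if meta["schema_version"] != SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema {meta['schema_version']}")
        kc = KernelConfig(**meta["kernel_config"])
        train = OmicsDataset(
            sample_ids=list(meta["sample_ids"]),
            Y=data["Y"],
            X_d=data["X_d"],
            covariate_names=list(meta["covariate_names"]),
            E=data["E"],
            expression_regions=list(meta["expression_regions"]),
            G_blocks={r: data[f"G::{r}"] for r in meta["g_regions"]},
            M_blocks={r: data[f"M::{r}"] for r in meta["m_regions"]},
            region_map=RegionMap([tuple(e) for e in meta["region_map"]]),
        )
        standardizers = {}
        for key in data.files:
            if key.startswith("std_mean::"):
                _, layer, region = key.split("::")
                standardizers[(layer, region)] = Standardizer(
                    mean=data[key], scale=data[f"std_scale::{layer}::{region}"]
                )
        kernel_set = build_kernel_set(train, kc)
        kernel_set.standardizers = standardizers
        e_std = None
        if "e_mean" in data.files:
            e_std = Standardizer(mean=data["e_mean"], scale=data["e_scale"])
        variance = VarianceComponents(
            sigma0_sq=float(data["sigma0_sq"]), sigma_sq=data["sigma_sq"]
        )
        fixed = FixedEffects(
            beta_d=data["beta_d"], gamma=data["gamma"], residual=data["residual"]
        )
        return MultiKernelLMM(
            variance=variance,
            fixed=fixed,
            kernel_set=kernel_set,
            Sigma=data["Sigma"],
            e_standardizer=e_std,
            train=train,
            lambdas=tuple(meta["lambdas"]),
            n_outer_iter=meta["n_outer_iter"],
            converged=meta["converged"],
        )
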