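"""Penalized method-of-moments estimation of variance components.

The residual second moment S = Z Z^T is matched to the model covariance
sum_k sigma_k^2 K_k + sigma_0^2 I by minimizing

    1/2 || S - sum_k K_k sigma_k^2 - sigma_0^2 I ||_F^2
        + lambda1 * sum_k sigma_k^2,    sigma^2 >= 0,

with the residual variance sigma_0^2 unpenalized.  Because the loss is
quadratic, the problem reduces to non-negative penalized least squares on the
Gram matrix of Frobenius inner products C[j, k] = <K_j, K_k>_F and the moment
vector b[k] = <K_k, S>_F = Z^T K_k Z.  C is O(K^2 n^2) but depends only on
the kernels, so it is computed once per fit; each solve is then O(K^2) per
coordinate sweep — the n x n residual is never re-materialized inside the
loop.

Updates are cyclic coordinate descent with projection onto [0, inf):

    sigma_k <- max(0, (b_k - sum_{j != k} C[k, j] sigma_j - lambda1 * [k >= 1]) / C[k, k])

which satisfies the KKT conditions at convergence and returns exact zeros for
inactive components.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._cd import cd_nonneg_gram
from .kernels import KernelSet

logger = logging.getLogger(__name__)


@dataclass
class VarianceComponents:
    """Non-negative weights over {identity} union kernels.

    ``sigma_sq[k]`` is the weight of the k-th kernel in the kernel set's
    order; strictly positive entries define the selected regions.
    """

    sigma0_sq: float
    sigma_sq: np.ndarray
    n_sweeps: int = 0
    kkt_residual: float = np.nan

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.sigma_sq > 0)

    def as_vector(self) -> np.ndarray:
        return np.concatenate([[self.sigma0_sq], self.sigma_sq])


@dataclass
class GmmWorkspace:
    """Precomputed moment matrices: identity is component 0.

    C[j, k] = <K_j, K_k>_F (so C[0, 0] = n, C[0, k] = trace(K_k));
    b[k] = <K_k, Z Z^T>_F.
    """

    C: np.ndarray
    stacked: np.ndarray | None = field(default=None, repr=False)  # (K, n, n)
    # per-kernel quadratic-form evaluators: F with K = F F^T, or an
    # interaction factor pair (Fg, Fm); None falls back to the dense kernel
    factors: list | None = field(default=None, repr=False)


def frobenius_gram(kernels: KernelSet | list[np.ndarray]) -> np.ndarray:
    """(K+1) x (K+1) Gram matrix of Frobenius inner products, identity first."""
    mats = [k.matrix for k in kernels.kernels] if isinstance(kernels, KernelSet) else list(kernels)
    if not mats:
        n = 0
        return np.array([[0.0]])
    n = mats[0].shape[0]
    for m in mats:
        if m.shape != (n, n):
            raise ValueError(f"kernel dimension mismatch: {m.shape} vs ({n}, {n})")
    K = len(mats)
    V = np.empty((K, n * n))
    for i, m in enumerate(mats):
        V[i] = m.ravel()
    C = np.empty((K + 1, K + 1))
    C[0, 0] = n
    traces = np.array([np.trace(m) for m in mats])
    C[0, 1:] = traces
    C[1:, 0] = traces
    C[1:, 1:] = V @ V.T
    return C


def make_workspace(kernels: KernelSet, n: int | None = None) -> GmmWorkspace:
    C = frobenius_gram(kernels)
    if C.shape == (1, 1) and n is not None:
        C[0, 0] = n  # empty kernel set: identity Gram entry comes from the caller
    stacked = (
        np.stack([k.matrix for k in kernels.kernels]) if len(kernels) else None
    )
    factors: list | None = []
    for k in kernels.kernels:
        if k.factor is not None:
            factors.append(k.factor)
        elif k.factor_pair is not None:
            factors.append(k.factor_pair)
        else:
            factors = None
            break
    return GmmWorkspace(C=C, stacked=stacked, factors=factors)


def moment_vector(workspace: GmmWorkspace, Z: np.ndarray) -> np.ndarray:
    """b[k] = Z^T K_k Z without forming Z Z^T (identity component first).

    Low-rank kernels use ||F^T Z||^2; interaction kernels use
    ||F_g^T diag(Z) F_m||_F^2, both exactly equal to the dense quadratic form.
    """
    n_k = 0 if workspace.stacked is None else workspace.stacked.shape[0]
    b = np.empty(1 + n_k)
    b[0] = Z @ Z
    if n_k == 0:
        return b
    if workspace.factors is not None:
        for i, fac in enumerate(workspace.factors):
            if isinstance(fac, tuple):
                Fg, Fm = fac
                T = (Fg * Z[:, None]).T @ Fm
                b[i + 1] = float((T * T).sum())
            else:
                v = fac.T @ Z
                b[i + 1] = float(v @ v)
    else:
        b[1:] = workspace.stacked @ Z @ Z
    return b


def _coordinate_descent(
    C: np.ndarray,
    b: np.ndarray,
    lambda1: float,
    tol: float,
    max_iter: int,
    init: np.ndarray | None,
) -> tuple[np.ndarray, int, float]:
    m = C.shape[0]
    penalty = np.full(m, lambda1)
    penalty[0] = 0.0  # residual variance is unpenalized
    diag = np.diag(C).copy()
    dead = diag <= 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} zero kernels: their components are fixed at 0",
            RuntimeWarning,
            stacklevel=3,
        )
        diag[dead] = 1.0
    sigma = np.zeros(m) if init is None else np.clip(np.asarray(init, float).copy(), 0.0, None)
    sigma[dead] = 0.0
    C_work = C.copy()
    np.fill_diagonal(C_work, diag)
    n_sweeps = cd_nonneg_gram(
        np.ascontiguousarray(C_work), np.ascontiguousarray(b, dtype=float),
        penalty, dead, sigma, tol, max_iter,
    )
    grad = C @ sigma - b + penalty  # grad of the smooth part plus the linear penalty
    active = sigma > 0
    kkt = 0.0
    if active.any():
        kkt = float(np.abs(grad[active]).max())
    inactive = (~active) & (~dead)
    if inactive.any():
        kkt = max(kkt, float(max(0.0, -grad[inactive].min())))
    return sigma, n_sweeps, kkt


def solve_gmm(
    S: np.ndarray,
    kernels: KernelSet,
    lambda1: float,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    workspace: GmmWorkspace | None = None,
    b: np.ndarray | None = None,
    init: np.ndarray | None = None,
) -> VarianceComponents:
    """Minimize the penalized Frobenius moment criterion over sigma^2 >= 0.

    Parameters
    ----------
    S : (n, n) ndarray
        Symmetric moment target, typically the residual outer product Z Z^T.
        Ignored when ``b`` is supplied directly.
    kernels : KernelSet
        Candidate kernels; the identity (residual variance) is always
        included as the unpenalized component 0.
    lambda1 : float
        L1 penalty on the kernel variance components (they are non-negative,
        so the penalty is linear).
    workspace, b, init : optional
        Reuse of the Frobenius Gram matrix, the moment vector and a warm
        start across outer iterations of the alternating fit.
    """
    if lambda1 < 0:
        raise ValueError(f"lambda1 must be >= 0, got {lambda1}")
    if b is None:
        S = np.asarray(S, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError(f"S must be square, got shape {S.shape}")
        if np.abs(S - S.T).max() > 1e-8 * max(1.0, np.abs(S).max()):
            raise ValueError("S must be symmetric")
    if workspace is None:
        workspace = make_workspace(kernels, n=None if S is None else S.shape[0])
    if b is None:
        mats = [k.matrix for k in kernels.kernels]
        b = np.empty(len(mats) + 1)
        b[0] = np.trace(S)
        for i, m in enumerate(mats):
            b[i + 1] = float(np.tensordot(m, S))
    sigma, sweeps, kkt = _coordinate_descent(
        workspace.C, b, lambda1, tol, max_iter, init
    )
    logger.debug("solve_gmm: %d sweeps, KKT residual %.3e", sweeps, kkt)
    return VarianceComponents(
        sigma0_sq=float(sigma[0]), sigma_sq=sigma[1:], n_sweeps=sweeps, kkt_residual=kkt
    )
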