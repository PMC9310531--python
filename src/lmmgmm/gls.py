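"""L1-penalized generalized least squares for the fixed effects.

With the covariance Sigma held fixed, maximizing the penalized Gaussian
log-likelihood in (beta_d, gamma) is a lasso on whitened data: factor
Sigma = L L^T and minimize

    1/2 || L^{-1} (Y - X_d beta_d - E gamma) ||^2 + lambda2 * ||gamma||_1.

Demographic covariates (including the always-added intercept) are
unpenalized and exact given gamma, so they are profiled out: gamma solves a
lasso on the whitened data projected off the whitened covariates, by
coordinate-wise soft-thresholding on the projected Gram matrix, and beta is
recovered by least squares.  Expression columns are standardized (train mean/scale)
before penalization so lambda2 acts evenly; coefficients are reported on the
original scale and excluded genes carry exact zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from ._cd import cd_lasso_gram
from .kernels import Standardizer


@dataclass
class FixedEffects:
    """Fitted fixed effects on the original data scale.

    ``beta_d[0]`` is the intercept, followed by the demographic covariates.
    ``residual`` recomputes exactly as Y - [1, X_d] beta_d - E gamma.
    """

    beta_d: np.ndarray
    gamma: np.ndarray
    residual: np.ndarray
    n_sweeps: int = 0
    gamma_std: np.ndarray | None = None  # standardized-scale coefficients, for warm starts


def _chol_with_jitter(Sigma: np.ndarray) -> np.ndarray:
    scale = max(np.trace(Sigma) / Sigma.shape[0], 1e-300)
    for jitter in (0.0, 1e-12, 1e-10, 1e-8, 1e-6, 1e-4):
        try:
            return linalg.cholesky(
                Sigma + jitter * scale * np.eye(Sigma.shape[0]), lower=True
            )
        except linalg.LinAlgError:
            continue
    raise linalg.LinAlgError(
        "covariance is numerically singular even after jitter; "
        "increase the residual-variance floor (sigma0_sq)"
    )


def whiten(Sigma: np.ndarray, columns: np.ndarray) -> np.ndarray:
    """L^{-1} @ columns for the lower Cholesky factor L of Sigma.

    Whitened inner products then equal Sigma^{-1}-weighted inner products.
    """
    Sigma = np.asarray(Sigma, dtype=float)
    if Sigma.ndim != 2 or Sigma.shape[0] != Sigma.shape[1]:
        raise ValueError(f"Sigma must be square, got {Sigma.shape}")
    L = _chol_with_jitter(Sigma)
    return linalg.solve_triangular(L, columns, lower=True)


def solve_penalized_gls(
    Y: np.ndarray,
    X_d: np.ndarray,
    E: np.ndarray,
    Sigma: np.ndarray,
    lambda2: float,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    e_standardizer: Standardizer | None = None,
    init_gamma: np.ndarray | None = None,
) -> FixedEffects:
    """Penalized GLS: exact LS for (intercept, X_d), soft-thresholding for gamma.

    Parameters
    ----------
    Y, X_d, E : arrays
        Outcome, demographic covariates (an intercept column is added
        internally and is unpenalized) and per-region expression.
    Sigma : (n, n) SPD ndarray
        Fixed outcome covariance from the current variance components.
    lambda2 : float
        L1 penalty on the (standardized-scale) expression coefficients.
    e_standardizer : optional
        Train-learned expression standardization, reused on validation/test
        fits; fitted from E when omitted.
    """
    if lambda2 < 0:
        raise ValueError(f"lambda2 must be >= 0, got {lambda2}")
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    X_full = np.column_stack([np.ones(n), np.asarray(X_d, dtype=float)])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("covariate matrix is rank deficient after adding an intercept")
    E = np.asarray(E, dtype=float)
    R_e = E.shape[1]
    std = e_standardizer
    if R_e and std is None:
        std = Standardizer.fit(E)
    Es = std.transform(E) if R_e else E

    L = _chol_with_jitter(np.asarray(Sigma, dtype=float))
    yt = linalg.solve_triangular(L, Y, lower=True)
    Xt = linalg.solve_triangular(L, X_full, lower=True)
    Et = linalg.solve_triangular(L, Es, lower=True) if R_e else Es

    XtX = Xt.T @ Xt
    X_cho = linalg.cho_factor(XtX)

    # beta is unpenalized and exact given gamma, so profile it out: gamma
    # solves a lasso on the data projected off the whitened covariates.
    gamma = np.zeros(R_e) if init_gamma is None else np.asarray(init_gamma, float).copy()
    n_sweeps = 0
    if R_e:
        XtE = Xt.T @ Et
        W = linalg.cho_solve(X_cho, XtE)  # (P, R_e)
        G = Et.T @ Et - XtE.T @ W  # Gram of projected columns
        xty = Xt.T @ yt
        c = Et.T @ yt - W.T @ xty
        n_sweeps = cd_lasso_gram(
            np.ascontiguousarray(G), np.ascontiguousarray(c), lambda2,
            gamma, tol, max_iter,
        )
    beta = linalg.cho_solve(X_cho, Xt.T @ (yt - (Et @ gamma if R_e else 0.0)))

    # report on the original scale: gamma_orig = gamma_std / scale, intercept absorbs means
    if R_e:
        gamma_orig = gamma / std.scale
        beta_orig = beta.copy()
        beta_orig[0] -= float(std.mean @ gamma_orig)
    else:
        gamma_orig = gamma
        beta_orig = beta
    residual = Y - X_full @ beta_orig - (E @ gamma_orig if R_e else 0.0)
    return FixedEffects(
        beta_d=beta_orig,
        gamma=gamma_orig,
        residual=residual,
        n_sweeps=n_sweeps,
        gamma_std=gamma,
    )
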