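"""Compiled coordinate-descent kernels.

Both solvers work on precomputed Gram matrices, so one full sweep is O(K^2)
regardless of sample size; the callers front-load all O(n^2) work.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def cd_nonneg_gram(
    C: np.ndarray,
    b: np.ndarray,
    penalty: np.ndarray,
    dead: np.ndarray,
    sigma: np.ndarray,
    tol: float,
    max_iter: int,
) -> int:
    """Cyclic projected coordinate descent for
    min 1/2 sigma' C sigma - b' sigma + penalty' sigma,  sigma >= 0.

    ``sigma`` is updated in place; returns the sweep count.  ``dead`` marks
    zero-diagonal components that stay fixed at 0.
    """
    m = C.shape[0]
    t = C @ sigma
    sweeps = 0
    for sweep in range(max_iter):
        sweeps = sweep + 1
        max_delta = 0.0
        for k in range(m):
            if dead[k]:
                continue
            ckk = C[k, k]
            new = (b[k] - (t[k] - ckk * sigma[k]) - penalty[k]) / ckk
            if new < 0.0:
                new = 0.0
            delta = new - sigma[k]
            if delta != 0.0:
                for j in range(m):
                    t[j] += C[j, k] * delta
                sigma[k] = new
                if abs(delta) > max_delta:
                    max_delta = abs(delta)
        if max_delta < tol:
            break
    return sweeps


@njit(cache=False)
def cd_lasso_gram(
    G: np.ndarray,
    c: np.ndarray,
    lam: float,
    gamma: np.ndarray,
    tol: float,
    max_iter: int,
) -> int:
    """Cyclic soft-thresholding coordinate descent for
    min 1/2 gamma' G gamma - c' gamma + lam * ||gamma||_1.

    ``gamma`` is updated in place; returns the sweep count.
    """
    m = G.shape[0]
    t = G @ gamma
    sweeps = 0
    for sweep in range(max_iter):
        sweeps = sweep + 1
        max_delta = 0.0
        for j in range(m):
            gjj = G[j, j]
            if gjj <= 0.0:
                continue
            rho = c[j] - (t[j] - gjj * gamma[j])
            if rho > lam:
                new = (rho - lam) / gjj
            elif rho < -lam:
                new = (rho + lam) / gjj
            else:
                new = 0.0
            delta = new - gamma[j]
            if delta != 0.0:
                for i in range(m):
                    t[i] += G[i, j] * delta
                gamma[j] = new
                if abs(delta) > max_delta:
                    max_delta = abs(delta)
        if max_delta < tol:
            break
    return sweeps
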