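"""Gram-based coordinate descent for the lasso path.

Solves, for a descending grid of penalties ``lam``,

    min_beta  (1/2n) * ||y - X beta||^2  +  lam * ||beta||_1

given only the Gram moments ``G = X'X / n`` and ``b = X'y / n`` (so a path at
p = 20 costs microseconds and bootstrap loops stay cheap).  Columns with zero
Gram diagonal (constant covariates after centring) keep a zero coefficient.
Warm starts carry the solution down the path.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: coordinate-update convergence threshold (max abs coefficient change)
DEFAULT_TOL = 1e-12
DEFAULT_MAX_ITER = 100_000


@njit(cache=True)
def _cd_path(G, b, lams, tol, max_iter):  # pragma: no cover - jitted
    p = b.shape[0]
    n_lam = lams.shape[0]
    coefs = np.zeros((n_lam, p))
    beta = np.zeros(p)
    for il in range(n_lam):
        lam = lams[il]
        for _ in range(max_iter):
            dmax = 0.0
            for j in range(p):
                gjj = G[j, j]
                if gjj <= 0.0:
                    beta[j] = 0.0
                    continue
                s = b[j] + gjj * beta[j]
                for k in range(p):
                    s -= G[j, k] * beta[k]
                if s > lam:
                    bj = (s - lam) / gjj
                elif s < -lam:
                    bj = (s + lam) / gjj
                else:
                    bj = 0.0
                d = bj - beta[j]
                if d != 0.0:
                    beta[j] = bj
                    ad = abs(d)
                    if ad > dmax:
                        dmax = ad
            if dmax < tol:
                break
        coefs[il] = beta
    return coefs


def cd_path(
    G: np.ndarray,
    b: np.ndarray,
    lams: np.ndarray,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> np.ndarray:
    """Coefficient matrix of shape (len(lams), p) along the penalty path."""
    G = np.ascontiguousarray(G, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    lams = np.ascontiguousarray(lams, dtype=np.float64)
    return _cd_path(G, b, lams, float(tol), int(max_iter))


def standardize(X: np.ndarray):
    """Center/scale columns (population sd); zero-variance columns get scale 1
    and become identically zero after centring."""
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale_safe = np.where(scale > 0, scale, 1.0)
    Xs = (X - center) / scale_safe
    return Xs, center, scale_safe, scale > 0


def path_on_data(X: np.ndarray, y: np.ndarray, lams: np.ndarray,
                 tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER):
    """Lasso path on raw data; returns original-scale coefficients and
    intercepts, shapes (n_lam, p) and (n_lam,)."""
    n = X.shape[0]
    Xs, center, scale, _ = standardize(X)
    ybar = y.mean()
    yc = y - ybar
    G = Xs.T @ Xs / n
    b = Xs.T @ yc / n
    coefs_std = cd_path(G, b, lams, tol, max_iter)
    coefs = coefs_std / scale
    intercepts = ybar - coefs @ center
    return coefs, intercepts


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty shrinking every slope to zero (standardised scale)."""
    n = X.shape[0]
    Xs, _, _, nonconst = standardize(X)
    if not nonconst.any():
        raise ValueError("all covariates are constant")
    return float(np.abs(Xs.T @ (y - y.mean())).max() / n)
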