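"""Graphical-lasso solver: blockwise coordinate descent, jit-compiled.

Maximizes  log det K - tr(SK) - lam * sum_{i != j} |K_ij|  (the penalty is
off-diagonal only, so marginal scales are untouched).  One column of the
working covariance W is updated per step by solving an L1-penalized
regression with coordinate descent; the precision K is recovered from the
regression coefficients at the end.  The solver is warm-startable, which
makes descending penalty paths cheap.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["glasso_cd", "support_refit"]


@njit(cache=True)
def _inner_lasso(W11, s12, lam, beta, inner_tol, inner_max_iter):
    pm = s12.shape[0]
    for _ in range(inner_max_iter):
        delta = 0.0
        for k in range(pm):
            r = s12[k]
            for l in range(pm):
                if l != k:
                    r -= W11[k, l] * beta[l]
            if r > lam:
                new = (r - lam) / W11[k, k]
            elif r < -lam:
                new = (r + lam) / W11[k, k]
            else:
                new = 0.0
            d = abs(new - beta[k])
            if d > delta:
                delta = d
            beta[k] = new
        if delta < inner_tol:
            break
    return beta


@njit(cache=True)
def _glasso_sweeps(S, lam, tol, max_iter, W, B):
    p = S.shape[0]
    idx = np.empty(p - 1, dtype=np.int64)
    W11 = np.empty((p - 1, p - 1))
    s12 = np.empty(p - 1)
    converged = False
    n_sweeps = 0
    for _ in range(max_iter):
        n_sweeps += 1
        max_change = 0.0
        for j in range(p):
            k = 0
            for i in range(p):
                if i != j:
                    idx[k] = i
                    k += 1
            for a in range(p - 1):
                s12[a] = S[idx[a], j]
                for b in range(p - 1):
                    W11[a, b] = W[idx[a], idx[b]]
            beta = B[:, j]
            _inner_lasso(W11, s12, lam, beta, 0.1 * tol, 200)
            for a in range(p - 1):
                w_new = 0.0
                for b in range(p - 1):
                    w_new += W11[a, b] * beta[b]
                change = abs(w_new - W[idx[a], j])
                if change > max_change:
                    max_change = change
                W[idx[a], j] = w_new
                W[j, idx[a]] = w_new
        if max_change < tol:
            converged = True
            break
    # recover the precision from the regression coefficients
    K = np.zeros((p, p))
    for j in range(p):
        k = 0
        for i in range(p):
            if i != j:
                idx[k] = i
                k += 1
        dot = 0.0
        for a in range(p - 1):
            dot += W[idx[a], j] * B[a, j]
        K[j, j] = 1.0 / (W[j, j] - dot)
        for a in range(p - 1):
            K[idx[a], j] = -B[a, j] * K[j, j]
    return K, converged, n_sweeps


@njit(cache=True)
def _refit_sweeps(S, support, tol, max_iter, W, B):
    """Covariance-selection MLE constrained to ``support`` (no penalty).

    Same blockwise regressions as the lasso solver, but coefficients outside
    the support are pinned at zero instead of soft-thresholded.
    """
    p = S.shape[0]
    idx = np.empty(p - 1, dtype=np.int64)
    W11 = np.empty((p - 1, p - 1))
    s12 = np.empty(p - 1)
    converged = False
    for _ in range(max_iter):
        max_change = 0.0
        for j in range(p):
            k = 0
            for i in range(p):
                if i != j:
                    idx[k] = i
                    k += 1
            for a in range(p - 1):
                s12[a] = S[idx[a], j]
                for b in range(p - 1):
                    W11[a, b] = W[idx[a], idx[b]]
            beta = B[:, j]
            for _inner in range(200):
                delta = 0.0
                for a in range(p - 1):
                    if not support[idx[a], j]:
                        beta[a] = 0.0
                        continue
                    r = s12[a]
                    for b in range(p - 1):
                        if b != a:
                            r -= W11[a, b] * beta[b]
                    new = r / W11[a, a]
                    d = abs(new - beta[a])
                    if d > delta:
                        delta = d
                    beta[a] = new
                if delta < 0.1 * tol:
                    break
            for a in range(p - 1):
                w_new = 0.0
                for b in range(p - 1):
                    w_new += W11[a, b] * beta[b]
                change = abs(w_new - W[idx[a], j])
                if change > max_change:
                    max_change = change
                W[idx[a], j] = w_new
                W[j, idx[a]] = w_new
        if max_change < tol:
            converged = True
            break
    K = np.zeros((p, p))
    for j in range(p):
        k = 0
        for i in range(p):
            if i != j:
                idx[k] = i
                k += 1
        dot = 0.0
        for a in range(p - 1):
            dot += W[idx[a], j] * B[a, j]
        K[j, j] = 1.0 / (W[j, j] - dot)
        for a in range(p - 1):
            K[idx[a], j] = -B[a, j] * K[j, j]
    return K, converged


def support_refit(
    S: np.ndarray,
    support: np.ndarray,
    tol: float = 1e-5,
    max_iter: int = 1000,
) -> tuple[np.ndarray, bool]:
    """Unpenalized precision MLE with off-support entries constrained to zero."""
    S = np.ascontiguousarray(S, dtype=np.float64)
    p = S.shape[0]
    support = np.ascontiguousarray(support, dtype=np.bool_)
    W = S.copy()
    B = np.zeros((p - 1, p))
    K, converged = _refit_sweeps(S, support, float(tol), int(max_iter), W, B)
    return (K + K.T) / 2.0, converged


def glasso_cd(
    S: np.ndarray,
    lam: float,
    tol: float = 1e-5,
    max_iter: int = 1000,
    W_init: np.ndarray | None = None,
    B_init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool, int]:
    """Solve the off-diagonal-penalized graphical lasso.

    Returns ``(K, W, B, converged, n_sweeps)``; pass ``W``/``B`` back in as
    ``W_init``/``B_init`` to warm-start the next penalty on a path.
    """
    S = np.ascontiguousarray(S, dtype=np.float64)
    p = S.shape[0]
    W = S.copy() if W_init is None else W_init.copy()
    np.fill_diagonal(W, np.diag(S))  # the diagonal is never penalized
    B = np.zeros((p - 1, p)) if B_init is None else B_init.copy()
    K, converged, n_sweeps = _glasso_sweeps(S, float(lam), float(tol), int(max_iter), W, B)
    K = (K + K.T) / 2.0
    return K, W, B, converged, n_sweeps
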