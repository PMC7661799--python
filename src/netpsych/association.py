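"""Mixed-type correlation matrices: Pearson, polyserial and polychoric.

Ordinal measures are modelled as discretized latent standard normals, so the
appropriate pairwise association is the latent correlation: polychoric for
two ordinal variables, polyserial for an ordinal/continuous pair, Pearson for
two continuous variables.  Both latent estimators use the standard two-step
maximum-likelihood recipe: thresholds are fixed at normal quantiles of the
marginal cumulative proportions, then the correlation is found by a
one-dimensional likelihood maximization.

Bivariate-normal cell probabilities are evaluated by Gauss-Legendre
quadrature of the conditional-normal representation
P(a<X<b, c<Y<d) = int_a^b phi(x) [Phi((d-rx)/s) - Phi((c-rx)/s)] dx,
which is smooth in r and vectorizes over the whole contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import ndtr, ndtri

from .datagen import MeasureTable

__all__ = [
    "AssociationMatrix",
    "pearson_corr",
    "polychoric_corr",
    "polyserial_corr",
    "mixed_correlation_matrix",
    "significance_filter",
    "nearest_psd",
]

RHO_BOUND = 0.999
# Ordinal scales with more observed categories than this behave like sums of
# many items; treat them as continuous to keep contingency tables dense.
CONTINUOUS_LEVELS_THRESHOLD = 10

_TAIL = 6.0  # latent scores beyond +-6 sd carry ~1e-9 mass
_GL_NODES = 32


@dataclass
class AssociationMatrix:
    """Symmetric pairwise-association matrix with method tags and p-values."""

    names: list[str]
    r: np.ndarray
    method: np.ndarray  # dtype=object, entries in {"pearson","polyserial","polychoric",""}
    p_value: np.ndarray
    n: int

    @property
    def p(self) -> int:
        return len(self.names)

    def validate(self) -> None:
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0):
            raise ValueError("correlation matrix diagonal must be 1")
        if np.any(np.abs(self.r) > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")
        if np.any((self.p_value < 0) | (self.p_value > 1)):
            raise ValueError("p-values must lie in [0, 1]")


def pearson_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation with the two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    for name, v in (("x", x), ("y", y)):
        if np.ptp(v) == 0:
            raise ValueError(f"{name} is constant; correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _thresholds_from_margins(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Observed category codes -> (sorted categories, interior normal quantiles)."""
    cats, counts = np.unique(codes, return_counts=True)
    if len(cats) < 2:
        raise ValueError("ordinal variable has a single observed category")
    cum = np.cumsum(counts)[:-1] / counts.sum()
    return cats, ndtri(cum)


def _strip_quadrature(edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights (weight includes phi(x)) for each row strip."""
    lo = np.clip(edges[:-1], -_TAIL, _TAIL)
    hi = np.clip(edges[1:], -_TAIL, _TAIL)
    gl_x, gl_w = np.polynomial.legendre.leggauss(_GL_NODES)
    half = (hi - lo) / 2.0
    mid = (hi + lo) / 2.0
    nodes = mid[:, None] + half[:, None] * gl_x[None, :]  # (strips, nodes)
    weights = half[:, None] * gl_w[None, :] * stats.norm.pdf(nodes)
    return nodes, weights


def _polychoric_cell_probs(
    nodes: np.ndarray, weights: np.ndarray, col_edges: np.ndarray, rho: float
) -> np.ndarray:
    """Cell probabilities of the bivariate normal over a threshold grid."""
    s = np.sqrt(max(1.0 - rho * rho, 1e-12))
    z = (col_edges[None, None, :] - rho * nodes[:, :, None]) / s
    cdf = ndtr(z)
    cdf[..., 0] = 0.0
    cdf[..., -1] = 1.0
    band = np.diff(cdf, axis=-1)  # (strips, nodes, cols)
    return np.einsum("sn,snc->sc", weights, band)


def _wald_p(negloglik, rho_hat: float, h: float = 1e-3) -> float:
    """Two-sided Wald p from the numerically differentiated observed information."""
    if abs(rho_hat) >= RHO_BOUND - 2 * h:
        return 0.0  # boundary estimate: association is effectively perfect
    f0 = negloglik(rho_hat)
    info = (negloglik(rho_hat + h) - 2 * f0 + negloglik(rho_hat - h)) / (h * h)
    if not np.isfinite(info) or info <= 0:
        # fall back on the likelihood ratio against independence
        lr = 2.0 * (negloglik(0.0) - f0)
        return float(stats.chi2.sf(max(lr, 0.0), 1))
    z = abs(rho_hat) * np.sqrt(info)
    return float(2.0 * ndtr(-z))


def _maximize_rho(negloglik) -> float:
    res = minimize_scalar(
        negloglik, bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
        options={"xatol": 1e-4},
    )
    best_rho, best_f = float(res.x), float(res.fun)
    for b in (-RHO_BOUND, RHO_BOUND):  # golden section never lands on the bounds
        fb = negloglik(b)
        if fb < best_f:
            best_rho, best_f = b, fb
    return float(np.clip(best_rho, -RHO_BOUND, RHO_BOUND))


def polychoric_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-step ML polychoric correlation between two ordinal variables."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size == 0 or x.shape != y.shape:
        raise ValueError("x and y must be non-empty and of equal length")
    cats_x, thr_x = _thresholds_from_margins(x)
    cats_y, thr_y = _thresholds_from_margins(y)
    table = np.zeros((len(cats_x), len(cats_y)))
    ix = np.searchsorted(cats_x, x)
    iy = np.searchsorted(cats_y, y)
    np.add.at(table, (ix, iy), 1.0)

    row_edges = np.concatenate(([-np.inf], thr_x, [np.inf]))
    col_edges = np.concatenate(([-np.inf], thr_y, [np.inf]))
    nodes, weights = _strip_quadrature(row_edges)

    def negloglik(rho: float) -> float:
        probs = _polychoric_cell_probs(nodes, weights, col_edges, rho)
        return float(-np.sum(table * np.log(np.clip(probs, 1e-12, None))))

    rho = _maximize_rho(negloglik)
    return rho, _wald_p(negloglik, rho)


def polyserial_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-step ML polyserial correlation (``x`` continuous, ``y`` ordinal)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.size == 0 or x.shape != y.shape:
        raise ValueError("x and y must be non-empty and of equal length")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; polyserial correlation undefined")
    cats, thr = _thresholds_from_margins(y)
    z = (x - x.mean()) / x.std()
    edges = np.concatenate(([-np.inf], thr, [np.inf]))
    iy = np.searchsorted(cats, y)
    upper = edges[iy + 1]
    lower = edges[iy]

    def negloglik(rho: float) -> float:
        s = np.sqrt(max(1.0 - rho * rho, 1e-12))
        p = ndtr((upper - rho * z) / s) - ndtr((lower - rho * z) / s)
        return float(-np.sum(np.log(np.clip(p, 1e-12, None))))

    rho = _maximize_rho(negloglik)
    return rho, _wald_p(negloglik, rho)


def _effective_kind(v) -> str:
    if v.kind == "ordinal" and (v.levels or 0) > CONTINUOUS_LEVELS_THRESHOLD:
        return "continuous"
    return v.kind


def mixed_correlation_matrix(table: MeasureTable) -> AssociationMatrix:
    """Pairwise association matrix with per-pair method dispatch on typing."""
    if table.n < 3:
        raise ValueError("need at least 3 subjects")
    values = table.values()
    kinds = [_effective_kind(v) for v in table.variables]
    for name, col in zip(table.names, values.T):
        if np.ptp(col) == 0:
            raise ValueError(f"column {name!r} is constant")
    p = len(kinds)
    r = np.eye(p)
    pv = np.zeros((p, p))
    method = np.full((p, p), "", dtype=object)
    for i in range(p):
        for j in range(i + 1, p):
            xi, xj = values[:, i], values[:, j]
            if kinds[i] == "continuous" and kinds[j] == "continuous":
                tag, (rij, pij) = "pearson", pearson_corr(xi, xj)
            elif kinds[i] == "ordinal" and kinds[j] == "ordinal":
                tag, (rij, pij) = "polychoric", polychoric_corr(xi, xj)
            elif kinds[i] == "continuous":
                tag, (rij, pij) = "polyserial", polyserial_corr(xi, xj)
            else:
                tag, (rij, pij) = "polyserial", polyserial_corr(xj, xi)
            r[i, j] = r[j, i] = rij
            pv[i, j] = pv[j, i] = pij
            method[i, j] = method[j, i] = tag
    out = AssociationMatrix(list(table.names), r, method, pv, table.n)
    out.validate()
    return out


def significance_filter(
    assoc: AssociationMatrix, alpha: float = 0.05
) -> tuple[AssociationMatrix, int]:
    """Zero out correlations whose p-value exceeds ``alpha``.

    Returns the filtered matrix and the number of (upper-triangle) entries
    set to zero.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie strictly in (0, 1), got {alpha}")
    r = assoc.r.copy()
    drop = assoc.p_value > alpha
    np.fill_diagonal(drop, False)
    r[drop] = 0.0
    n_zeroed = int(np.triu(drop, 1).sum())
    return AssociationMatrix(assoc.names, r, assoc.method.copy(), assoc.p_value.copy(), assoc.n), n_zeroed


def nearest_psd(r: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Repair an indefinite correlation matrix by eigenvalue clipping.

    Eigenvalues are clipped at ``eps``, the matrix is reconstructed, and the
    diagonal is rescaled back to 1.  Positive-semidefinite inputs are returned
    unchanged.
    """
    r = np.asarray(r, dtype=float)
    if not np.allclose(r, r.T, atol=1e-10):
        raise ValueError("input matrix is not symmetric")
    vals, vecs = np.linalg.eigh(r)
    if vals.min() >= 0:
        return r.copy()
    rebuilt = (vecs * np.clip(vals, eps, None)) @ vecs.T
    d = np.sqrt(np.diag(rebuilt))
    rebuilt = rebuilt / np.outer(d, d)
    np.fill_diagonal(rebuilt, 1.0)
    return rebuilt
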