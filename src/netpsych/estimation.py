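"""Regularized Gaussian graphical model estimation.

The pipeline stage: an L1-penalized precision matrix (graphical lasso) is fit
over a descending log-spaced penalty grid, the penalty is chosen by BIC, and
the selected precision is converted to a partial-correlation network
(w_ij = -K_ij / sqrt(K_ii K_jj)).  The input is the significance-filtered,
positive-semidefinite-repaired mixed correlation matrix, not a covariance:
mixed-type correlations carry no common covariance scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._glasso import glasso_cd, support_refit
from .association import mixed_correlation_matrix, nearest_psd, significance_filter
from .datagen import MeasureTable

__all__ = [
    "PrecisionEstimate",
    "NetworkModel",
    "graphical_lasso",
    "kkt_violation",
    "bic_score",
    "select_penalty",
    "precision_to_partial",
    "estimate_network",
]

logger = logging.getLogger(__name__)

EDGE_TOL = 1e-8  # |K_ij| below this counts as a structural zero


@dataclass
class PrecisionEstimate:
    """An estimated precision (inverse covariance) matrix and its penalty."""

    precision: np.ndarray
    lam: float
    converged: bool = True

    def __post_init__(self) -> None:
        self.precision = np.asarray(self.precision, dtype=float)

    @property
    def p(self) -> int:
        return self.precision.shape[0]

    def edge_count(self) -> int:
        return int(np.count_nonzero(np.abs(np.triu(self.precision, 1)) > EDGE_TOL))


@dataclass
class NetworkModel:
    """A weighted undirected partial-correlation network."""

    nodes: list[str]
    weights: np.ndarray  # p x p symmetric, zero diagonal
    lam: float
    bic: float
    n: int
    stages: dict = field(default_factory=dict)  # per-stage log of the estimation

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.allclose(self.weights, self.weights.T, atol=1e-10):
            raise ValueError("edge weights must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("edge-weight diagonal must be zero")

    @property
    def p(self) -> int:
        return len(self.nodes)

    def edge_count(self) -> int:
        return int(np.count_nonzero(np.abs(np.triu(self.weights, 1)) > EDGE_TOL))

    def degree(self, node: str) -> int:
        i = self.nodes.index(node)
        return int(np.count_nonzero(np.abs(self.weights[i]) > EDGE_TOL))

    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        p = self.p
        for i in range(p):
            for j in range(i + 1, p):
                if abs(self.weights[i, j]) > EDGE_TOL:
                    out.append((self.nodes[i], self.nodes[j], float(self.weights[i, j])))
        return out


def _check_input_matrix(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("S must be symmetric")
    if not np.allclose(np.diag(S), 1.0, atol=1e-6):
        raise ValueError("S must have unit diagonal (a correlation matrix)")
    if np.linalg.eigvalsh(S).min() < -1e-8:
        raise ValueError("S is not positive semidefinite; repair it first")
    return S


def graphical_lasso(
    S: np.ndarray, lam: float, tol: float = 1e-5, max_iter: int = 1000
) -> PrecisionEstimate:
    """L1-penalized precision estimate at penalty ``lam``.

    ``lam = 0`` returns the unpenalized maximum-likelihood estimate, i.e. the
    plain matrix inverse.
    """
    S = _check_input_matrix(S)
    if lam < 0:
        raise ValueError("penalty must be nonnegative")
    if lam == 0:
        try:
            K = np.linalg.inv(S)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "S is singular: the unpenalized (lambda=0) estimate does not exist"
            ) from exc
        return PrecisionEstimate((K + K.T) / 2.0, 0.0, converged=True)
    K, _, _, converged, n_sweeps = glasso_cd(S, lam, tol=tol, max_iter=max_iter)
    if not converged:
        est = PrecisionEstimate(K, float(lam), converged=False)
        raise RuntimeError(
            f"graphical lasso did not converge at lambda={lam} within {max_iter} sweeps "
            f"(KKT residual {kkt_violation(S, est):.3g})"
        )
    return PrecisionEstimate(K, float(lam), converged=True)


def kkt_violation(S: np.ndarray, est: PrecisionEstimate) -> float:
    """Maximum off-diagonal violation of the stationarity conditions.

    For the penalized log-likelihood the gradient condition at the solution K
    reads W - S - lam * sign(K) = 0 on active off-diagonal entries (W = K^-1)
    and |W_ij - S_ij| <= lam on zeroed ones.
    """
    S = np.asarray(S, dtype=float)
    W = np.linalg.inv(est.precision)
    diff = W - S
    off = ~np.eye(S.shape[0], dtype=bool)
    active = off & (np.abs(est.precision) > EDGE_TOL)
    inactive = off & ~active
    v_active = np.abs(diff[active] - est.lam * np.sign(est.precision[active])) if active.any() else np.array([0.0])
    v_inactive = np.clip(np.abs(diff[inactive]) - est.lam, 0.0, None) if inactive.any() else np.array([0.0])
    return float(max(v_active.max(), v_inactive.max()))


def bic_score(est: PrecisionEstimate, S: np.ndarray, n: int) -> float:
    """Bayesian information criterion: -2*loglik + (edge count)*ln(n)."""
    S = np.asarray(S, dtype=float)
    K = est.precision
    if S.shape != K.shape:
        raise ValueError("dimension mismatch between S and the precision estimate")
    if n < 2:
        raise ValueError("n must be >= 2")
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0 or not np.isfinite(logdet):
        raise np.linalg.LinAlgError("precision estimate is singular; BIC undefined")
    loglik = (n / 2.0) * (logdet - np.trace(S @ K))
    return float(-2.0 * loglik + est.edge_count() * np.log(n))


def select_penalty(
    S: np.ndarray,
    n: int,
    grid_size: int = 100,
    tol: float = 1e-5,
    lambda_floor_ratio: float = 0.01,
    refit: bool = True,
) -> tuple[float, PrecisionEstimate]:
    """BIC penalty selection over a descending log-spaced lambda grid.

    The grid runs from lambda_max (the largest absolute off-diagonal of S,
    beyond which the model is empty) down to ``lambda_floor_ratio`` times it.
    With ``refit=True`` (default) each candidate edge set is scored by the
    BIC of the unpenalized MLE constrained to that support: scoring the
    shrunken lasso estimate itself systematically favours the densest model,
    because the L1 penalty degrades the likelihood of the retained strong
    edges.  Ties in BIC resolve toward the larger penalty (the sparser
    model).
    """
    S = _check_input_matrix(S)
    if grid_size < 1:
        raise ValueError("grid_size must be >= 1")
    p = S.shape[0]
    lam_max = float(np.max(np.abs(S - np.eye(p)))) if p > 1 else 0.0
    if lam_max <= 0:
        est = PrecisionEstimate(np.eye(p), 0.0)
        return 0.0, est
    if grid_size == 1:
        grid = np.array([lam_max])
    else:
        grid = np.geomspace(lam_max, lambda_floor_ratio * lam_max, grid_size)
    best: tuple[float, PrecisionEstimate, float] | None = None
    failures: list[str] = []
    W = B = None  # warm start along the descending path
    for lam in grid:
        try:
            K, W, B, converged, _ = glasso_cd(S, float(lam), tol=tol, W_init=W, B_init=B)
            if not converged:
                raise RuntimeError("did not converge")
            est = PrecisionEstimate(K, float(lam), converged=True)
            if refit:
                sup = np.abs(K) > EDGE_TOL
                np.fill_diagonal(sup, False)
                K_refit, conv_refit = support_refit(S, sup, tol=tol)
                if not conv_refit:
                    raise RuntimeError("support refit did not converge")
                est = PrecisionEstimate(K_refit, float(lam), converged=True)
            bic = bic_score(est, S, n)
        except (RuntimeError, np.linalg.LinAlgError) as exc:
            failures.append(f"lambda={lam:.4g}: {exc}")
            continue
        if best is None or bic < best[2] - 1e-9:
            best = (float(lam), est, bic)
    if best is None:
        raise RuntimeError(
            "graphical lasso failed on the entire penalty grid: " + "; ".join(failures[:3])
        )
    return best[0], best[1]


def precision_to_partial(
    est: PrecisionEstimate,
    nodes: list[str] | None = None,
    n: int = 0,
    bic: float = float("nan"),
) -> NetworkModel:
    """Convert a precision matrix to the partial-correlation edge weights."""
    K = est.precision
    d = np.diag(K)
    if np.any(d <= 0):
        raise ValueError("precision diagonal must be positive")
    scale = np.sqrt(np.outer(d, d))
    w = -K / scale
    np.fill_diagonal(w, 0.0)
    w[np.abs(w) <= EDGE_TOL] = 0.0
    if nodes is None:
        nodes = [f"v{i}" for i in range(K.shape[0])]
    return NetworkModel(list(nodes), (w + w.T) / 2.0, est.lam, float(bic), n)


def estimate_network(
    table: MeasureTable,
    alpha: float = 0.05,
    grid_size: int = 100,
    tol: float = 1e-5,
    filter_stage: str = "post",
) -> NetworkModel:
    """Full estimation stage: mixed correlations, significance filtering,
    PSD repair, penalized precision estimation, partial-correlation network.

    ``filter_stage`` controls where "only significant correlations are
    maintained": ``"post"`` (default) removes estimated edges whose
    underlying pairwise correlation has p > alpha after regularization;
    ``"pre"`` zeroes the correlations before the graphical lasso (this can
    leave the input matrix strongly indefinite at small n, making model
    selection unstable -- see the methods notes); ``"none"`` disables it.
    """
    if filter_stage not in ("pre", "post", "none"):
        raise ValueError(f"unknown filter_stage {filter_stage!r}")
    assoc = mixed_correlation_matrix(table)
    n_zeroed = 0
    r = assoc.r
    if filter_stage == "pre":
        filtered, n_zeroed = significance_filter(assoc, alpha=alpha)
        r = filtered.r
    S = nearest_psd(r)
    lam, est = select_penalty(S, table.n, grid_size=grid_size, tol=tol)
    bic = bic_score(est, S, table.n)
    net = precision_to_partial(est, nodes=table.names, n=table.n, bic=bic)
    if filter_stage == "post":
        drop = (assoc.p_value > alpha) & (np.abs(net.weights) > EDGE_TOL)
        np.fill_diagonal(drop, False)
        n_zeroed = int(np.triu(drop, 1).sum())
        net.weights[drop] = 0.0
    net.stages = {
        "filter_stage": filter_stage,
        "n_correlations_zeroed": n_zeroed,
        "lambda": lam,
        "edge_count": net.edge_count(),
    }
    logger.info(
        "estimate_network: filter=%s zeroed=%d lambda*=%.4g edges=%d",
        filter_stage, n_zeroed, lam, net.edge_count(),
    )
    return net
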