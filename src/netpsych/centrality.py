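"""Node centrality for weighted partial-correlation networks.

Edge weights are association strengths, so geodesic distances use the
reciprocal transform d_ij = 1/|w_ij|: stronger edges are shorter.  Three
indices are computed:

* strength  k_i = sum_j |w_ij| -- local connectivity;
* betweenness b_i = sum_{j<k} p_jk(i)/p_jk, the tie-weighted count of
  geodesics through i (endpoints excluded, unnormalized);
* closeness, the reciprocal of the mean geodesic distance from a node to the
  others in its component: r_i / sum_j d_ij with r_i the number of reachable
  other nodes (isolated nodes score 0).

Equal-length geodesics are all counted; path-length ties are detected with a
small relative tolerance so that equal sums of floating-point distances
compare as equal.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np

from .estimation import EDGE_TOL, NetworkModel

__all__ = [
    "CentralityProfile",
    "edge_distances",
    "node_strength",
    "shortest_paths_counts",
    "betweenness",
    "closeness",
    "centrality_profile",
]

_REL_TOL = 1e-9
_ABS_TOL = 1e-12


def _close(a: float, b: float) -> bool:
    return math.isclose(a, b, rel_tol=_REL_TOL, abs_tol=_ABS_TOL)


@dataclass
class CentralityProfile:
    """Per-node strength, betweenness and closeness for one network."""

    nodes: list[str]
    strength: np.ndarray
    betweenness: np.ndarray
    closeness: np.ndarray
    distance_matrix: np.ndarray

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {
            metric: dict(zip(self.nodes, getattr(self, metric).tolist()))
            for metric in ("strength", "betweenness", "closeness")
        }


def edge_distances(network: NetworkModel) -> np.ndarray:
    """Geodesic edge lengths d_ij = 1/|w_ij|; absent edges are infinite."""
    w = np.abs(network.weights)
    with np.errstate(divide="ignore"):
        d = np.where(w > EDGE_TOL, 1.0 / w, np.inf)
    np.fill_diagonal(d, 0.0)
    return d


def _node_index(network: NetworkModel, node: str) -> int:
    try:
        return network.nodes.index(node)
    except ValueError:
        raise KeyError(f"unknown node {node!r}") from None


def node_strength(network: NetworkModel, node: str, signed: bool = False) -> float:
    """Sum of incident edge weights (absolute by default)."""
    i = _node_index(network, node)
    row = network.weights[i]
    return float(row.sum() if signed else np.abs(row).sum())


def _dijkstra_counts(d: np.ndarray, source: int) -> tuple[np.ndarray, np.ndarray]:
    """Single-source geodesic lengths and shortest-path counts with tie handling."""
    p = d.shape[0]
    dist = np.full(p, np.inf)
    sigma = np.zeros(p)
    dist[source] = 0.0
    sigma[source] = 1.0
    done = np.zeros(p, dtype=bool)
    heap: list[tuple[float, int]] = [(0.0, source)]
    neighbors = [np.flatnonzero(np.isfinite(d[i]) & (np.arange(p) != i)) for i in range(p)]
    while heap:
        du, u = heapq.heappop(heap)
        if done[u] or du > dist[u] and not _close(du, dist[u]):
            continue
        done[u] = True
        for v in neighbors[u]:
            if done[v]:
                continue
            cand = dist[u] + d[u, v]
            if _close(cand, dist[v]):
                sigma[v] += sigma[u]
            elif cand < dist[v]:
                dist[v] = cand
                sigma[v] = sigma[u]
                heapq.heappush(heap, (cand, v))
    return dist, sigma


def shortest_paths_counts(
    distances: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs geodesics on a distance matrix.

    Returns ``(D, sigma, through)`` where ``D[j, k]`` is the geodesic length,
    ``sigma[j, k]`` the number of equal-length geodesics, and
    ``through[j, k, i]`` the number of j-k geodesics with ``i`` as an interior
    node (``sigma[j, i] * sigma[i, k]`` whenever the path through i is tight).
    """
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    if np.any(np.diag(d) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    p = d.shape[0]
    D = np.empty((p, p))
    sigma = np.empty((p, p))
    for s in range(p):
        D[s], sigma[s] = _dijkstra_counts(d, s)

    # through[j, k, i] = sigma[j, i] * sigma[i, k] where the detour via i is
    # tight: D[j, i] + D[i, k] == D[j, k] (within the tie tolerance).
    via = D[:, None, :] + D.T[None, :, :]  # [j, k, i] = D[j,i] + D[i,k]
    target = D[:, :, None]
    finite = np.isfinite(via) & np.isfinite(target)
    tight = finite & np.isclose(via, target, rtol=_REL_TOL, atol=_ABS_TOL)
    idx = np.arange(p)
    tight[idx, :, idx] = False  # i == j
    tight[:, idx, idx] = False  # i == k
    tight[idx, idx, :] = False  # j == k
    through = np.where(tight, sigma[:, None, :] * sigma.T[None, :, :], 0.0)
    return D, sigma, through


def _betweenness_from_counts(
    D: np.ndarray, sigma: np.ndarray, through: np.ndarray
) -> np.ndarray:
    p = D.shape[0]
    upper = np.triu(np.isfinite(D) & (sigma > 0), 1)  # pairs j < k with a path
    frac = np.zeros_like(through)
    frac[upper] = through[upper] / sigma[upper, None]
    return frac.sum(axis=(0, 1))


def _betweenness_all(network: NetworkModel) -> np.ndarray:
    D, sigma, through = shortest_paths_counts(edge_distances(network))
    return _betweenness_from_counts(D, sigma, through)


def betweenness(network: NetworkModel, node: str) -> float:
    """Tie-weighted geodesic pass-through count for one node."""
    i = _node_index(network, node)
    return float(_betweenness_all(network)[i])


def _closeness_from_lengths(D: np.ndarray, scaled: bool = True) -> np.ndarray:
    p = D.shape[0]
    out = np.zeros(p)
    for i in range(p):
        reach = np.isfinite(D[i]) & (np.arange(p) != i)
        r = int(reach.sum())
        if r == 0:
            continue
        total = float(D[i, reach].sum())
        out[i] = (r / total) if scaled else (1.0 / total)
    return out


def _closeness_all(network: NetworkModel, scaled: bool = True) -> np.ndarray:
    D, _, _ = shortest_paths_counts(edge_distances(network))
    return _closeness_from_lengths(D, scaled=scaled)


def closeness(network: NetworkModel, node: str, scaled: bool = True) -> float:
    """Inverse mean geodesic distance within the node's component.

    ``scaled=True`` gives the (reachable count)/(distance sum) convention;
    ``scaled=False`` the raw reciprocal distance sum.  Isolated nodes score 0.
    """
    i = _node_index(network, node)
    return float(_closeness_all(network, scaled=scaled)[i])


def centrality_profile(
    network: NetworkModel, signed: bool = False, scaled_closeness: bool = True
) -> CentralityProfile:
    """All three centrality indices for every node, plus the distances used."""
    w = network.weights
    strength = w.sum(axis=1) if signed else np.abs(w).sum(axis=1)
    d = edge_distances(network)
    D, sigma, through = shortest_paths_counts(d)
    return CentralityProfile(
        nodes=list(network.nodes),
        strength=np.asarray(strength, dtype=float),
        betweenness=_betweenness_from_counts(D, sigma, through),
        closeness=_closeness_from_lengths(D, scaled=scaled_closeness),
        distance_matrix=d,
    )
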