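"""Community detection by greedy modularity optimization.

Modularity uses the standard weighted Newman-Girvan form on absolute edge
weights (partial-correlation networks carry negative edges; signed-modularity
variants are out of scope here):

    Q = (1/2m) * sum_ij [a_ij - s_i s_j / (2m)] * delta(c_i, c_j)

with a_ij = |w_ij|, s_i the node strengths and 2m the total weight.  The
greedy local-move/aggregation optimizer is order-dependent, so it is restarted
with shuffled node orders and the best-Q partition is kept; results are
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .estimation import EDGE_TOL, NetworkModel

__all__ = ["CommunityPartition", "modularity", "louvain", "interpret_modularity"]


@dataclass
class CommunityPartition:
    """Node -> community assignment with its modularity and provenance."""

    assignment: dict[str, int]
    Q: float
    n_communities: int
    seed: int
    restarts: int

    def communities(self) -> list[list[str]]:
        out: list[list[str]] = [[] for _ in range(self.n_communities)]
        for node, c in self.assignment.items():
            out[c].append(node)
        return out


def _abs_adjacency(network: NetworkModel) -> np.ndarray:
    a = np.abs(network.weights).copy()
    a[a <= EDGE_TOL] = 0.0
    return a


def modularity(network: NetworkModel, assignment: dict[str, int]) -> float:
    """Weighted modularity of a partition, on absolute edge weights."""
    missing = [n for n in network.nodes if n not in assignment]
    if missing:
        raise ValueError(f"assignment is missing nodes: {missing}")
    a = _abs_adjacency(network)
    two_m = a.sum()
    if two_m <= 0:
        raise ValueError("modularity is undefined for an edgeless network")
    s = a.sum(axis=1)
    labels = np.array([assignment[n] for n in network.nodes])
    same = labels[:, None] == labels[None, :]
    return float(((a - np.outer(s, s) / two_m) * same).sum() / two_m)


def _relabel_contiguous(network: NetworkModel, communities) -> dict[str, int]:
    """Stable contiguous labels: communities ordered by their first node."""
    order = {n: i for i, n in enumerate(network.nodes)}
    groups = sorted((sorted(c, key=order.get) for c in communities), key=lambda c: order[c[0]])
    return {node: ci for ci, group in enumerate(groups) for node in group}


def louvain(network: NetworkModel, seed: int = 0, restarts: int = 20) -> CommunityPartition:
    """Best-of-``restarts`` greedy modularity partition; isolated nodes become
    singleton communities."""
    a = _abs_adjacency(network)
    if a.sum() <= 0:
        raise ValueError("community detection is undefined for an edgeless network")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    for i, u in enumerate(network.nodes):
        for j in range(i + 1, len(network.nodes)):
            if a[i, j] > 0:
                g.add_edge(u, network.nodes[j], weight=float(a[i, j]))
    sub_seeds = np.random.SeedSequence(seed).generate_state(restarts) % (2**31)
    best_assignment: dict[str, int] | None = None
    best_q = -np.inf
    for s in sub_seeds:
        communities = nx.community.louvain_communities(g, weight="weight", seed=int(s))
        assignment = _relabel_contiguous(network, communities)
        q = modularity(network, assignment)
        if q > best_q + 1e-12:
            best_q, best_assignment = q, assignment
    assert best_assignment is not None
    return CommunityPartition(
        assignment=best_assignment,
        Q=best_q,
        n_communities=max(best_assignment.values()) + 1,
        seed=seed,
        restarts=restarts,
    )


def interpret_modularity(Q: float) -> str:
    """Qualitative reading of a modularity value.

    Values near zero mean the division is no better than random; real-world
    community structure typically yields Q between 0.3 and 0.7.
    """
    if not -1.0 <= Q <= 1.0:
        raise ValueError(f"modularity must lie in [-1, 1], got {Q}")
    if Q < 0.3:
        return "no-community-structure"
    if Q <= 0.7:
        return "community-structure"
    return "exceptionally-strong"
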