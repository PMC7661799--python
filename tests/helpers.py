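"""Shared test utilities: independent oracles and synthetic fixtures.

The oracles here are deliberately naive (exhaustive enumeration) so they
cannot share a code path, or a bug, with the package implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from netpsych.datagen import GroupSpec, VariableSpec, thresholds_from_probs
from netpsych.estimation import NetworkModel

REL_TOL = 1e-9
ABS_TOL = 1e-12

# reciprocal-friendly weights: distances 2, 4, 5, 8, 10 are exact floats,
# so equal-length geodesic ties are exact and tie handling is exercised
TIE_FRIENDLY_WEIGHTS = (0.5, 0.25, 0.2, 0.125, 0.1)


def make_network(weights: np.ndarray, nodes: list[str] | None = None) -> NetworkModel:
    w = np.asarray(weights, dtype=float)
    if nodes is None:
        nodes = [f"v{i}" for i in range(w.shape[0])]
    return NetworkModel(nodes, w, lam=0.0, bic=float("nan"), n=0)


def random_tie_network(rng: np.random.Generator, p: int | None = None) -> NetworkModel:
    """Random weighted graph with exact-tie-friendly weights, possibly disconnected."""
    if p is None:
        p = int(rng.integers(4, 9))
    density = rng.uniform(0.25, 0.8)
    w = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < density:
                weight = rng.choice(TIE_FRIENDLY_WEIGHTS) * rng.choice([-1.0, 1.0])
                w[i, j] = w[j, i] = weight
    return make_network(w)


# --- brute-force geodesic oracle -------------------------------------------

def _all_simple_paths(adj: dict[int, dict[int, float]], src: int, dst: int):
    """Yield (length, interior-node tuple) for every simple src->dst path."""
    stack = [(src, (src,), 0.0)]
    while stack:
        node, path, length = stack.pop()
        if node == dst:
            yield length, path[1:-1]
            continue
        for nxt, d in adj[node].items():
            if nxt not in path:
                stack.append((nxt, path + (nxt,), length + d))


def brute_force_centrality(network: NetworkModel) -> tuple[np.ndarray, np.ndarray]:
    """(betweenness, closeness) by enumerating ALL simple paths."""
    w = network.weights
    p = w.shape[0]
    adj: dict[int, dict[int, float]] = {
        i: {j: 1.0 / abs(w[i, j]) for j in range(p) if j != i and abs(w[i, j]) > 1e-12}
        for i in range(p)
    }
    geodesic = np.full((p, p), np.inf)
    between = np.zeros(p)
    for j in range(p):
        for k in range(j + 1, p):
            paths = list(_all_simple_paths(adj, j, k))
            if not paths:
                continue
            dmin = min(length for length, _ in paths)
            shortest = [
                interior
                for length, interior in paths
                if math.isclose(length, dmin, rel_tol=REL_TOL, abs_tol=ABS_TOL)
            ]
            geodesic[j, k] = geodesic[k, j] = dmin
            for interior in shortest:
                for node in interior:
                    between[node] += 1.0 / len(shortest)
    closeness = np.zeros(p)
    for i in range(p):
        reach = [geodesic[i, j] for j in range(p) if j != i and np.isfinite(geodesic[i, j])]
        if reach:
            closeness[i] = len(reach) / sum(reach)
    return between, closeness


# --- exhaustive modularity oracle ------------------------------------------

def _set_partitions(items: list):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def modularity_of_labels(a: np.ndarray, labels: np.ndarray) -> float:
    two_m = a.sum()
    s = a.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    return float(((a - np.outer(s, s) / two_m) * same).sum() / two_m)


def exhaustive_best_modularity(network: NetworkModel) -> tuple[float, list[list[int]]]:
    """Optimal Q over every partition of the nodes (feasible for p <= 8)."""
    a = np.abs(network.weights)
    p = a.shape[0]
    best_q, best_part = -np.inf, None
    for part in _set_partitions(list(range(p))):
        labels = np.empty(p, dtype=int)
        for ci, group in enumerate(part):
            labels[group] = ci
        q = modularity_of_labels(a, labels)
        if q > best_q:
            best_q, best_part = q, part
    return best_q, best_part


# --- scaled two-group experiment design ------------------------------------

def experiment_variables() -> list[VariableSpec]:
    """A 6-measure mixed-type battery mirroring the study's variable types."""
    return [
        VariableSpec("REV", "continuous", bounds=(0, 36)),
        VariableSpec("EYES", "ordinal", levels=15, bounds=(0, 14)),
        VariableSpec("BEL", "ordinal", levels=6, bounds=(0, 5)),
        VariableSpec("EMO", "ordinal", levels=6, bounds=(0, 5)),
        VariableSpec("ENC", "ordinal", levels=5, bounds=(0, 4)),
        VariableSpec("RC", "ordinal", levels=9, bounds=(0, 8)),
    ]


def experiment_thresholds(variables) -> dict[str, np.ndarray]:
    from scipy.stats import binom

    out = {}
    for v in variables:
        if v.kind != "ordinal":
            continue
        k = v.levels - 1
        out[v.name] = thresholds_from_probs(binom.pmf(np.arange(k + 1), k, 0.65))
    return out


def exchangeable_group(label: str, n: int, partial: float) -> GroupSpec:
    variables = experiment_variables()
    p = len(variables)
    prec = np.full((p, p), -partial)
    np.fill_diagonal(prec, 1.0)
    return GroupSpec(label, n, variables, prec, experiment_thresholds(variables))


def hub_battery() -> list[VariableSpec]:
    """Mixed battery with two continuous-like neighbours for the hub node."""
    return [
        VariableSpec("REV", "continuous", bounds=(0, 36)),
        VariableSpec("EYES", "ordinal", levels=15, bounds=(0, 14)),
        VariableSpec("TOT", "continuous", bounds=(0, 50)),
        VariableSpec("BEL", "ordinal", levels=6, bounds=(0, 5)),
        VariableSpec("ENC", "ordinal", levels=5, bounds=(0, 4)),
        VariableSpec("RC", "ordinal", levels=9, bounds=(0, 8)),
    ]


def hub_group(label: str, n: int, spoke_weight: float) -> GroupSpec:
    """A star network: REV linked to its three neighbours at ``spoke_weight``.

    With ``spoke_weight=0`` the group's network is empty, so the pair
    (hub_group(w), hub_group(0)) builds in a global strength difference whose
    most-affected node is the hub.
    """
    variables = hub_battery()
    prec = np.eye(len(variables))
    for j in (1, 2, 3):
        prec[0, j] = prec[j, 0] = -spoke_weight
    return GroupSpec(label, n, variables, prec, experiment_thresholds(variables))
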