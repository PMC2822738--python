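"""Brute-force reference implementations used to cross-check the package.

These deliberately avoid the package's vectorized code paths: plain
Python loops over dyads, and networkx's reachability for hierarchy.
They are only ever run on tiny graphs.
"""

from __future__ import annotations

import networkx as nx
import numpy as np


def oracle_density(adj: np.ndarray) -> float:
    n = adj.shape[0]
    ties = sum(
        int(adj[i, j]) for i in range(n) for j in range(n) if i != j
    )
    return ties / (n * (n - 1))


def oracle_centralization(adj: np.ndarray, mode: str) -> float:
    n = adj.shape[0]
    if mode == "out":
        degrees = [sum(int(adj[i, j]) for j in range(n) if j != i) for i in range(n)]
    else:
        degrees = [sum(int(adj[j, i]) for j in range(n) if j != i) for i in range(n)]
    c_max = max(degrees)
    return 100.0 * sum(c_max - c for c in degrees) / (n - 1) ** 2


def oracle_hierarchy(adj: np.ndarray) -> float:
    """Krackhardt hierarchy via networkx descendants (explicit closure)."""
    n = adj.shape[0]
    g = nx.from_numpy_array(np.asarray(adj), create_using=nx.DiGraph)
    reachable = {i: nx.descendants(g, i) for i in range(n)}
    pairs = [
        (i, j) for i in range(n) for j in range(n)
        if i != j and j in reachable[i]
    ]
    if not pairs:
        return 0.0
    unreciprocated = sum(1 for i, j in pairs if i not in reachable[j])
    return unreciprocated / len(pairs)


def oracle_total_overlap(a: np.ndarray, b: np.ndarray) -> float:
    n = a.shape[0]
    matches = sum(
        1 for i in range(n) for j in range(n)
        if i != j and int(a[i, j]) == int(b[i, j])
    )
    return matches / (n * (n - 1))


def oracle_connected_individuals(adjs: list[np.ndarray]) -> float:
    n = adjs[0].shape[0]
    total_ties = sum(
        int(a[i, j]) for a in adjs for i in range(n) for j in range(n) if i != j
    )
    if total_ties == 0:
        return 0.0
    incident = set()
    for a in adjs:
        for i in range(n):
            for j in range(n):
                if i != j and a[i, j]:
                    incident.add(i)
                    incident.add(j)
    return total_ties / len(incident)


def oracle_agreement(
    receive: np.ndarray,
    provide: np.ndarray,
    receive_missing: list[bool],
    provide_missing: list[bool],
) -> tuple[float | None, int]:
    """Simple matching over ordered pairs where both reports exist."""
    n = receive.shape[0]
    pairs = matches = 0
    for i in range(n):
        for j in range(n):
            if i == j or receive_missing[i] or provide_missing[j]:
                continue
            pairs += 1
            if int(receive[i, j]) == int(provide[j, i]):
                matches += 1
    if pairs == 0:
        return None, 0
    return matches / pairs, pairs
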