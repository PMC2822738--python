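"""Descriptive statistics of one directed network.

All metrics operate on the internal members only (external category ties
are handled separately) and are intended for *imputed* receiving
networks, though they are defined for any binary digraph:

* **density** — present ties / ``n(n-1)`` possible directed ties.
* **degree centralization** (Freeman) — how strongly out- (in-) ties
  concentrate on one actor; 100% for a perfect star, 0% when all degrees
  are equal.  Directed normalization ``(n-1)^2``.
* **hierarchy** (Krackhardt) — among ordered pairs ``(i, j)`` where *j*
  is reachable from *i* by a directed path, the share for which *i* is
  *not* reachable back from *j*; 1 for a DAG, 0 for a fully reciprocated
  network, 0 by convention when nothing is reachable.
* **most central actors** — all members attaining the maximal degree,
  with their discipline; ties are returned, not broken.

Internal values keep full precision; rounding happens only in the
reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .build import DirectedNetwork
from .roster import Discipline


class UndefinedMetricError(ValueError):
    """The metric is undefined for this network (e.g. fewer than 2 nodes)."""


def _require_order(net: DirectedNetwork, minimum: int = 2) -> None:
    if net.n < minimum:
        raise UndefinedMetricError(
            f"metric undefined for network of order {net.n} (need >= {minimum})"
        )


def density(net: DirectedNetwork) -> float:
    """Proportion of the ``n(n-1)`` possible directed ties that are present."""
    _require_order(net)
    return net.tie_count / (net.n * (net.n - 1))


def out_degrees(net: DirectedNetwork) -> dict[str, int]:
    sums = net.adjacency.sum(axis=1)
    return {m.member_id: int(sums[i]) for i, m in enumerate(net.members)}


def in_degrees(net: DirectedNetwork) -> dict[str, int]:
    sums = net.adjacency.sum(axis=0)
    return {m.member_id: int(sums[i]) for i, m in enumerate(net.members)}


def degree_centralization(net: DirectedNetwork, mode: str) -> float:
    """Freeman degree centralization, as a percentage in [0, 100].

    ``100 * sum_i(c_max - c_i) / (n - 1)^2`` where ``c_i`` is actor *i*'s
    out- or in-degree and ``c_max`` the maximum observed.  A perfect
    out-star scores 100 in out mode; any degree-regular digraph scores 0.
    """
    _require_order(net)
    if mode not in ("out", "in"):
        raise ValueError(f"mode must be 'out' or 'in', got {mode!r}")
    axis = 1 if mode == "out" else 0
    degrees = net.adjacency.sum(axis=axis).astype(float)
    n = net.n
    return 100.0 * float((degrees.max() - degrees).sum()) / (n - 1) ** 2


def reachability(net: DirectedNetwork) -> np.ndarray:
    """Boolean transitive closure: entry (i, j) iff a directed path i -> j."""
    reach = net.adjacency.astype(bool)
    for k in range(net.n):  # Floyd-Warshall on booleans; n <= 20 in practice
        reach |= np.outer(reach[:, k], reach[k, :])
    np.fill_diagonal(reach, False)
    return reach


def hierarchy(net: DirectedNetwork) -> float:
    """Krackhardt graph hierarchy of the directed network.

    The reachability relation is computed on the digraph as-is (no
    symmetrizing); the value is the proportion of reachable ordered
    pairs that are not reachable in the reverse direction.
    """
    _require_order(net)
    reach = reachability(net)
    total = int(reach.sum())
    if total == 0:
        return 0.0
    unreciprocated = int((reach & ~reach.T).sum())
    return unreciprocated / total


def most_central_actors(
    net: DirectedNetwork, mode: str = "out"
) -> frozenset[tuple[str, Discipline]]:
    """All members attaining the maximal out- (in-) degree, with discipline.

    Ties are preserved: the set may contain several members, possibly of
    different disciplines (reported as e.g. "P;N").  In an all-isolates
    network every member attains the maximum (0) and all are returned.
    """
    if net.n < 1:
        raise UndefinedMetricError("network has no members")
    degs = out_degrees(net) if mode == "out" else in_degrees(net)
    top = max(degs.values())
    return frozenset(
        (m.member_id, m.discipline) for m in net.members if degs[m.member_id] == top
    )


@dataclass(frozen=True)
class NetworkMetrics:
    """Full-precision descriptive statistics for one directed network."""

    density: float
    centralization_out: float
    centralization_in: float
    hierarchy: float
    actor_out_degree: dict[str, int]
    actor_in_degree: dict[str, int]
    most_central_out: frozenset[tuple[str, Discipline]]

    @property
    def central_disciplines(self) -> str:
        """Disciplines of the most out-central actors, P/A/N joined by ';'."""
        order = {"P": 0, "A": 1, "N": 2}
        codes = sorted({d.code for _, d in self.most_central_out}, key=order.get)
        return ";".join(codes)


def compute_metrics(net: DirectedNetwork) -> NetworkMetrics:
    """All descriptive statistics of one network in a single container."""
    return NetworkMetrics(
        density=density(net),
        centralization_out=degree_centralization(net, "out"),
        centralization_in=degree_centralization(net, "in"),
        hierarchy=hierarchy(net),
        actor_out_degree=out_degrees(net),
        actor_in_degree=in_degrees(net),
        most_central_out=most_central_actors(net, "out"),
    )
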