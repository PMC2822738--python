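"""Overlap between condition-specific networks of the same practice.

Two complementary measures:

* **total overlap** (pairwise only) — simple matching over all
  ``n(n-1)`` ordered dyads: the proportion of dyads on which the two
  networks agree on the *presence or absence* of a tie.  Sparse networks
  can score high purely through shared absence, hence the second measure.
* **connected-individuals overlap** (2 or 3 networks) — total number of
  ties summed across the networks, divided by the number of distinct
  members incident to at least one tie in at least one of them: the mean
  number of ties held by any connected individual.

Both expect imputed networks (no missing rows) over identical rosters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .build import DirectedNetwork
from .metrics import UndefinedMetricError
from .roster import Condition


def _check_comparable(nets: Sequence[DirectedNetwork]) -> None:
    first = nets[0]
    for other in nets[1:]:
        if not first.same_roster(other):
            raise ValueError("networks have mismatched practice rosters")
    for net in nets:
        if net.has_missing:
            raise ValueError(
                f"network {net.condition.value}/{net.direction.value} has "
                "missing rows; impute before computing overlap"
            )


def total_overlap(a: DirectedNetwork, b: DirectedNetwork) -> float:
    """Simple-matching overlap of two networks over the same roster.

    Equals ``1 - (normalized Hamming distance)`` between the two
    adjacency relations; 1.0 for identical networks, 0.0 for exact
    complements.
    """
    _check_comparable([a, b])
    if a.n < 2:
        raise UndefinedMetricError("total_overlap undefined for order < 2")
    off = ~np.eye(a.n, dtype=bool)
    matches = int(((a.adjacency == b.adjacency) & off).sum())
    return matches / (a.n * (a.n - 1))


def connected_individuals_overlap(nets: Sequence[DirectedNetwork]) -> float:
    """Mean number of ties per connected individual across networks.

    Sums tie counts across the networks (a tie shared by two networks
    counts once per network) and divides by the number of members with
    at least one incident tie — in or out — in at least one network.
    Defined as 0 when the networks hold no ties at all.
    """
    if not 2 <= len(nets) <= 3:
        raise ValueError("overlap is defined for 2 or 3 networks")
    _check_comparable(nets)
    total_ties = sum(net.tie_count for net in nets)
    if total_ties == 0:
        return 0.0
    incident = np.zeros(nets[0].n, dtype=bool)
    for net in nets:
        incident |= net.adjacency.any(axis=0) | net.adjacency.any(axis=1)
    return total_ties / int(incident.sum())


@dataclass(frozen=True)
class OverlapResult:
    """Overlap measures for one pair or triple of condition networks.

    ``total`` is None for triples (simple matching is pairwise only).
    """

    conditions: tuple[Condition, ...]
    total: Optional[float]
    connected_individuals: float

    @property
    def tag(self) -> str:
        return "-".join(c.value for c in self.conditions)


def compute_overlaps(nets: dict[Condition, DirectedNetwork]) -> list[OverlapResult]:
    """All pairwise overlaps plus the triple, in canonical condition order."""
    conditions = [c for c in Condition if c in nets]
    results: list[OverlapResult] = []
    for i, a in enumerate(conditions):
        for b in conditions[i + 1:]:
            results.append(
                OverlapResult(
                    (a, b),
                    total_overlap(nets[a], nets[b]),
                    connected_individuals_overlap([nets[a], nets[b]]),
                )
            )
    if len(conditions) == 3:
        results.append(
            OverlapResult(
                tuple(conditions),
                None,
                connected_individuals_overlap([nets[c] for c in conditions]),
            )
        )
    return results
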