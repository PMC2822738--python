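"""Boundary-spanner statistics: ties to providers outside the practice.

External alters are unnamed categories (other GPs, cardiologists, ...),
so an external connection is one member ticking one category; several
categories ticked by the same member count separately.  Outsiders were
not surveyed, so external ticks have no reciprocal report and are taken
at face value.

The "most central individual" is defined by outdegree centrality on the
*internal* receiving network; when several members tie for the maximum,
the reported share is the largest among them and the tie is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .build import DirectedNetwork
from .metrics import UndefinedMetricError, most_central_actors
from .roster import Condition


def external_counts(net: DirectedNetwork) -> tuple[int, int]:
    """(external_count, internal_count) for one imputed network."""
    return net.external_tie_count, net.tie_count


def external_fraction(external_count: int, internal_count: int) -> float:
    """External ties as a percentage of all ties for the condition."""
    denominator = external_count + internal_count
    if denominator == 0:
        raise UndefinedMetricError(
            "external fraction undefined: no connections at all"
        )
    return 100.0 * external_count / denominator


@dataclass(frozen=True)
class CentralShare:
    """External ties held by the most central internal actor.

    ``held`` out of ``total`` external ties; rendered as "h/t" in report
    tables.  ``tied`` flags that maximal centrality was shared and the
    maximum held among the tied actors is reported.
    """

    held: int
    total: int
    tied: bool

    def __str__(self) -> str:
        return f"{self.held}/{self.total}"


def central_actor_external_share(
    net: DirectedNetwork, central: Iterable[str]
) -> CentralShare:
    """External ties of the most central actor(s) out of all external ties."""
    central = list(central)
    if not central:
        raise ValueError("central actor set must be nonempty")
    unknown = set(central) - set(net.member_ids)
    if unknown:
        raise ValueError(f"central actors not on roster: {sorted(unknown)}")
    held = max(len(net.external_ties.get(m, frozenset())) for m in central)
    return CentralShare(held, net.external_tie_count, tied=len(central) > 1)


@dataclass(frozen=True)
class ExternalStats:
    """Boundary-spanning summary for one condition network."""

    condition: Condition
    external_count: int
    internal_count: int
    central_share: CentralShare

    @property
    def external_fraction(self) -> Optional[float]:
        """Percentage of all ties that are external; None when no ties exist."""
        if self.external_count + self.internal_count == 0:
            return None
        return external_fraction(self.external_count, self.internal_count)


def compute_external_stats(net: DirectedNetwork) -> ExternalStats:
    """External-tie statistics of one imputed receiving network.

    Central actors are taken from outdegree centrality of the same
    network's internal ties.
    """
    ext, internal = external_counts(net)
    central = [m for m, _ in most_central_actors(net, "out")]
    return ExternalStats(
        condition=net.condition,
        external_count=ext,
        internal_count=internal,
        central_share=central_actor_external_share(net, central),
    )
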