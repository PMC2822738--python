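"""Construction of directed condition networks from survey responses.

The receiving and providing questionnaires describe the same underlying
ties from two sides: if *i* truly receives information from *j*, then
*i*'s RECEIVE report should tick *j* and *j*'s PROVIDE report should tick
*i*.  This module builds one :class:`DirectedNetwork` per
(condition, direction), quantifies the agreement between the two sides
(simple matching over dyads where both reports exist), and imputes the
rows of receiving nonrespondents from the reciprocal providing reports —
zero-filling only when both sides are silent.

Adjacency orientation: entry ``(i, j)`` means "i receives information
from j" in a RECEIVE network and "i provides information to j" in a
PROVIDE network; i.e. row *i* is always respondent *i*'s own report.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .roster import Condition, Direction, Member, SurveyDataset


class Provenance(enum.IntEnum):
    """Origin of one adjacency entry."""

    MISSING = 0      # respondent's report absent, not yet imputed
    REPORTED = 1     # taken directly from the respondent's own ticks
    IMPUTED = 2      # copied from the alter's reciprocal report
    ZERO_FILLED = 3  # both sides silent; absence of data coded as 0


@dataclass
class DirectedNetwork:
    """Binary directed network over the internal members of one practice.

    ``adjacency`` and ``provenance`` are ``n x n`` integer arrays indexed
    by roster order; ``missing_rows[i]`` flags that member *i*'s report
    for this (condition, direction) is absent.  ``external_ties`` maps
    each member to the set of external provider categories they ticked
    (taken at face value — outsiders were not surveyed, so there is no
    reciprocal report to check against).
    """

    practice_id: str
    condition: Condition
    direction: Direction
    members: tuple[Member, ...]
    adjacency: np.ndarray
    provenance: np.ndarray
    missing_rows: np.ndarray
    external_ties: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        n = len(self.members)
        self.adjacency = np.asarray(self.adjacency, dtype=np.int8)
        self.provenance = np.asarray(self.provenance, dtype=np.int8)
        self.missing_rows = np.asarray(self.missing_rows, dtype=bool)
        if self.adjacency.shape != (n, n) or self.provenance.shape != (n, n):
            raise ValueError("adjacency/provenance must be n x n")
        if self.missing_rows.shape != (n,):
            raise ValueError("missing_rows must have length n")
        if np.any(np.diag(self.adjacency)):
            raise ValueError("self-loops are not allowed")
        if not np.isin(self.adjacency, (0, 1)).all():
            raise ValueError("adjacency entries must be binary")

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(m.member_id for m in self.members)

    def index(self, member_id: str) -> int:
        return self.member_ids.index(member_id)

    @property
    def tie_count(self) -> int:
        return int(self.adjacency.sum())

    @property
    def external_tie_count(self) -> int:
        return sum(len(s) for s in self.external_ties.values())

    @property
    def has_missing(self) -> bool:
        return bool(self.missing_rows.any())

    def provenance_counts(self) -> dict[str, int]:
        """Number of off-diagonal entries per provenance class."""
        off = ~np.eye(self.n, dtype=bool)
        return {
            tag.name.lower(): int((self.provenance[off] == tag).sum())
            for tag in Provenance
        }

    def same_roster(self, other: "DirectedNetwork") -> bool:
        return (
            self.practice_id == other.practice_id
            and self.member_ids == other.member_ids
        )


def build_network(
    dataset: SurveyDataset, condition: Condition, direction: Direction
) -> DirectedNetwork:
    """Assemble the directed network for one condition and direction.

    Entry ``(i, j)`` is 1 iff member *i*'s response ticks *j*.  Rows of
    members whose response is missing (or absent from the dataset) stay
    all-zero with provenance MISSING, pending imputation.
    """
    members = tuple(dataset.members)
    n = len(members)
    idx = {m.member_id: k for k, m in enumerate(members)}
    adjacency = np.zeros((n, n), dtype=np.int8)
    provenance = np.full((n, n), Provenance.MISSING, dtype=np.int8)
    missing_rows = np.zeros(n, dtype=bool)
    external: dict[str, frozenset[str]] = {}
    for i, m in enumerate(members):
        r = dataset.response_for(m.member_id, condition, direction)
        if r is None or r.missing:
            missing_rows[i] = True
            external[m.member_id] = frozenset()
            continue
        provenance[i, :] = Provenance.REPORTED
        for alter in r.internal_ticks:
            adjacency[i, idx[alter]] = 1
        external[m.member_id] = frozenset(r.external_ticks)
    np.fill_diagonal(provenance, Provenance.MISSING)
    return DirectedNetwork(
        dataset.practice_id, condition, direction,
        members, adjacency, provenance, missing_rows, external,
    )


@dataclass(frozen=True)
class AgreementResult:
    """Simple-matching agreement between receiving and providing reports.

    ``proportion`` is None when no dyad had both reports available — an
    undefined result, deliberately distinct from zero agreement.
    """

    proportion: Optional[float]
    n_pairs: int
    n_matches: int

    @property
    def defined(self) -> bool:
        return self.proportion is not None


def agreement(receiving: DirectedNetwork, providing: DirectedNetwork) -> AgreementResult:
    """Proportion of dyads where the two directional reports agree.

    Over all ordered pairs ``(i, j)``, ``i != j``, where *i*'s RECEIVE
    report and *j*'s PROVIDE report both exist, a match means
    ``receiving(i, j) == providing(j, i)`` — mutual agreement on either
    presence or absence of the tie.  Must be computed before imputation
    (imputed entries copy the provider report and would mechanically
    inflate agreement).
    """
    _check_pair(receiving, providing)
    if np.any(receiving.provenance == Provenance.IMPUTED) or np.any(
        providing.provenance == Provenance.IMPUTED
    ):
        raise ValueError("agreement must be computed on pre-imputation networks")
    n = receiving.n
    # evaluable(i, j): i's receive row and j's provide row both reported
    evaluable = (
        ~receiving.missing_rows[:, None] & ~providing.missing_rows[None, :]
    ) & ~np.eye(n, dtype=bool)
    match = receiving.adjacency == providing.adjacency.T
    n_pairs = int(evaluable.sum())
    n_matches = int((match & evaluable).sum())
    if n_pairs == 0:
        return AgreementResult(None, 0, 0)
    return AgreementResult(n_matches / n_pairs, n_pairs, n_matches)


def impute_receiving(
    receiving: DirectedNetwork, providing: DirectedNetwork
) -> DirectedNetwork:
    """Fill missing receiving rows from the reciprocal providing reports.

    For each member *i* whose RECEIVE report is missing, entry ``(i, j)``
    becomes *j*'s providing report about *i* when that report exists
    (provenance IMPUTED) and 0 when *j* is also silent (ZERO_FILLED).
    Reported rows are never altered, so the operation is idempotent; the
    result has no missing rows.
    """
    _check_pair(receiving, providing)
    if receiving.direction is not Direction.RECEIVE:
        raise ValueError("first argument must be the receiving network")
    if not receiving.has_missing:
        return replace(
            receiving,
            adjacency=receiving.adjacency.copy(),
            provenance=receiving.provenance.copy(),
            missing_rows=receiving.missing_rows.copy(),
            external_ties=dict(receiving.external_ties),
        )
    adjacency = receiving.adjacency.copy()
    provenance = receiving.provenance.copy()
    n = receiving.n
    for i in np.flatnonzero(receiving.missing_rows):
        for j in range(n):
            if j == i:
                continue
            if providing.missing_rows[j]:
                adjacency[i, j] = 0
                provenance[i, j] = Provenance.ZERO_FILLED
            else:
                adjacency[i, j] = providing.adjacency[j, i]
                provenance[i, j] = Provenance.IMPUTED
    return replace(
        receiving,
        adjacency=adjacency,
        provenance=provenance,
        missing_rows=np.zeros(n, dtype=bool),
        external_ties=dict(receiving.external_ties),
    )


def _check_pair(receiving: DirectedNetwork, providing: DirectedNetwork) -> None:
    if not receiving.same_roster(providing):
        raise ValueError("networks come from different practices/rosters")
    if receiving.condition is not providing.condition:
        raise ValueError("networks refer to different conditions")
    if receiving.direction is providing.direction:
        raise ValueError("need one RECEIVE and one PROVIDE network")


# -- exports --------------------------------------------------------------

def to_networkx(net: DirectedNetwork, include_external: bool = True):
    """Convert to a networkx DiGraph.

    Internal nodes carry ``discipline`` and ``kind='internal'``; external
    category nodes carry ``kind='external'``.  Edges carry the condition
    and the provenance of the entry.
    """
    import networkx as nx

    g = nx.DiGraph(
        practice_id=net.practice_id,
        condition=net.condition.value,
        direction=net.direction.value,
    )
    for m in net.members:
        g.add_node(m.member_id, discipline=m.discipline.code, kind="internal")
    for i, src in enumerate(net.members):
        for j, dst in enumerate(net.members):
            if net.adjacency[i, j]:
                g.add_edge(
                    src.member_id,
                    dst.member_id,
                    condition=net.condition.value,
                    provenance=Provenance(net.provenance[i, j]).name.lower(),
                )
    if include_external:
        for member_id, cats in net.external_ties.items():
            for cat in sorted(cats):
                if cat not in g:
                    g.add_node(cat, kind="external")
                g.add_edge(
                    member_id, cat,
                    condition=net.condition.value, provenance="reported",
                )
    return g


def write_graphml(net: DirectedNetwork, path: str | Path) -> None:
    import networkx as nx

    nx.write_graphml(to_networkx(net), str(path))


def write_edge_csv(net: DirectedNetwork, path: str | Path) -> None:
    """Edge-list CSV: source,target,target_kind,condition,direction,provenance."""
    import csv

    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target", "target_kind", "condition", "direction", "provenance"])
        for i, src in enumerate(net.members):
            for j, dst in enumerate(net.members):
                if net.adjacency[i, j]:
                    writer.writerow([
                        src.member_id, dst.member_id, "internal",
                        net.condition.value, net.direction.value,
                        Provenance(net.provenance[i, j]).name.lower(),
                    ])
        for member_id in net.member_ids:
            for cat in sorted(net.external_ties.get(member_id, ())):
                writer.writerow([
                    member_id, cat, "external",
                    net.condition.value, net.direction.value, "reported",
                ])


_DOT_SHAPE = {"P": "circle", "A": "box", "N": "diamond"}


def write_dot(net: DirectedNetwork, path: str | Path) -> None:
    """Write a Graphviz DOT file for visual network maps.

    Disciplines are distinguished by node shape (GP circle, assistant
    box, nurse diamond); imputed edges are dashed.
    """
    lines = [f'digraph "{net.practice_id}_{net.condition.value}_{net.direction.value}" {{']
    for m in net.members:
        shape = _DOT_SHAPE[m.discipline.code]
        lines.append(f'  "{m.member_id}" [shape={shape}, label="{m.member_id}"];')
    for i, src in enumerate(net.members):
        for j, dst in enumerate(net.members):
            if net.adjacency[i, j]:
                style = (
                    ' [style=dashed]'
                    if net.provenance[i, j] == Provenance.IMPUTED
                    else ""
                )
                lines.append(f'  "{src.member_id}" -> "{dst.member_id}"{style};')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
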