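from __future__ import annotations

import itertools

import numpy as np
import pytest

from practicenet.build import DirectedNetwork, Provenance
from practicenet.roster import (
    Condition,
    Direction,
    Discipline,
    ExternalCategory,
    Member,
    Response,
    SurveyDataset,
)

_DISCIPLINE_CYCLE = (Discipline.GP, Discipline.ASSISTANT, Discipline.NURSE)


def make_members(n: int) -> tuple[Member, ...]:
    return tuple(
        Member(f"m{k + 1:02d}", _DISCIPLINE_CYCLE[k % 3]) for k in range(n)
    )


def make_network(
    adjacency,
    *,
    condition: Condition = Condition.CHF,
    direction: Direction = Direction.RECEIVE,
    missing_rows=None,
    external: dict[str, set[str]] | None = None,
    practice_id: str = "test",
) -> DirectedNetwork:
    """Build a DirectedNetwork directly from an adjacency matrix."""
    adjacency = np.asarray(adjacency, dtype=np.int8)
    n = adjacency.shape[0]
    members = make_members(n)
    if missing_rows is None:
        missing_rows = np.zeros(n, dtype=bool)
    else:
        missing_rows = np.asarray(missing_rows, dtype=bool)
    provenance = np.full((n, n), Provenance.REPORTED, dtype=np.int8)
    provenance[missing_rows, :] = Provenance.MISSING
    np.fill_diagonal(provenance, Provenance.MISSING)
    adjacency = adjacency.copy()
    adjacency[missing_rows, :] = 0
    external_ties = {
        m.member_id: frozenset((external or {}).get(m.member_id, ()))
        for m in members
    }
    return DirectedNetwork(
        practice_id, condition, direction,
        members, adjacency, provenance, missing_rows, external_ties,
    )


def random_adjacency(rng: np.random.Generator, n: int, p: float = 0.5) -> np.ndarray:
    adj = (rng.random((n, n)) < p).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return adj


def full_response_dataset(
    n: int,
    ticks: dict[tuple[str, Condition, Direction], set[str]] | None = None,
    external_ticks: dict[tuple[str, Condition, Direction], set[str]] | None = None,
    missing: set[tuple[str, Condition, Direction]] | None = None,
    practice_id: str = "test",
) -> SurveyDataset:
    """A dataset with every response present; ticks default to empty."""
    members = list(make_members(n))
    categories = [
        ExternalCategory("ext_cardio", "cardiologists"),
        ExternalCategory("ext_physio", "physiotherapists"),
    ]
    ticks = ticks or {}
    external_ticks = external_ticks or {}
    missing = missing or set()
    responses = []
    for m, condition, direction in itertools.product(members, Condition, Direction):
        key = (m.member_id, condition, direction)
        if key in missing:
            responses.append(Response(m.member_id, condition, direction, missing=True))
        else:
            responses.append(
                Response(
                    m.member_id, condition, direction,
                    frozenset(ticks.get(key, ())),
                    frozenset(external_ticks.get(key, ())),
                )
            )
    return SurveyDataset(practice_id, members, categories, responses)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
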