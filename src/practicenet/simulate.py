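"""Synthetic roster-survey generator.

Emulates the data a small primary-care practice produces: a roster of
2-20 members across three disciplines, one *true* directed
information-exchange network per chronic condition (independent
Bernoulli ties, optionally concentrated on a designated hub), and the
two directional questionnaire reports derived from the truth with an
independent per-report flip probability ``report_flip`` — the mechanism
behind imperfect receiving/providing agreement.  Whole-member
nonresponse removes all six of a member's responses.

Because each side of a dyad is flipped independently, the expected
simple-matching agreement between receiving and providing reports is
``eps**2 + (1 - eps)**2`` (both flipped or neither), which the test
suite verifies by Monte-Carlo.

Everything is drawn from one :func:`numpy.random.default_rng` stream in
a fixed order, so equal seeds give byte-identical datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .roster import (
    Condition,
    Direction,
    Discipline,
    ExternalCategory,
    Member,
    Response,
    SurveyDataset,
    write_survey,
)

#: External provider categories offered on the questionnaire.
DEFAULT_EXTERNAL_CATEGORIES = (
    ExternalCategory("ext_gp", "other GPs"),
    ExternalCategory("ext_nurse", "other practice nurses"),
    ExternalCategory("ext_cardio", "cardiologists"),
    ExternalCategory("ext_intern", "internists"),
    ExternalCategory("ext_physio", "physiotherapists"),
    ExternalCategory("ext_other", "others"),
)


def _default_tie_prob() -> dict[Condition, float]:
    # Condition-dependent true densities: chronic heart failure networks
    # are sparsest, diabetes densest, mirroring the division of labour in
    # Dutch primary care where nurses and assistants hold recognized
    # roles in diabetes/COPD care.
    return {Condition.CHF: 0.25, Condition.COPD: 0.33, Condition.DIABETES: 0.36}


@dataclass
class GeneratorConfig:
    """Parameters of one simulated practice.

    Defaults reproduce the structure observed across eight real
    practices: a six-member roster (2 GPs, 3 assistants, 1 nurse),
    condition-dependent tie densities around 0.25-0.36, a ~15% chance
    that a single directional report contradicts the true tie, and ~20%
    whole-member nonresponse.  ``centralization_bias`` in (0, 1] pushes
    the first GP's out-tie probabilities toward 1, producing the
    star-like maps seen in centralized practices.
    """

    seed: int = 0
    n_gps: int = 2
    n_assistants: int = 3
    n_nurses: int = 1
    tie_prob: dict[Condition, float] = field(default_factory=_default_tie_prob)
    external_prob: float = 0.05
    report_flip: float = 0.15
    nonresponse_prob: float = 0.2
    centralization_bias: float = 0.0

    def __post_init__(self) -> None:
        if self.n_gps < 0 or self.n_assistants < 0 or self.n_nurses < 0:
            raise ValueError("discipline counts must be nonnegative")
        if self.n_members < 2:
            raise ValueError("a practice needs at least 2 members")
        probs = list(self.tie_prob.values()) + [
            self.external_prob,
            self.report_flip,
            self.nonresponse_prob,
            self.centralization_bias,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        missing = [c for c in Condition if c not in self.tie_prob]
        if missing:
            raise ValueError(f"tie_prob missing conditions: {missing}")

    @property
    def n_members(self) -> int:
        return self.n_gps + self.n_assistants + self.n_nurses


@dataclass
class GroundTruth:
    """What the generator knows that the survey does not.

    ``true_networks[c][i, j] == 1`` means member *i* truly receives
    information from member *j* for condition *c* (receiving
    orientation).  ``true_external[c]`` holds each member's true
    external-category ties; ``nonresponders`` the members whose entire
    questionnaire was dropped; ``hub_id`` the designated central member
    when ``centralization_bias > 0``.
    """

    config: GeneratorConfig
    member_ids: tuple[str, ...]
    true_networks: dict[Condition, np.ndarray]
    true_external: dict[Condition, dict[str, frozenset[str]]]
    nonresponders: frozenset[str]
    hub_id: Optional[str]

    def true_density(self, condition: Condition) -> float:
        n = len(self.member_ids)
        return float(self.true_networks[condition].sum()) / (n * (n - 1))


def generate_practice(
    config: GeneratorConfig, practice_id: str = "sim"
) -> tuple[SurveyDataset, GroundTruth]:
    """Draw one synthetic practice: survey responses plus ground truth.

    Deterministic given ``config.seed``.  Report derivation: member *i*'s
    RECEIVE report ticks *j* iff the true tie (i receives from j) XOR an
    independent Bernoulli(``report_flip``); *i*'s PROVIDE report about
    *j* reads the transposed true tie with its own independent flip.
    External ticks are reported faithfully and identically in both
    directions (no reciprocal informant exists to disagree with).
    """
    rng = np.random.default_rng(config.seed)
    members = _make_roster(config)
    n = len(members)
    member_ids = tuple(m.member_id for m in members)
    categories = list(DEFAULT_EXTERNAL_CATEGORIES)
    cat_ids = [c.category_id for c in categories]

    hub_index: Optional[int] = None
    if config.centralization_bias > 0:
        hub_index = 0  # first GP (roster order puts GPs first)

    true_networks: dict[Condition, np.ndarray] = {}
    true_external: dict[Condition, dict[str, frozenset[str]]] = {}
    for condition in Condition:
        p = config.tie_prob[condition]
        probs = np.full((n, n), p)
        if hub_index is not None:
            # boost the hub's out-ties (its row) toward 1 so the hub
            # attains maximal outdegree centrality
            w = config.centralization_bias
            probs[hub_index, :] = (1 - w) * p + w * 1.0
        adj = (rng.random((n, n)) < probs).astype(np.int8)
        np.fill_diagonal(adj, 0)
        true_networks[condition] = adj
        ext = (rng.random((n, len(cat_ids))) < config.external_prob)
        true_external[condition] = {
            member_ids[i]: frozenset(
                cat_ids[k] for k in range(len(cat_ids)) if ext[i, k]
            )
            for i in range(n)
        }

    responses: list[Response] = []
    for condition in Condition:
        adj = true_networks[condition]
        flips_receive = rng.random((n, n)) < config.report_flip
        flips_provide = rng.random((n, n)) < config.report_flip
        for i in range(n):
            receive_ticks = frozenset(
                member_ids[j]
                for j in range(n)
                if j != i and bool(adj[i, j]) != bool(flips_receive[i, j])
            )
            # i's PROVIDE report about j mirrors the true tie "j receives
            # from i", with its own independent flip
            provide_ticks = frozenset(
                member_ids[j]
                for j in range(n)
                if j != i and bool(adj[j, i]) != bool(flips_provide[i, j])
            )
            ext_ticks = true_external[condition][member_ids[i]]
            responses.append(
                Response(member_ids[i], condition, Direction.RECEIVE,
                         receive_ticks, ext_ticks)
            )
            responses.append(
                Response(member_ids[i], condition, Direction.PROVIDE,
                         provide_ticks, ext_ticks)
            )

    nonresponse_draws = rng.random(n) < config.nonresponse_prob
    nonresponders = frozenset(
        member_ids[i] for i in range(n) if nonresponse_draws[i]
    )
    if nonresponders:
        responses = [
            r
            if r.respondent not in nonresponders
            else Response(r.respondent, r.condition, r.direction, missing=True)
            for r in responses
        ]

    dataset = SurveyDataset(practice_id, members, categories, responses)
    truth = GroundTruth(
        config=config,
        member_ids=member_ids,
        true_networks=true_networks,
        true_external=true_external,
        nonresponders=nonresponders,
        hub_id=member_ids[hub_index] if hub_index is not None else None,
    )
    return dataset, truth


def _make_roster(config: GeneratorConfig) -> list[Member]:
    members: list[Member] = []
    k = 1
    for count, discipline in (
        (config.n_gps, Discipline.GP),
        (config.n_assistants, Discipline.ASSISTANT),
        (config.n_nurses, Discipline.NURSE),
    ):
        for _ in range(count):
            members.append(Member(f"m{k:02d}", discipline))
            k += 1
    return members


def write_fixture(
    dataset: SurveyDataset, truth: GroundTruth, output_dir: str | Path
) -> dict[str, Path]:
    """Write survey/roster CSVs plus a ground-truth JSON sidecar."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "survey": output_dir / "survey.csv",
        "roster": output_dir / "roster.csv",
        "ground_truth": output_dir / "ground_truth.json",
    }
    write_survey(dataset, paths["survey"], paths["roster"])
    payload = {
        "practice_id": dataset.practice_id,
        "config": {
            "seed": truth.config.seed,
            "n_gps": truth.config.n_gps,
            "n_assistants": truth.config.n_assistants,
            "n_nurses": truth.config.n_nurses,
            "tie_prob": {c.value: p for c, p in truth.config.tie_prob.items()},
            "external_prob": truth.config.external_prob,
            "report_flip": truth.config.report_flip,
            "nonresponse_prob": truth.config.nonresponse_prob,
            "centralization_bias": truth.config.centralization_bias,
        },
        "member_ids": list(truth.member_ids),
        "true_networks": {
            c.value: truth.true_networks[c].tolist() for c in Condition
        },
        "true_external": {
            c.value: {m: sorted(s) for m, s in truth.true_external[c].items()}
            for c in Condition
        },
        "nonresponders": sorted(truth.nonresponders),
        "hub_id": truth.hub_id,
    }
    paths["ground_truth"].write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return paths
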