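"""Domain model for roster-based sociometric surveys in primary-care practices.

A practice roster lists every internal member (GPs, practice assistants,
practice nurses) plus a small set of *external* provider categories
(e.g. cardiologists, physiotherapists).  Each member answers, for each
chronic condition and each direction of information flow (receiving /
providing), a tick-box question over all other roster entries.  The raw
unit of data is therefore one :class:`Response` per
(respondent, condition, direction).

Serialization uses two plain CSV files:

* **survey CSV** — long form, one row per tick, header
  ``practice_id,respondent,condition,direction,alter,alter_kind``.
  A row whose ``alter`` is the literal ``__NONE__`` means "responded,
  ticked nobody"; ``__MISSING__`` means "did not answer this question".
  Every (respondent, condition, direction) combination must appear, so
  absence of data is always explicit.
* **roster CSV** — header ``practice_id,kind,id,name,discipline`` with
  ``kind`` in {``member``, ``external``}; external rows leave the
  discipline blank.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

NONE_TOKEN = "__NONE__"
MISSING_TOKEN = "__MISSING__"


class Discipline(str, enum.Enum):
    """Staff role in a Dutch primary-care practice."""

    GP = "GP"
    ASSISTANT = "ASSISTANT"
    NURSE = "NURSE"

    @property
    def code(self) -> str:
        """Single-letter code used in report tables (P/A/N)."""
        return {"GP": "P", "ASSISTANT": "A", "NURSE": "N"}[self.value]


class Condition(str, enum.Enum):
    """Chronic condition a network refers to."""

    CHF = "CHF"
    COPD = "COPD"
    DIABETES = "DM"


class Direction(str, enum.Enum):
    """Direction of the information-exchange question."""

    RECEIVE = "RECEIVE"
    PROVIDE = "PROVIDE"


class SurveyError(ValueError):
    """Base error for malformed survey inputs."""


class SurveyFormatError(SurveyError):
    """File-level problem: bad header, unknown token, missing rows."""


class SurveyValidationError(SurveyError):
    """Semantic problem: invariant of the survey model violated."""


@dataclass(frozen=True)
class Member:
    """An internal practice member.

    Identifiers are short stable tokens (``m01``, ``m02``, ...); names are
    optional so datasets can be fully anonymized.
    """

    member_id: str
    discipline: Discipline
    name: str = ""


@dataclass(frozen=True)
class ExternalCategory:
    """A category of providers outside the practice (unnamed individuals)."""

    category_id: str
    label: str = ""


@dataclass(frozen=True)
class Response:
    """One respondent's tick set for one condition and direction.

    ``missing=True`` means the question was left unanswered; both tick
    sets must then be empty.  An empty tick set with ``missing=False`` is
    a valid answer meaning "no connections" — the distinction drives the
    missing-data imputation downstream.
    """

    respondent: str
    condition: Condition
    direction: Direction
    internal_ticks: frozenset[str] = frozenset()
    external_ticks: frozenset[str] = frozenset()
    missing: bool = False


def _response_sort_key(r: Response) -> tuple:
    return (r.respondent, r.condition.value, r.direction.value)


@dataclass
class SurveyDataset:
    """All questionnaire responses for one practice.

    Responses are stored in canonical (respondent, condition, direction)
    order so that equal datasets compare equal regardless of input order.
    Invariants are enforced at construction time.
    """

    practice_id: str
    members: list[Member]
    external_categories: list[ExternalCategory]
    responses: list[Response] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.responses = sorted(self.responses, key=_response_sort_key)
        self._validate()

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        member_ids = [m.member_id for m in self.members]
        if len(set(member_ids)) != len(member_ids):
            raise SurveyValidationError(
                f"duplicate member_id in practice {self.practice_id!r}"
            )
        category_ids = [c.category_id for c in self.external_categories]
        if len(set(category_ids)) != len(category_ids):
            raise SurveyValidationError(
                f"duplicate external category_id in practice {self.practice_id!r}"
            )
        member_set = set(member_ids)
        category_set = set(category_ids)
        seen: set[tuple[str, Condition, Direction]] = set()
        for r in self.responses:
            key = (r.respondent, r.condition, r.direction)
            if key in seen:
                raise SurveyValidationError(
                    f"duplicate response for respondent={r.respondent!r} "
                    f"condition={r.condition.value} direction={r.direction.value}"
                )
            seen.add(key)
            if r.respondent not in member_set:
                raise SurveyValidationError(
                    f"response from unknown respondent {r.respondent!r}"
                )
            if r.missing and (r.internal_ticks or r.external_ticks):
                raise SurveyValidationError(
                    f"missing response with nonempty ticks: {r.respondent!r}"
                )
            if r.respondent in r.internal_ticks:
                raise SurveyValidationError(
                    f"self-tick by respondent {r.respondent!r}"
                )
            unknown = r.internal_ticks - member_set
            if unknown:
                raise SurveyValidationError(
                    f"tick referencing unknown member(s) {sorted(unknown)} "
                    f"by {r.respondent!r}"
                )
            unknown = r.external_ticks - category_set
            if unknown:
                raise SurveyValidationError(
                    f"tick referencing unknown external categor(ies) "
                    f"{sorted(unknown)} by {r.respondent!r}"
                )

    # -- convenience ------------------------------------------------------

    @property
    def n_members(self) -> int:
        return len(self.members)

    def member(self, member_id: str) -> Member:
        for m in self.members:
            if m.member_id == member_id:
                return m
        raise KeyError(member_id)

    def response_for(
        self, respondent: str, condition: Condition, direction: Direction
    ) -> Optional[Response]:
        """The unique response for the combination, or None if absent.

        An absent response is treated downstream exactly like an explicit
        ``missing=True`` one (partial missingness).
        """
        for r in self.responses:
            if (
                r.respondent == respondent
                and r.condition is condition
                and r.direction is direction
            ):
                return r
        return None

    def is_nonresponder(self, member_id: str) -> bool:
        """True if every one of the member's six responses is missing/absent."""
        for condition in Condition:
            for direction in Direction:
                r = self.response_for(member_id, condition, direction)
                if r is not None and not r.missing:
                    return False
        return True

    def nonresponders(self) -> list[str]:
        return [m.member_id for m in self.members if self.is_nonresponder(m.member_id)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SurveyDataset):
            return NotImplemented
        return (
            self.practice_id == other.practice_id
            and self.members == other.members
            and self.external_categories == other.external_categories
            and self.responses == other.responses
        )


def response_rate(dataset: SurveyDataset) -> float:
    """Fraction of roster members who returned any part of the questionnaire.

    A nonresponder is a member *all* of whose responses are missing; a
    member who answered even one condition/direction counts as a
    responder.  Equals 1.0 iff no member is fully missing.
    """
    n = dataset.n_members
    if n < 1:
        raise SurveyValidationError("response_rate requires at least one member")
    return (n - len(dataset.nonresponders())) / n


# -- CSV reading/writing --------------------------------------------------

SURVEY_HEADER = ["practice_id", "respondent", "condition", "direction", "alter", "alter_kind"]
ROSTER_HEADER = ["practice_id", "kind", "id", "name", "discipline"]


def read_roster(path: str | Path) -> tuple[str, list[Member], list[ExternalCategory]]:
    """Parse a roster CSV into members and external categories."""
    path = Path(path)
    members: list[Member] = []
    categories: list[ExternalCategory] = []
    practice_id: Optional[str] = None
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != ROSTER_HEADER:
            raise SurveyFormatError(
                f"{path}: expected roster header {ROSTER_HEADER}, got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            pid = row["practice_id"]
            if practice_id is None:
                practice_id = pid
            elif pid != practice_id:
                raise SurveyFormatError(f"{path}:{i}: mixed practice_id values")
            kind = row["kind"]
            if kind == "member":
                try:
                    disc = Discipline(row["discipline"])
                except ValueError:
                    raise SurveyFormatError(
                        f"{path}:{i}: unknown discipline {row['discipline']!r}"
                    ) from None
                members.append(Member(row["id"], disc, row["name"]))
            elif kind == "external":
                categories.append(ExternalCategory(row["id"], row["name"]))
            else:
                raise SurveyFormatError(f"{path}:{i}: unknown kind {kind!r}")
    if practice_id is None:
        raise SurveyFormatError(f"{path}: empty roster")
    return practice_id, members, categories


def read_survey(survey_path: str | Path, roster_path: str | Path) -> SurveyDataset:
    """Read and validate a long-form survey CSV against its roster.

    Every (respondent, condition, direction) combination must be present,
    either as tick rows or as a single ``__NONE__`` / ``__MISSING__``
    sentinel row.  Duplicate ticks, unknown alters, self-ticks and
    sentinel rows mixed with ticks are hard errors naming the offending
    row.
    """
    practice_id, members, categories = read_roster(roster_path)
    member_ids = {m.member_id for m in members}
    category_ids = {c.category_id for c in categories}

    survey_path = Path(survey_path)
    groups: dict[tuple[str, Condition, Direction], list[tuple[int, str, str]]] = {}
    with survey_path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != SURVEY_HEADER:
            raise SurveyFormatError(
                f"{survey_path}: expected header {SURVEY_HEADER}, got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            if row["practice_id"] != practice_id:
                raise SurveyFormatError(
                    f"{survey_path}:{i}: practice_id {row['practice_id']!r} "
                    f"does not match roster {practice_id!r}"
                )
            respondent = row["respondent"]
            if respondent not in member_ids:
                raise SurveyFormatError(
                    f"{survey_path}:{i}: unknown respondent {respondent!r}"
                )
            try:
                condition = Condition(row["condition"])
                direction = Direction(row["direction"])
            except ValueError as exc:
                raise SurveyFormatError(f"{survey_path}:{i}: {exc}") from None
            groups.setdefault((respondent, condition, direction), []).append(
                (i, row["alter"], row["alter_kind"])
            )

    responses: list[Response] = []
    for m in members:
        for condition in Condition:
            for direction in Direction:
                key = (m.member_id, condition, direction)
                rows = groups.pop(key, None)
                if rows is None:
                    raise SurveyFormatError(
                        f"{survey_path}: no row for respondent={m.member_id!r} "
                        f"condition={condition.value} direction={direction.value}; "
                        f"use {NONE_TOKEN} or {MISSING_TOKEN} to make absence explicit"
                    )
                responses.append(
                    _parse_group(survey_path, m.member_id, condition, direction,
                                 rows, member_ids, category_ids)
                )
    return SurveyDataset(practice_id, members, categories, responses)


def _parse_group(
    path: Path,
    respondent: str,
    condition: Condition,
    direction: Direction,
    rows: list[tuple[int, str, str]],
    member_ids: set[str],
    category_ids: set[str],
) -> Response:
    sentinels = [r for r in rows if r[1] in (NONE_TOKEN, MISSING_TOKEN)]
    if sentinels:
        line, token, _ = sentinels[0]
        if len(rows) > 1:
            raise SurveyFormatError(
                f"{path}:{line}: {token} row mixed with other rows for "
                f"{respondent!r}/{condition.value}/{direction.value}"
            )
        missing = token == MISSING_TOKEN
        return Response(respondent, condition, direction, missing=missing)

    internal: set[str] = set()
    external: set[str] = set()
    for line, alter, kind in rows:
        if kind == "internal":
            if alter == respondent:
                raise SurveyFormatError(f"{path}:{line}: self-tick by {respondent!r}")
            if alter not in member_ids:
                raise SurveyFormatError(
                    f"{path}:{line}: tick references unknown member {alter!r}"
                )
            if alter in internal:
                raise SurveyFormatError(
                    f"{path}:{line}: duplicate tick {respondent!r}->{alter!r}"
                )
            internal.add(alter)
        elif kind == "external":
            if alter not in category_ids:
                raise SurveyFormatError(
                    f"{path}:{line}: tick references unknown category {alter!r}"
                )
            if alter in external:
                raise SurveyFormatError(
                    f"{path}:{line}: duplicate external tick {respondent!r}->{alter!r}"
                )
            external.add(alter)
        else:
            raise SurveyFormatError(f"{path}:{line}: unknown alter_kind {kind!r}")
    return Response(
        respondent, condition, direction,
        internal_ticks=frozenset(internal), external_ticks=frozenset(external),
    )


def write_survey(
    dataset: SurveyDataset, survey_path: str | Path, roster_path: str | Path
) -> None:
    """Write a dataset back to the survey/roster CSV pair.

    Output is canonical (sorted rows, explicit sentinels), so
    write-then-read is the identity on valid datasets.
    """
    roster_path = Path(roster_path)
    with roster_path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ROSTER_HEADER)
        for m in dataset.members:
            writer.writerow(
                [dataset.practice_id, "member", m.member_id, m.name, m.discipline.value]
            )
        for c in dataset.external_categories:
            writer.writerow([dataset.practice_id, "external", c.category_id, c.label, ""])

    survey_path = Path(survey_path)
    with survey_path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SURVEY_HEADER)
        for r in dataset.responses:
            base = [dataset.practice_id, r.respondent, r.condition.value, r.direction.value]
            if r.missing:
                writer.writerow(base + [MISSING_TOKEN, ""])
            elif not r.internal_ticks and not r.external_ticks:
                writer.writerow(base + [NONE_TOKEN, ""])
            else:
                for alter in sorted(r.internal_ticks):
                    writer.writerow(base + [alter, "internal"])
                for alter in sorted(r.external_ticks):
                    writer.writerow(base + [alter, "external"])
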