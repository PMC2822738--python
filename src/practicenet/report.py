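"""Pipeline driver and report assembly.

Runs the full analysis for one practice in the order the method
prescribes — build networks, assess receiving/providing agreement
*before* imputation, impute missing receiving rows, then compute
metrics, cross-condition overlap and external-tie statistics on the
imputed receiving networks — and assembles the result into a
:class:`PracticeReport` plus four summary tables:

* table 1 — roster counts, reported connections, theoretical maximum
  ``n(n-1)``, per-condition agreement;
* table 2 — density, hierarchy, out/in centralization, disciplines of
  the most out-central actors;
* table 3 — overlap for the three condition pairs and the triple;
* table 4 — external connections, their share of all connections, and
  the most central actor's share of them.

Rounding happens here and only here: density and hierarchy to 2
decimals, agreement and overlap to 3, centralization and percentages to
whole numbers, always half-away-from-zero.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional

import pandas as pd

from .build import (
    AgreementResult,
    DirectedNetwork,
    agreement,
    build_network,
    impute_receiving,
    write_dot,
    write_edge_csv,
    write_graphml,
)
from .external import ExternalStats, compute_external_stats
from .metrics import NetworkMetrics, compute_metrics
from .overlap import OverlapResult, compute_overlaps
from .roster import Condition, Direction, Discipline, SurveyDataset, read_survey, response_rate

logger = logging.getLogger("practicenet")


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round half away from zero (what report tables use), not banker's."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConditionBlock:
    """Everything the report knows about one condition's networks."""

    condition: Condition
    internal_ties: int
    external_ties: int
    theoretical_max: int
    agreement: AgreementResult
    metrics: NetworkMetrics
    external: ExternalStats
    imputed_entries: int
    zero_filled_entries: int


@dataclass
class PracticeReport:
    """Assembled summary of one practice across the three conditions."""

    practice_id: str
    n_members: int
    n_by_discipline: dict[Discipline, int]
    nonresponders: list[str]
    response_rate: float
    conditions: dict[Condition, ConditionBlock]
    overlaps: list[OverlapResult]

    @property
    def theoretical_max(self) -> int:
        return self.n_members * (self.n_members - 1)


def analyze_practice(dataset: SurveyDataset) -> PracticeReport:
    """Run the full per-practice analysis pipeline on one survey dataset."""
    imputed: dict[Condition, DirectedNetwork] = {}
    blocks: dict[Condition, ConditionBlock] = {}
    for condition in Condition:
        receiving = build_network(dataset, condition, Direction.RECEIVE)
        providing = build_network(dataset, condition, Direction.PROVIDE)
        agree = agreement(receiving, providing)
        net = impute_receiving(receiving, providing)
        imputed[condition] = net
        counts = net.provenance_counts()
        blocks[condition] = ConditionBlock(
            condition=condition,
            internal_ties=net.tie_count,
            external_ties=net.external_tie_count,
            theoretical_max=net.n * (net.n - 1),
            agreement=agree,
            metrics=compute_metrics(net),
            external=compute_external_stats(net),
            imputed_entries=counts["imputed"],
            zero_filled_entries=counts["zero_filled"],
        )
        logger.info(
            "practice %s %s: %d ties, agreement %s over %d pairs, "
            "%d imputed / %d zero-filled entries",
            dataset.practice_id, condition.value, net.tie_count,
            "undefined" if not agree.defined else f"{agree.proportion:.3f}",
            agree.n_pairs, counts["imputed"], counts["zero_filled"],
        )
    n_by_discipline = {d: 0 for d in Discipline}
    for m in dataset.members:
        n_by_discipline[m.discipline] += 1
    return PracticeReport(
        practice_id=dataset.practice_id,
        n_members=dataset.n_members,
        n_by_discipline=n_by_discipline,
        nonresponders=dataset.nonresponders(),
        response_rate=response_rate(dataset),
        conditions=blocks,
        overlaps=compute_overlaps(imputed),
    )


# -- table emitters -------------------------------------------------------

def table1(report: PracticeReport) -> pd.DataFrame:
    """Roster composition, connection counts and agreement per condition."""
    rows = []
    for c in Condition:
        block = report.conditions[c]
        agree = block.agreement
        rows.append({
            "practice_id": report.practice_id,
            "condition": c.value,
            "n_gps": report.n_by_discipline[Discipline.GP],
            "n_assistants": report.n_by_discipline[Discipline.ASSISTANT],
            "n_nurses": report.n_by_discipline[Discipline.NURSE],
            "n_members": report.n_members,
            "n_nonresponders": len(report.nonresponders),
            "receiving_connections": block.internal_ties,
            "theoretical_max": block.theoretical_max,
            "agreement": (
                round_half_up(agree.proportion, 3) if agree.defined else None
            ),
            "agreement_pairs": agree.n_pairs,
        })
    return pd.DataFrame(rows)


def table2(report: PracticeReport) -> pd.DataFrame:
    """Density, hierarchy, centralization and central disciplines."""
    rows = []
    for c in Condition:
        m = report.conditions[c].metrics
        rows.append({
            "practice_id": report.practice_id,
            "condition": c.value,
            "density": round_half_up(m.density, 2),
            "hierarchy": round_half_up(m.hierarchy, 2),
            "centralization_out_pct": int(round_half_up(m.centralization_out)),
            "centralization_in_pct": int(round_half_up(m.centralization_in)),
            "central_disciplines": m.central_disciplines,
        })
    return pd.DataFrame(rows)


def table3(report: PracticeReport) -> pd.DataFrame:
    """Overlap between condition-specific networks (pairs + triple)."""
    rows = []
    for o in report.overlaps:
        rows.append({
            "practice_id": report.practice_id,
            "networks": o.tag,
            "total": round_half_up(o.total, 3) if o.total is not None else None,
            "connected_individuals": round_half_up(o.connected_individuals, 3),
        })
    return pd.DataFrame(rows)


def table4(report: PracticeReport) -> pd.DataFrame:
    """External connections and the central actor's share of them."""
    rows = []
    for c in Condition:
        block = report.conditions[c]
        frac = block.external.external_fraction
        rows.append({
            "practice_id": report.practice_id,
            "condition": c.value,
            "external_connections": block.external_ties,
            "external_pct": int(round_half_up(frac)) if frac is not None else None,
            "central_share": str(block.external.central_share),
            "central_tied": block.external.central_share.tied,
        })
    return pd.DataFrame(rows)


def report_to_dict(report: PracticeReport) -> dict:
    """JSON-serializable view of the full report (full precision)."""
    def block(b: ConditionBlock) -> dict:
        return {
            "internal_ties": b.internal_ties,
            "external_ties": b.external_ties,
            "theoretical_max": b.theoretical_max,
            "agreement": b.agreement.proportion,
            "agreement_pairs": b.agreement.n_pairs,
            "density": b.metrics.density,
            "hierarchy": b.metrics.hierarchy,
            "centralization_out": b.metrics.centralization_out,
            "centralization_in": b.metrics.centralization_in,
            "central_actors": sorted(m for m, _ in b.metrics.most_central_out),
            "central_disciplines": b.metrics.central_disciplines,
            "external_pct": b.external.external_fraction,
            "central_share": str(b.external.central_share),
            "imputed_entries": b.imputed_entries,
            "zero_filled_entries": b.zero_filled_entries,
        }

    return {
        "practice_id": report.practice_id,
        "n_members": report.n_members,
        "n_by_discipline": {d.value: k for d, k in report.n_by_discipline.items()},
        "nonresponders": report.nonresponders,
        "response_rate": report.response_rate,
        "theoretical_max": report.theoretical_max,
        "conditions": {c.value: block(b) for c, b in report.conditions.items()},
        "overlaps": [
            {
                "networks": o.tag,
                "total": o.total,
                "connected_individuals": o.connected_individuals,
            }
            for o in report.overlaps
        ],
    }


# -- pipeline -------------------------------------------------------------

def run_pipeline(
    survey_path: str | Path,
    roster_path: str | Path,
    output_dir: str | Path,
    *,
    export_graphml: bool = True,
    export_dot: bool = True,
    export_edges: bool = True,
) -> PracticeReport:
    """Read one practice's survey, analyze it and write all outputs.

    Writes ``table1.csv`` ... ``table4.csv``, ``report.json`` and, per
    condition, network exports (GraphML/DOT/edge CSV for the imputed
    receiving and the raw providing network).  On failure, any partially
    written outputs are removed before the exception propagates.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(path: Path, writer) -> None:
        writer(path)
        written.append(path)

    try:
        dataset = read_survey(survey_path, roster_path)
        report = analyze_practice(dataset)

        for name, frame in (
            ("table1", table1(report)),
            ("table2", table2(report)),
            ("table3", table3(report)),
            ("table4", table4(report)),
        ):
            emit(output_dir / f"{name}.csv",
                 lambda p, f=frame: f.to_csv(p, index=False))
        emit(
            output_dir / "report.json",
            lambda p: p.write_text(
                json.dumps(report_to_dict(report), indent=2, sort_keys=True) + "\n",
                encoding="utf-8",
            ),
        )

        for condition in Condition:
            receiving = impute_receiving(
                build_network(dataset, condition, Direction.RECEIVE),
                build_network(dataset, condition, Direction.PROVIDE),
            )
            providing = build_network(dataset, condition, Direction.PROVIDE)
            for net, tag in ((receiving, "receive"), (providing, "provide")):
                stem = f"{dataset.practice_id}_{condition.value}_{tag}"
                if export_graphml:
                    emit(output_dir / f"{stem}.graphml",
                         lambda p, n=net: write_graphml(n, p))
                if export_dot:
                    emit(output_dir / f"{stem}.dot",
                         lambda p, n=net: write_dot(n, p))
                if export_edges:
                    emit(output_dir / f"{stem}_edges.csv",
                         lambda p, n=net: write_edge_csv(n, p))
        logger.info(
            "practice %s: wrote %d output files to %s (deterministic, no RNG)",
            report.practice_id, len(written), output_dir,
        )
        return report
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
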