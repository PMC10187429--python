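"""Agreement scoring, top-k sweeps, marker-presence diagnostics, and the
reproducibility statistic.

Agreement between a manual annotation and a model annotation of the same
cluster is a three-level human judgment — fully match (score 1), partially
match (0.5, e.g. one label is a subtype of the other), mismatch (0). The
package consumes adjudication tables; it never decides the judgment itself
beyond pre-filling "fully" for surface-identical labels.

Reproducibility of repeated identical queries is the proportion of responses
equal to the most prevalent response, after surface normalisation (case fold,
whitespace collapse) but deliberately without any synonym or stemming model:
"endothelial cells" and "blood vascular endothelial cells" count as different.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .annotate import annotate_clusters
from .backends import Backend
from .errors import CellPromptError, FormatError
from .marker_io import ClusterMarkerList, DifferentialGeneTable, extract_top_genes
from .prompts import PromptOptions, TissueContext

logger = logging.getLogger(__name__)


class MatchLevel(Enum):
    FULLY = "fully"
    PARTIALLY = "partially"
    MISMATCH = "mismatch"

    @property
    def score(self) -> float:
        return {"fully": 1.0, "partially": 0.5, "mismatch": 0.0}[self.value]

    @classmethod
    def from_string(cls, text: str) -> "MatchLevel":
        try:
            return cls(text.strip().lower())
        except ValueError:
            raise ValueError(
                f"match level must be one of fully/partially/mismatch, got {text!r}"
            ) from None


def normalize_label(label: str) -> str:
    """Surface normalisation: trim, case-fold, collapse internal whitespace."""
    return " ".join(label.split()).casefold()


@dataclass
class AdjudicationRow:
    unit_id: str
    manual_label: str
    model_label: str
    level: MatchLevel | None
    tissue: str = ""
    category: str | None = None


@dataclass
class AdjudicationTable:
    """Per-cluster match levels driving agreement scores."""

    rows: list[AdjudicationRow]

    def __post_init__(self):
        ids = [r.unit_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("unit_ids must be unique")

    @classmethod
    def read_csv(cls, path: str | Path) -> "AdjudicationTable":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        required = {"unit_id", "manual_label", "model_label", "level"}
        missing = required - set(frame.columns)
        if missing:
            raise FormatError(f"adjudication table missing columns: {sorted(missing)}")
        rows = [
            AdjudicationRow(
                unit_id=rec["unit_id"],
                manual_label=rec["manual_label"],
                model_label=rec["model_label"],
                level=MatchLevel.from_string(rec["level"]) if rec["level"] else None,
                tissue=rec.get("tissue", ""),
                category=rec.get("category") or None,
            )
            for rec in frame.to_dict("records")
        ]
        return cls(rows=rows)

    def write_csv(self, path: str | Path) -> None:
        frame = pd.DataFrame(
            {
                "unit_id": [r.unit_id for r in self.rows],
                "tissue": [r.tissue for r in self.rows],
                "category": [r.category or "" for r in self.rows],
                "manual_label": [r.manual_label for r in self.rows],
                "model_label": [r.model_label for r in self.rows],
                "level": [r.level.value if r.level else "" for r in self.rows],
            }
        )
        frame.to_csv(path, index=False)


@dataclass(frozen=True)
class AgreementSummary:
    group_key: str
    n: int
    prop_fully: float
    prop_partially: float
    prop_mismatch: float
    mean_score: float


def prefill_adjudications(
    pairs: Iterable[tuple[str, str, str]],
    tissue: str = "",
    category: str | None = None,
) -> AdjudicationTable:
    """Draft an adjudication table from (unit_id, manual, model) triples.

    Surface-identical labels are pre-filled as ``fully``; everything else is
    left blank for a human adjudicator — no synonym inference is attempted.
    """
    rows = [
        AdjudicationRow(
            unit_id=uid,
            manual_label=manual,
            model_label=model,
            level=MatchLevel.FULLY
            if normalize_label(manual) == normalize_label(model)
            else None,
            tissue=tissue,
            category=category,
        )
        for uid, manual, model in pairs
    ]
    return AdjudicationTable(rows=rows)


def score_agreement(
    table: AdjudicationTable, group_by: str | None = None
) -> list[AgreementSummary]:
    """Summarise match levels, optionally grouped by ``tissue`` or ``category``.

    The mean score is the unweighted mean over the group's rows, i.e. each
    annotated cell type counts once.
    """
    if not table.rows:
        raise ValueError("adjudication table is empty")
    if any(r.level is None for r in table.rows):
        raise ValueError("every row must be adjudicated before scoring")
    if group_by is None:
        groups: dict[str, list[AdjudicationRow]] = {"all": list(table.rows)}
    elif group_by in {"tissue", "category"}:
        groups = {}
        for row in table.rows:
            key = getattr(row, group_by) or ""
            groups.setdefault(key, []).append(row)
    else:
        raise ValueError(f"cannot group by {group_by!r}")

    summaries = []
    for key, rows in groups.items():
        n = len(rows)
        counts = {lvl: sum(1 for r in rows if r.level is lvl) for lvl in MatchLevel}
        summaries.append(
            AgreementSummary(
                group_key=key,
                n=n,
                prop_fully=counts[MatchLevel.FULLY] / n,
                prop_partially=counts[MatchLevel.PARTIALLY] / n,
                prop_mismatch=counts[MatchLevel.MISMATCH] / n,
                mean_score=sum(r.level.score for r in rows) / n,
            )
        )
    return summaries


Adjudicator = Callable[[str, str], MatchLevel]


def exact_match_adjudicator(truth: Mapping[str, str]) -> Adjudicator:
    """Adjudicator scoring ``fully`` iff the label equals the per-cluster truth
    after surface normalisation, ``mismatch`` otherwise."""
    normalized = {cid: normalize_label(lab) for cid, lab in truth.items()}

    def judge(cluster_id: str, label: str) -> MatchLevel:
        if normalize_label(label) == normalized[cluster_id]:
            return MatchLevel.FULLY
        return MatchLevel.MISMATCH

    return judge


def sweep_top_k(
    table: DifferentialGeneTable,
    ks: Sequence[int],
    context: TissueContext,
    backend: Backend,
    adjudicator: Adjudicator | Mapping[tuple[str, str], MatchLevel],
    options: PromptOptions = PromptOptions(),
) -> dict[int, AgreementSummary]:
    """Run the full annotation pipeline at each ``k`` and score agreement.

    ``adjudicator`` maps (cluster_id, label) to a match level — either a
    callable or an explicit mapping.
    """
    if not ks:
        raise ValueError("ks must be non-empty")
    if callable(adjudicator):
        judge = adjudicator
    else:
        judge = lambda cid, lab: adjudicator[(cid, lab)]  # noqa: E731

    results: dict[int, AgreementSummary] = {}
    for k in ks:
        try:
            markers = extract_top_genes(table, k)
            result = annotate_clusters(markers, context, backend, options)
            adj = AdjudicationTable(
                rows=[
                    AdjudicationRow(
                        unit_id=cid,
                        manual_label="",
                        model_label=label,
                        level=judge(cid, label),
                    )
                    for cid, label in result.labels.items()
                ]
            )
            results[k] = score_agreement(adj)[0]
        except CellPromptError as exc:
            raise type(exc)(f"top-k sweep failed at k={k}: {exc}") from exc
    return results


def gene_presence_report(
    markers: ClusterMarkerList,
    gene_set: Sequence[str],
    grouping: Mapping[str, str],
) -> dict[str, float]:
    """Per group, the proportion of clusters whose marker list contains at
    least one gene from ``gene_set`` (e.g. type I collagen genes in clusters
    called fibroblast/stromal)."""
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    missing = [cid for cid in markers.entries if cid not in grouping]
    if missing:
        raise ValueError(f"clusters missing from grouping: {missing}")
    wanted = set(gene_set)
    hits: dict[str, list[bool]] = {}
    for cid, genes in markers.entries.items():
        hits.setdefault(grouping[cid], []).append(bool(wanted & set(genes)))
    return {group: sum(flags) / len(flags) for group, flags in hits.items()}


@dataclass(frozen=True)
class CellTypeReproducibility:
    n_queries: int
    modal_label: str
    modal_count: int
    reproducibility: float


@dataclass
class ReproducibilityReport:
    per_cell_type: dict[str, CellTypeReproducibility]
    mean_reproducibility: float


def round_half_up(value: float, digits: int = 2) -> float:
    """Display rounding (0.885 -> 0.89); raw fractions stay in the report."""
    quantum = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def reproducibility(
    labels_by_cell_type: Mapping[str, Sequence[str]]
) -> ReproducibilityReport:
    """Modal-annotation proportion per repeatedly queried cell type.

    Labels are surface-normalised before counting; the modal label is the most
    frequent normalised form (ties broken lexicographically) and the
    reproducibility is modal_count / n_queries. The mean over cell types is
    unweighted.
    """
    per: dict[str, CellTypeReproducibility] = {}
    for cell_type, labels in labels_by_cell_type.items():
        if not labels:
            raise ValueError(f"cell type {cell_type!r} has no recorded labels")
        counts: dict[str, int] = {}
        for label in labels:
            key = normalize_label(label)
            counts[key] = counts.get(key, 0) + 1
        modal = min(counts, key=lambda lab: (-counts[lab], lab))
        per[cell_type] = CellTypeReproducibility(
            n_queries=len(labels),
            modal_label=modal,
            modal_count=counts[modal],
            reproducibility=counts[modal] / len(labels),
        )
    if not per:
        raise ValueError("no cell types supplied")
    mean = sum(r.reproducibility for r in per.values()) / len(per)
    return ReproducibilityReport(per_cell_type=per, mean_reproducibility=mean)
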