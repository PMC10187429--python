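"""Simulation benchmarks for mixed and unknown cell types.

Two generators build query batches with ground truth:

* mixed: marker rows formed by combining the marker lists of two randomly
  chosen distinct cell types, interleaved with single-type negative controls;
* unknown: marker rows of randomly drawn genes from a gene universe (a
  cluster matching no documented type), interleaved with known-type controls.

Each study runs ten positives and ten negative controls per iteration and is
repeated five times by default. Responses are classified by a configurable
keyword rule (the original correctness judgment was human, so the rule is
conservative and logged with results), and accuracy is the proportion of
queries whose single-versus-positive call matches the truth — the specific
cell type name of a negative control does not need to match.
"""

from __future__ import annotations

import csv
import io
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import SimulationError
from .evaluation import normalize_label
from .marker_io import MarkerGeneSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MixedSimSpec:
    """Mixed-cell-type study: per rep, ``n_mixed`` two-type combinations and
    ``n_single`` single-type negative controls."""

    n_mixed: int = 10
    n_single: int = 10
    n_reps: int = 5
    seed: int = 0

    def __post_init__(self):
        if min(self.n_mixed, self.n_single, self.n_reps) < 1:
            raise ValueError("all counts must be >= 1")


@dataclass(frozen=True)
class UnknownSimSpec:
    """Unknown-cell-type study: per rep, ``n_unknown`` random-gene rows and
    ``n_known`` known-type negative controls."""

    n_unknown: int = 10
    genes_per_unknown: int = 10
    n_known: int = 10
    n_reps: int = 5
    seed: int = 0

    def __post_init__(self):
        if min(self.n_unknown, self.genes_per_unknown, self.n_known, self.n_reps) < 1:
            raise ValueError("all counts must be >= 1")


@dataclass(frozen=True)
class QueryTruth:
    """Ground truth for one query: kind is single/mixed/unknown; detail names
    the source type (single) or the two parents (mixed)."""

    kind: str
    detail: str = ""


@dataclass(frozen=True)
class SimQuery:
    query_id: str
    rep_index: int
    row: str


@dataclass
class SimulationBatch:
    queries: list[SimQuery]
    truth: dict[str, QueryTruth]
    batch_id: str = "sim"

    def __post_init__(self):
        missing = [q.query_id for q in self.queries if q.query_id not in self.truth]
        if missing:
            raise ValueError(f"truth missing for query_ids: {missing}")

    def to_csv(self) -> str:
        """Queries and truth as one deterministic CSV string."""
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["query_id", "rep", "row_genes", "truth_class", "detail"])
        for q in self.queries:
            t = self.truth[q.query_id]
            writer.writerow([q.query_id, q.rep_index, q.row, t.kind, t.detail])
        return buf.getvalue()


def _combine_markers(first: Sequence[str], second: Sequence[str]) -> str:
    """Dedup-union preserving first-parent order, then the second's novel genes."""
    seen = dict.fromkeys(first)
    merged = list(seen) + [g for g in second if g not in seen]
    return ",".join(merged)


def simulate_mixed(
    spec: MixedSimSpec,
    markers: MarkerGeneSet,
    rng: np.random.Generator | None = None,
    batch_id: str = "mixed",
) -> SimulationBatch:
    """Generate the mixed-cell-type benchmark with ground truth.

    Mixture parents are sampled uniformly without replacement (a type is never
    mixed with itself); negative-control types are distinct within a rep.
    Queries are shuffled within each rep so positives and negatives interleave.
    Fully reproducible from ``spec.seed``.
    """
    names = list(markers.entries)
    if len(names) < 2:
        raise SimulationError("mixed simulation needs at least 2 source cell types")
    if spec.n_single > len(names):
        raise SimulationError(
            f"cannot draw {spec.n_single} distinct single types from {len(names)}"
        )
    rng = rng if rng is not None else np.random.default_rng(spec.seed)

    queries: list[SimQuery] = []
    truth: dict[str, QueryTruth] = {}
    for rep in range(1, spec.n_reps + 1):
        rep_queries: list[SimQuery] = []
        for i in range(spec.n_mixed):
            a, b = (names[j] for j in rng.choice(len(names), size=2, replace=False))
            qid = f"{batch_id}-r{rep}-m{i}"
            rep_queries.append(
                SimQuery(qid, rep, _combine_markers(markers.entries[a], markers.entries[b]))
            )
            truth[qid] = QueryTruth(kind="mixed", detail=f"{a},{b}")
        for i, j in enumerate(rng.choice(len(names), size=spec.n_single, replace=False)):
            name = names[j]
            qid = f"{batch_id}-r{rep}-s{i}"
            rep_queries.append(SimQuery(qid, rep, ",".join(markers.entries[name])))
            truth[qid] = QueryTruth(kind="single", detail=name)
        order = rng.permutation(len(rep_queries))
        queries.extend(rep_queries[j] for j in order)
    return SimulationBatch(queries=queries, truth=truth, batch_id=batch_id)


def simulate_unknown(
    spec: UnknownSimSpec,
    universe: Sequence[str],
    markers: MarkerGeneSet,
    rng: np.random.Generator | None = None,
    batch_id: str = "unknown",
) -> SimulationBatch:
    """Generate the unknown-cell-type benchmark with ground truth.

    Unknown rows draw ``genes_per_unknown`` genes without replacement from the
    gene universe; known-type negative controls reuse genuine marker lists.
    """
    universe = [g.strip() for g in universe if g and g.strip()]
    names = list(markers.entries)
    if len(universe) < spec.genes_per_unknown:
        raise SimulationError(
            f"gene universe has {len(universe)} symbols, "
            f"need >= {spec.genes_per_unknown}"
        )
    if spec.n_known > len(names):
        raise SimulationError(
            f"cannot draw {spec.n_known} distinct known types from {len(names)}"
        )
    rng = rng if rng is not None else np.random.default_rng(spec.seed)

    queries: list[SimQuery] = []
    truth: dict[str, QueryTruth] = {}
    for rep in range(1, spec.n_reps + 1):
        rep_queries: list[SimQuery] = []
        for i in range(spec.n_unknown):
            picks = rng.choice(len(universe), size=spec.genes_per_unknown, replace=False)
            qid = f"{batch_id}-r{rep}-u{i}"
            rep_queries.append(SimQuery(qid, rep, ",".join(universe[j] for j in picks)))
            truth[qid] = QueryTruth(kind="unknown")
        for i, j in enumerate(rng.choice(len(names), size=spec.n_known, replace=False)):
            name = names[j]
            qid = f"{batch_id}-r{rep}-s{i}"
            rep_queries.append(SimQuery(qid, rep, ",".join(markers.entries[name])))
            truth[qid] = QueryTruth(kind="single", detail=name)
        order = rng.permutation(len(rep_queries))
        queries.extend(rep_queries[j] for j in order)
    return SimulationBatch(queries=queries, truth=truth, batch_id=batch_id)


#: Default keyword rules for classifying free-text responses. Logged with
#: results because the original correctness judgment was made by a reader.
MIXED_KEYWORDS: tuple[str, ...] = ("mixture", "mixed")
MIXED_JOINERS: tuple[str, ...] = (r"\band\b", r"/", r"\+")
UNKNOWN_KEYWORDS: tuple[str, ...] = ("unknown", "novel", "unidentified", "not a known")


@dataclass(frozen=True)
class Classification:
    positive: bool
    label: str | None  # pass-through label for negative calls


def classify_response(
    label: str,
    mode: str,
    keywords: Sequence[str] | None = None,
) -> Classification:
    """Call a response positive (mixture / unknown claimed) or negative.

    ``mixed_test`` is positive when the label mentions a mixture or joins two
    names with and / ``/`` / ``+``; ``unknown_test`` when it declares the type
    unknown, novel or unidentified.
    """
    if not label or not label.strip():
        raise ValueError("label must be non-empty")
    norm = normalize_label(label)
    if mode == "mixed_test":
        kws = keywords if keywords is not None else MIXED_KEYWORDS
        if any(kw in norm for kw in kws):
            return Classification(positive=True, label=None)
        if any(re.search(j, norm) for j in MIXED_JOINERS):
            return Classification(positive=True, label=None)
        return Classification(positive=False, label=label)
    if mode == "unknown_test":
        kws = keywords if keywords is not None else UNKNOWN_KEYWORDS
        if any(kw in norm for kw in kws):
            return Classification(positive=True, label=None)
        return Classification(positive=False, label=label)
    raise ValueError(f"unknown classification mode {mode!r}")


@dataclass(frozen=True)
class RepAccuracy:
    rep_index: int
    n_correct: int
    n_total: int
    accuracy: float


@dataclass
class SimAccuracyResult:
    per_rep: list[RepAccuracy]
    mean_accuracy: float
    pooled_accuracy: float
    #: mixed-truth queries answered with exactly one parent type: counted
    #: incorrect, but reported separately because the call is debatable
    parent_only_ids: list[str] = field(default_factory=list)


def compute_sim_accuracy(
    batch: SimulationBatch,
    labels: Mapping[str, str],
    mode: str,
    keywords: Sequence[str] | None = None,
) -> SimAccuracyResult:
    """Score backend labels against a batch's truth table.

    A query is correct iff the keyword classifier's single-versus-positive
    call agrees with the truth category. Per-rep accuracies (unweighted mean
    reported) and the pooled per-query accuracy are both returned.
    """
    missing = [q.query_id for q in batch.queries if q.query_id not in labels]
    if missing:
        raise SimulationError(f"labels missing for query_ids: {missing}")

    per_rep_counts: dict[int, list[int]] = {}
    parent_only: list[str] = []
    n_correct_total = 0
    for q in batch.queries:
        t = batch.truth[q.query_id]
        cls = classify_response(labels[q.query_id], mode, keywords)
        correct = cls.positive == (t.kind in {"mixed", "unknown"})
        if t.kind == "mixed" and not cls.positive:
            parents = {normalize_label(p) for p in t.detail.split(",")}
            if normalize_label(labels[q.query_id]) in parents:
                parent_only.append(q.query_id)
        counts = per_rep_counts.setdefault(q.rep_index, [0, 0])
        counts[0] += int(correct)
        counts[1] += 1
        n_correct_total += int(correct)

    per_rep = [
        RepAccuracy(rep, c, n, c / n)
        for rep, (c, n) in sorted(per_rep_counts.items())
    ]
    if parent_only:
        logger.info(
            "%d mixed queries answered with a single parent type: %s",
            len(parent_only), parent_only,
        )
    return SimAccuracyResult(
        per_rep=per_rep,
        mean_accuracy=sum(r.accuracy for r in per_rep) / len(per_rep),
        pooled_accuracy=n_correct_total / len(batch.queries),
        parent_only_ids=parent_only,
    )


def collect_negative_control_labels(
    batches: Iterable[SimulationBatch],
    labels: Mapping[str, str],
) -> dict[str, list[str]]:
    """Group negative-control labels by their true cell type.

    Pools across reps and across studies (a type sampled in both the mixed and
    unknown benchmarks contributes all its repeats), feeding
    :func:`cellprompt.evaluation.reproducibility`.
    """
    grouped: dict[str, list[str]] = {}
    for batch in batches:
        for q in batch.queries:
            t = batch.truth[q.query_id]
            if t.kind == "single" and q.query_id in labels:
                grouped.setdefault(t.detail, []).append(labels[q.query_id])
    return grouped
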