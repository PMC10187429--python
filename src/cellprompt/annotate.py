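"""End-to-end cluster annotation: markers -> prompt -> backend -> labels.

Every backend exchange is appended to a single conversation log, so a run can
be replayed bit-exactly through a transcript backend recorded from it. Labels
are stored verbatim as returned — normalisation happens only at evaluation
time, keeping the raw output auditable.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, replace

from .backends import Backend, BackendConfig, Conversation
from .errors import ResponseParseError
from .marker_io import Markers, format_marker_rows
from .prompts import (
    PromptOptions,
    TissueContext,
    build_annotation_prompt,
    build_refinement_prompt,
    parse_annotation_response,
)


@dataclass
class AnnotationResult:
    """Per-cluster labels with full conversation provenance."""

    labels: dict[str, str]
    conversation_log: Conversation
    context: TissueContext
    k_used: int
    backend_info: BackendConfig | None = None
    refined_labels: dict[str, str] | None = None

    def __post_init__(self):
        if self.refined_labels is not None and set(self.refined_labels) != set(self.labels):
            raise ValueError("refined_labels must cover exactly the original clusters")


def _chunk(seq: list, size: int | None) -> list[list]:
    if size is None or size >= len(seq):
        return [seq]
    return [seq[i : i + size] for i in range(0, len(seq), size)]


def annotate_rows(
    rows: list[tuple[str, str]],
    context: TissueContext,
    backend: Backend,
    options: PromptOptions = PromptOptions(),
    conversation: Conversation | None = None,
    max_rows_per_prompt: int | None = None,
    prompt_set: str = "default",
) -> dict[str, str]:
    """Annotate (row_id, marker row) pairs; returns row_id -> label in order.

    Large inputs can be split across prompts with ``max_rows_per_prompt``;
    chunks are reassembled deterministically in input order.
    """
    if not rows:
        raise ValueError("no rows to annotate")
    conv = conversation if conversation is not None else Conversation()
    labels: dict[str, str] = {}
    for batch in _chunk(rows, max_rows_per_prompt):
        prompt = build_annotation_prompt(
            context, [text for _, text in batch], options, prompt_set
        )
        conv.append("user", prompt)
        raw = backend.complete(conv)
        parsed = parse_annotation_response(raw, expected_n=len(batch))
        conv.append("assistant", raw)
        for (row_id, _), label in zip(batch, parsed.labels):
            labels[row_id] = label
    return labels


def annotate_clusters(
    markers: Markers,
    context: TissueContext,
    backend: Backend,
    options: PromptOptions = PromptOptions(),
    backend_info: BackendConfig | None = None,
    max_rows_per_prompt: int | None = None,
    prompt_set: str = "default",
) -> AnnotationResult:
    """Annotate every cluster (or cell type) of a marker collection.

    All clusters go into a single prompt by default — one marker row per
    cluster — and the response must carry exactly one label per row. A parse
    or backend failure propagates and leaves no partial result.
    """
    if not markers.entries:
        raise ValueError("marker collection is empty")
    ids = list(markers.entries)
    rows = list(zip(ids, format_marker_rows(markers)))
    conv = Conversation()
    labels = annotate_rows(
        rows, context, backend, options,
        conversation=conv, max_rows_per_prompt=max_rows_per_prompt,
        prompt_set=prompt_set,
    )
    k_used = getattr(markers, "k_requested", None) or max(
        len(genes) for genes in markers.entries.values()
    )
    return AnnotationResult(
        labels=labels,
        conversation_log=conv,
        context=context,
        k_used=k_used,
        backend_info=backend_info,
    )


def refine_annotations(result: AnnotationResult, backend: Backend) -> AnnotationResult:
    """Send the refinement turn in the same conversation and parse the reply.

    Refinement applies to all rows at once. The original result is untouched;
    a count mismatch raises without modifying anything.
    """
    if not result.labels:
        raise ValueError("cannot refine an empty annotation result")
    conv = result.conversation_log.copy()
    conv.append("user", build_refinement_prompt())
    raw = backend.complete(conv)
    parsed = parse_annotation_response(raw, expected_n=len(result.labels))
    conv.append("assistant", raw)
    refined = dict(zip(result.labels, parsed.labels))
    return replace(result, refined_labels=refined, conversation_log=conv)


def _escape_r(label: str) -> str:
    return label.replace("'", "\\'")


def export_labels(result: AnnotationResult, format: str = "csv") -> str:
    """Serialise labels as ``csv``, ``r_vector`` or ``json``.

    The ``r_vector`` form emits ``c('label1','label2',...)`` in cluster order
    with single quotes (apostrophes escaped), round-trippable through
    :func:`cellprompt.prompts.parse_vector_response`.
    """
    if not result.labels:
        raise ValueError("annotation result is empty")
    if format == "r_vector":
        quoted = ",".join(f"'{_escape_r(lab)}'" for lab in result.labels.values())
        return f"c({quoted})"
    if format == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf)
        if result.refined_labels is not None:
            writer.writerow(["cluster_id", "label", "refined_label"])
            for cid, lab in result.labels.items():
                writer.writerow([cid, lab, result.refined_labels[cid]])
        else:
            writer.writerow(["cluster_id", "label"])
            for cid, lab in result.labels.items():
                writer.writerow([cid, lab])
        return buf.getvalue()
    if format == "json":
        payload = {
            "context": {"species": result.context.species, "tissue": result.context.tissue},
            "k_used": result.k_used,
            "labels": result.labels,
            "refined_labels": result.refined_labels,
            "conversation": [
                {"role": role, "text": text}
                for role, text in result.conversation_log.turns
            ],
        }
        if result.backend_info is not None:
            payload["backend"] = {
                "backend_kind": result.backend_info.backend_kind,
                "model_name": result.backend_info.model_name,
                "temperature": result.backend_info.temperature,
            }
        return json.dumps(payload, indent=2)
    raise ValueError(f"unknown export format {format!r}")
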