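"""Construct annotation prompts and parse backend responses into labels.

The prompt grammar is deliberately rigid: a two-sentence header naming the
species and tissue, optional single-sentence clauses permitting mixture or
unknown answers (in that fixed order, between header and rows), then one
comma-joined marker row per cluster. Byte-determinism of the rendered prompt
is part of the contract — it is what makes transcript replay and caching
meaningful.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Sequence

import yaml

from .errors import ResponseParseError


@lru_cache(maxsize=None)
def load_template_set(name: str = "default") -> dict[str, str]:
    """Load a named prompt template set shipped with the package."""
    ref = resources.files("cellprompt") / "templates" / f"{name}.yaml"
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise ValueError(f"unknown prompt set {name!r}") from None
    return yaml.safe_load(text)


@dataclass(frozen=True)
class TissueContext:
    """Species plus tissue. An empty tissue (aggregated atlases annotated
    across all tissues at once) simply drops the tissue word from the header."""

    species: str
    tissue: str = ""

    def __post_init__(self):
        if self.species not in {"human", "mouse"}:
            raise ValueError("species must be 'human' or 'mouse'")

    @property
    def subject(self) -> str:
        return f"{self.species} {self.tissue}".strip()


@dataclass(frozen=True)
class PromptOptions:
    """Independent switches for the mixture and unknown-cell-type clauses."""

    allow_mixture: bool = False
    allow_unknown: bool = False


@dataclass(frozen=True)
class AnnotationQuery:
    """A rendered prompt together with the row ids it covers."""

    context: TissueContext
    rows: tuple[tuple[str, str], ...]
    options: PromptOptions
    rendered_prompt: str


@dataclass(frozen=True)
class AnnotationResponse:
    raw_text: str
    labels: tuple[str, ...]


def build_annotation_prompt(
    context: TissueContext,
    rows: Sequence[str],
    options: PromptOptions = PromptOptions(),
    prompt_set: str = "default",
) -> str:
    """Render the initial annotation prompt: header, clauses, marker rows."""
    if not rows:
        raise ValueError("at least one marker row is required")
    templates = load_template_set(prompt_set)
    parts = [templates["annotation_header"].format(subject=context.subject)]
    if options.allow_mixture:
        parts.append(templates["mixture_clause"])
    if options.allow_unknown:
        parts.append(templates["unknown_clause"])
    parts.extend(rows)
    return "\n".join(parts)


def build_query(
    context: TissueContext,
    rows: Sequence[tuple[str, str]],
    options: PromptOptions = PromptOptions(),
    prompt_set: str = "default",
) -> AnnotationQuery:
    """Like :func:`build_annotation_prompt` but keeps row ids for bookkeeping."""
    prompt = build_annotation_prompt(
        context, [text for _, text in rows], options, prompt_set
    )
    return AnnotationQuery(
        context=context,
        rows=tuple((str(i), str(t)) for i, t in rows),
        options=options,
        rendered_prompt=prompt,
    )


def build_refinement_prompt(prompt_set: str = "default") -> str:
    """The follow-up turn asking for finer annotation granularity."""
    return load_template_set(prompt_set)["refinement"]


def build_vector_prompt(prompt_set: str = "default") -> str:
    """The conversion turn asking for the labels as an R ``c('...')`` vector."""
    return load_template_set(prompt_set)["vector_conversion"]


_ENUMERATION = re.compile(r"^\s*(?:\d+\s*[.)]|[-*•])\s*")


def _clean_label(line: str) -> str:
    # Verbose responses sometimes echo the genes or "Row 1:" before the label;
    # keep only what follows the last colon.
    if ":" in line:
        line = line.rsplit(":", 1)[1]
    line = _ENUMERATION.sub("", line.strip())
    return line.strip().rstrip(".").strip()


def parse_annotation_response(raw: str, expected_n: int) -> AnnotationResponse:
    """Split a response into one label per marker row.

    Blank lines are dropped; enumeration prefixes (``1.``, ``1)``, ``-``,
    ``*``), any leading ``...:`` echo, and a trailing period are stripped.
    The cleaned line count must equal ``expected_n``.
    """
    if not raw or not raw.strip():
        raise ResponseParseError("empty response", raw_text=raw)
    labels = [_clean_label(line) for line in raw.splitlines() if line.strip()]
    labels = [lab for lab in labels if lab]
    if len(labels) != expected_n:
        raise ResponseParseError(
            f"expected {expected_n} labels but parsed {len(labels)} "
            f"from response: {raw!r}",
            raw_text=raw,
        )
    return AnnotationResponse(raw_text=raw, labels=tuple(labels))


_VECTOR = re.compile(
    r"c\(\s*('(?:[^'\\]|\\.)*'(?:\s*,\s*'(?:[^'\\]|\\.)*')*)\s*\)"
)
_ELEMENT = re.compile(r"'((?:[^'\\]|\\.)*)'")


def parse_vector_response(raw: str, expected_n: int) -> list[str]:
    """Extract labels from an R-style ``c('a','b',...)`` expression.

    The expression may be embedded in surrounding prose; escaped quotes
    (``\\'``) inside labels are unescaped.
    """
    match = _VECTOR.search(raw)
    if match is None:
        raise ResponseParseError(
            f"no c('...') vector expression found in response: {raw!r}",
            raw_text=raw,
        )
    labels = [m.replace("\\'", "'") for m in _ELEMENT.findall(match.group(1))]
    if len(labels) != expected_n:
        raise ResponseParseError(
            f"vector has {len(labels)} elements, expected {expected_n}",
            raw_text=raw,
        )
    return labels
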