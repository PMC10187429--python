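"""Text-completion backends: the conversation contract, deterministic offline
implementations (dictionary mock and transcript replay), response caching, and
a thin live-service adapter.

The mock dictionary is a test oracle standing in for the language model: it
annotates a marker row by gene-set overlap against a known dictionary. It makes
the whole pipeline testable offline and is not a biological annotator.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
import urllib.request
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Protocol

from .errors import BackendError, TranscriptMissError

logger = logging.getLogger(__name__)


@dataclass
class Conversation:
    """Alternating user/assistant turns; the first turn is always user."""

    turns: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        self._validate()

    def _validate(self) -> None:
        for i, (role, _) in enumerate(self.turns):
            expected = "user" if i % 2 == 0 else "assistant"
            if role != expected:
                raise ValueError(
                    f"turn {i} has role {role!r}, expected {expected!r}"
                )

    def append(self, role: str, text: str) -> None:
        self.turns.append((role, text))
        self._validate()

    def copy(self) -> "Conversation":
        return Conversation(turns=list(self.turns))

    def last_user_text(self) -> str:
        if not self.turns or self.turns[-1][0] != "user":
            raise ValueError("conversation must end with a user turn")
        return self.turns[-1][1]

    def last_assistant_text(self) -> str | None:
        for role, text in reversed(self.turns):
            if role == "assistant":
                return text
        return None

    def rendered(self) -> str:
        return "\x1e".join(f"{role}\x1f{text}" for role, text in self.turns)

    def digest(self) -> str:
        """Stable identity of the rendered conversation (prompt digest)."""
        return hashlib.sha256(self.rendered().encode("utf-8")).hexdigest()


@dataclass(frozen=True)
class BackendConfig:
    """Provenance snapshot of how responses were obtained.

    ``model_name`` records the model version (e.g. a dated chat-model release)
    so results stay attributable; mock and transcript backends ignore
    credentials entirely.
    """

    backend_kind: str = "mock_dictionary"
    model_name: str = "mock-overlap-v1"
    temperature: float = 0.0
    max_retries: int = 0
    cache_enabled: bool = True
    credential_source: str = ""

    def __post_init__(self):
        if self.backend_kind not in {"mock_dictionary", "transcript", "live"}:
            raise ValueError(f"unknown backend_kind {self.backend_kind!r}")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.max_retries < 0:
            raise ValueError("max_retries must be >= 0")
        if self.backend_kind == "live" and not self.credential_source:
            raise ValueError("live backend requires credential_source")


@dataclass
class MockDictionary:
    """Cell type -> marker gene set, the oracle the mock backend scores against."""

    entries: dict[str, frozenset[str]]
    unknown_label: str = "unknown cell type"
    mixture_format: str = "mixture of {a} and {b}"
    mixture_threshold: float = 0.5

    def __post_init__(self):
        self.entries = {name: frozenset(genes) for name, genes in self.entries.items()}
        if not all(self.entries.values()):
            raise ValueError("every dictionary cell type needs at least one gene")


def mock_annotate_rows(rows: Iterable[str], dictionary: MockDictionary) -> list[str]:
    """Annotate marker rows by overlap with the dictionary.

    Each cell type is scored as |row ∩ markers| / |markers| — normalising by
    the cell type's own marker-set size so a long row containing all of a small
    type's markers still matches it strongly. The best scorer wins (ties broken
    lexicographically); zero overlap everywhere yields the unknown label. When
    the best scorer and the best *disjoint* second type each reach the mixture
    threshold, a mixture of the two (names in lexicographic order) is emitted.
    """
    if not dictionary.entries:
        raise ValueError("mock dictionary is empty")
    labels = []
    for row in rows:
        genes = {g.strip() for g in row.split(",") if g.strip()}
        scores = {
            name: len(genes & markers) / len(markers)
            for name, markers in dictionary.entries.items()
        }
        best_name = min(scores, key=lambda n: (-scores[n], n))
        if scores[best_name] == 0:
            labels.append(dictionary.unknown_label)
            continue
        disjoint = {
            name: s
            for name, s in scores.items()
            if dictionary.entries[name].isdisjoint(dictionary.entries[best_name])
        }
        if disjoint:
            second = min(disjoint, key=lambda n: (-disjoint[n], n))
            if (
                scores[best_name] >= dictionary.mixture_threshold
                and scores[second] >= dictionary.mixture_threshold
            ):
                a, b = sorted((best_name, second))
                labels.append(dictionary.mixture_format.format(a=a, b=b))
                continue
        labels.append(best_name)
    return labels


class Backend(Protocol):
    def complete(self, conversation: Conversation) -> str: ...


def _looks_like_marker_row(line: str) -> bool:
    # Prompt header and clause sentences all end with a period; marker rows
    # are bare comma-joined symbols.
    stripped = line.strip()
    return bool(stripped) and not stripped.endswith(".")


class MockBackend:
    """Deterministic oracle backend driven by a :class:`MockDictionary`.

    Understands the three prompt kinds the pipeline issues: the initial
    annotation prompt (answered row by row from the dictionary), the
    refinement turn (answered by suffixing the previous labels), and the
    vector-conversion turn (answered with a ``c('...')`` expression).
    """

    def __init__(self, dictionary: MockDictionary, refinement_suffix: str = ", specific subtype"):
        self.dictionary = dictionary
        self.refinement_suffix = refinement_suffix
        self.call_count = 0

    def _previous_labels(self, conversation: Conversation) -> list[str]:
        text = conversation.last_assistant_text()
        if text is None:
            raise BackendError("no previous annotation to build on")
        return [line.strip() for line in text.splitlines() if line.strip()]

    def complete(self, conversation: Conversation) -> str:
        self.call_count += 1
        text = conversation.last_user_text()
        if text.strip() == "Be more specific":
            labels = self._previous_labels(conversation)
            return "\n".join(lab + self.refinement_suffix for lab in labels)
        if "concatenate all results" in text:
            labels = self._previous_labels(conversation)
            quoted = ",".join("'" + lab.replace("'", "\\'") + "'" for lab in labels)
            return f"c({quoted})"
        rows = [line for line in text.splitlines() if _looks_like_marker_row(line)]
        if not rows:
            raise BackendError("annotation prompt contains no marker rows")
        return "\n".join(mock_annotate_rows(rows, self.dictionary))


class TranscriptBackend:
    """Replay responses recorded in a JSON Lines transcript store."""

    def __init__(self, store: str | Path):
        self.store = Path(store)
        self._responses: dict[str, str] = {}
        if self.store.exists():
            for line in self.store.read_text().splitlines():
                if not line.strip():
                    continue
                rec = json.loads(line)
                self._responses[rec["digest"]] = rec["response"]

    def complete(self, conversation: Conversation) -> str:
        digest = conversation.digest()
        if digest not in self._responses:
            raise TranscriptMissError(digest)
        return self._responses[digest]


def record_transcript(
    conversation: Conversation,
    response: str,
    store: str | Path,
    model_name: str = "",
) -> None:
    """Append one exchange to a transcript store, keyed by conversation digest.

    Re-recording an identical pair is a no-op; a digest collision with
    different text is refused rather than silently overwritten.
    """
    store = Path(store)
    digest = conversation.digest()
    if store.exists():
        for line in store.read_text().splitlines():
            if not line.strip():
                continue
            rec = json.loads(line)
            if rec["digest"] == digest:
                if rec["response"] != response:
                    raise BackendError(
                        f"digest {digest} already recorded with different text"
                    )
                return
    record = {
        "digest": digest,
        "prompt": conversation.rendered(),
        "response": response,
        "model_name": model_name,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    with store.open("a") as fh:
        fh.write(json.dumps(record) + "\n")


class LiveBackend:
    """Adapter for an OpenAI-compatible chat-completions endpoint.

    Requires network access and a credential in the environment variable named
    by ``config.credential_source``; it is never exercised by the test suite.
    Because the original annotations were produced through a chat website,
    defaults here cannot claim fidelity to any particular historical run.
    """

    def __init__(self, config: BackendConfig, endpoint: str = "https://api.openai.com/v1/chat/completions"):
        self.config = config
        self.endpoint = endpoint
        key = os.environ.get(config.credential_source, "")
        if not key:
            raise BackendError(
                f"credential environment variable {config.credential_source!r} is not set"
            )
        self._key = key

    def complete(self, conversation: Conversation) -> str:
        payload = json.dumps(
            {
                "model": self.config.model_name,
                "temperature": self.config.temperature,
                "messages": [
                    {"role": role, "content": text}
                    for role, text in conversation.turns
                ],
            }
        ).encode("utf-8")
        last_error: Exception | None = None
        for attempt in range(self.config.max_retries + 1):
            req = urllib.request.Request(
                self.endpoint,
                data=payload,
                headers={
                    "Content-Type": "application/json",
                    "Authorization": f"Bearer {self._key}",
                },
            )
            try:
                with urllib.request.urlopen(req, timeout=120) as resp:
                    body = json.loads(resp.read().decode("utf-8"))
                logger.info(
                    "live completion ok (model=%s, id=%s)",
                    body.get("model"), body.get("id"),
                )
                return body["choices"][0]["message"]["content"]
            except Exception as exc:  # noqa: BLE001 - retried, then wrapped
                last_error = exc
                logger.warning("live backend attempt %d failed: %s", attempt + 1, exc)
        raise BackendError(
            f"live backend failed after {self.config.max_retries + 1} attempts"
        ) from last_error


class CachedBackend:
    """Wrap a backend with response caching on (digest, model, temperature).

    A stochastic configuration (temperature > 0) disables caching so repeated
    queries genuinely hit the backend. Caching never changes results, only the
    inner call count.
    """

    def __init__(self, inner: Backend, config: BackendConfig):
        self.inner = inner
        self.config = config
        self._cache: dict[tuple[str, str, float], str] = {}

    @property
    def enabled(self) -> bool:
        return self.config.cache_enabled and self.config.temperature == 0

    def complete(self, conversation: Conversation) -> str:
        if not self.enabled:
            return self.inner.complete(conversation)
        key = (conversation.digest(), self.config.model_name, self.config.temperature)
        if key not in self._cache:
            self._cache[key] = self.inner.complete(conversation)
        return self._cache[key]


def create_backend(
    config: BackendConfig,
    dictionary: MockDictionary | None = None,
    transcript_path: str | Path | None = None,
) -> Backend:
    """Instantiate the backend a config describes."""
    if config.backend_kind == "mock_dictionary":
        if dictionary is None:
            raise ValueError("mock_dictionary backend requires a dictionary")
        return MockBackend(dictionary)
    if config.backend_kind == "transcript":
        if transcript_path is None:
            raise ValueError("transcript backend requires a transcript_path")
        return TranscriptBackend(transcript_path)
    return LiveBackend(config)


def complete(conversation: Conversation, backend: Backend) -> str:
    """Single completion turn: the conversation must end with a user turn."""
    conversation.last_user_text()
    return backend.complete(conversation)
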