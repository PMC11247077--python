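"""Prompt construction and batched-response parsing for article generation.

Simulated abstracts are elicited from a generative model with a
parameterized prompt holding five fixed elements, in order: the role the
model should assume, the batched request, the topic, the required record
fields, and the word-range constraint — plus the instruction to answer with
valid JSON.  The generation client itself is a contract (send a prompt,
receive text) injected by the caller; tests use a canned-response fake, and
no live API is ever contacted by this package.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

from .corpus_io import Article, Corpus, CorpusValidationError, Label

logger = logging.getLogger(__name__)

REQUIRED_FIELDS = ("ID", "Title", "Abstract")


@dataclass(frozen=True)
class PromptSpec:
    """Parameters of one generation prompt."""

    topic: str
    role_text: str = "a biomedical researcher"
    request_text: str = "Generate a list of {batch_size} simulated PubMed-style abstracts"
    batch_size: int = 20
    word_range: tuple[int, int] = (200, 250)
    required_fields: tuple[str, ...] = REQUIRED_FIELDS

    def __post_init__(self) -> None:
        if not self.topic or not self.topic.strip():
            raise ValueError("topic must be non-empty")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        lo, hi = self.word_range
        if lo > hi:
            raise ValueError("word_range min exceeds max")
        missing = set(REQUIRED_FIELDS) - set(self.required_fields)
        if missing:
            raise ValueError(f"required_fields must include {sorted(missing)}")


class GenerationClient(Protocol):
    """Contract for a text-generation backend: prompt in, raw text out."""

    def complete(self, prompt: str) -> str: ...


@dataclass
class CannedClient:
    """Offline stand-in client replaying pre-built responses in order."""

    responses: Sequence[str]
    _cursor: int = field(default=0, init=False)

    def complete(self, prompt: str) -> str:
        if self._cursor >= len(self.responses):
            raise RuntimeError("canned client exhausted")
        out = self.responses[self._cursor]
        self._cursor += 1
        return out


def build_prompt(spec: PromptSpec) -> str:
    """Render the five prompt elements, in fixed order, as a single text."""
    lo, hi = spec.word_range
    article_word = "abstract" if spec.batch_size == 1 else "abstracts"
    request = spec.request_text.format(batch_size=spec.batch_size)
    if "{batch_size}" not in spec.request_text:
        request = f"{spec.request_text} ({spec.batch_size} {article_word})"
    fields = ", ".join(spec.required_fields)
    return (
        f"You are {spec.role_text}. "
        f"{request} "
        f"on the topic of {spec.topic}. "
        f"Each article must contain {fields} fields. "
        f"Each abstract must be between {lo} and {hi} words long. "
        f"Generate a valid JSON response: a JSON array of objects with exactly "
        f"those fields."
    )


def parse_generation_response(raw: str, spec: PromptSpec, source_tag: str = "") -> Corpus:
    """Parse one raw JSON response into a generated-class corpus.

    Raises on invalid JSON, a non-array payload, or a record missing any
    required field (the error names the field and record index).
    """
    try:
        data = json.loads(raw)
    except json.JSONDecodeError as exc:
        raise CorpusValidationError(f"response is not valid JSON: {exc}") from exc
    if not isinstance(data, list):
        raise CorpusValidationError("response must be a JSON array of records")
    if not data:
        logger.warning("generation response contained an empty array")
    articles = []
    for i, rec in enumerate(data):
        if not isinstance(rec, dict):
            raise CorpusValidationError(f"record {i}: expected an object", index=i)
        for fname in spec.required_fields:
            if fname not in rec or not str(rec[fname]).strip():
                raise CorpusValidationError(
                    f"record {i}: missing required field {fname!r}", index=i
                )
        articles.append(
            Article(
                id=str(rec["ID"]),
                title=str(rec["Title"]),
                abstract=str(rec["Abstract"]),
                label=Label.GPT,
            )
        )
    return Corpus(tuple(articles), source_tag=source_tag)


def accumulate_batches(
    batches: Sequence[Corpus], query: str = ""
) -> tuple[Corpus, dict[str, int]]:
    """Concatenate generation batches in order, with manifest accounting.

    Colliding ids across batches are re-namespaced by batch index (with a
    warning) so all articles are retained.  The manifest maps the query to
    the total record count.
    """
    seen: set[str] = set()
    articles: list[Article] = []
    for b_idx, batch in enumerate(batches):
        for a in batch:
            if a.id in seen:
                new_id = f"batch{b_idx}:{a.id}"
                logger.warning("duplicate id %r re-namespaced to %r", a.id, new_id)
                a = Article(id=new_id, title=a.title, abstract=a.abstract,
                            label=a.label, period=a.period)
            seen.add(a.id)
            articles.append(a)
    corpus = Corpus(tuple(articles), source_tag=query or "accumulated")
    manifest = {query or "total": len(articles)}
    return corpus, manifest


def generate_corpus(
    spec: PromptSpec,
    client: GenerationClient,
    n_batches: int,
    query: str = "",
) -> tuple[Corpus, dict[str, int]]:
    """Drive the injected client for ``n_batches`` rounds and accumulate."""
    prompt = build_prompt(spec)
    batches = [
        parse_generation_response(client.complete(prompt), spec,
                                  source_tag=f"batch-{i}")
        for i in range(n_batches)
    ]
    return accumulate_batches(batches, query=query or spec.topic)
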