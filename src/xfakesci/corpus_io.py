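"""Reading, writing, filtering and partitioning of article corpora.

An article corpus is a flat list of short records — id, title, abstract,
class label, optional publication-period tag — stored as a JSON array or as
JSON-Lines.  Downstream stages consume a :class:`SplitPlan` that carves a
corpus into a training block (first ``n_train`` articles), sequential
calibration folds of exactly ``fold_size`` articles, and whatever trailing
articles do not fill a fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence


class Label(str, Enum):
    """Class label of an article: genuine publication, generated text, or unknown."""

    PUBMED = "PUBMED"
    GPT = "GPT"
    UNKNOWN = "UNKNOWN"


class CorpusValidationError(ValueError):
    """A record failed schema validation; carries the offending record index."""

    def __init__(self, message: str, index: int | None = None):
        super().__init__(message)
        self.index = index


@dataclass(frozen=True)
class Article:
    """One bibliographic record: the atomic input of the pipeline."""

    id: str
    title: str
    abstract: str
    label: Label = Label.UNKNOWN
    period: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise CorpusValidationError("article id must be non-empty")


@dataclass(frozen=True)
class Corpus:
    """An ordered, id-unique collection of articles."""

    articles: tuple[Article, ...]
    source_tag: str = ""

    def __post_init__(self) -> None:
        ids = [a.id for a in self.articles]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            for i, aid in enumerate(ids):
                if aid in seen:
                    raise CorpusValidationError(
                        f"duplicate article id {aid!r} at position {i}", index=i
                    )
                seen.add(aid)

    def __len__(self) -> int:
        return len(self.articles)

    def __iter__(self) -> Iterator[Article]:
        return iter(self.articles)

    def __getitem__(self, i: int) -> Article:
        return self.articles[i]

    def with_label(self, label: Label) -> "Corpus":
        """Return a copy with every article relabelled."""
        return Corpus(tuple(replace(a, label=label) for a in self.articles), self.source_tag)


@dataclass(frozen=True)
class SplitPlan:
    """Sequential partition of a corpus into train / calibration folds / leftover.

    ``train`` holds the first ``n_train`` articles; the remainder is chunked
    in file order into folds of exactly ``fold_size``; a trailing partial
    chunk is kept aside in ``leftover`` (it is excluded from calibration so
    every fold mean averages the same number of documents).
    """

    train: tuple[Article, ...]
    folds: tuple[tuple[Article, ...], ...]
    leftover: tuple[Article, ...]
    n_train: int
    fold_size: int


# JSON field names are case-tolerant: generation output casing is not pinned.
_FIELD_ALIASES = {
    "id": ("ID", "Id", "id"),
    "title": ("Title", "title"),
    "abstract": ("Abstract", "abstract"),
    "label": ("Label", "label"),
    "period": ("Period", "period"),
}


def _get_field(record: dict, name: str):
    for alias in _FIELD_ALIASES[name]:
        if alias in record:
            return record[alias]
    return None


def article_from_record(record: dict, index: int) -> Article:
    """Validate one raw JSON object and build an :class:`Article`.

    Raises :class:`CorpusValidationError` naming the record index when a
    mandatory field (id, title, abstract) is missing or empty.
    """
    if not isinstance(record, dict):
        raise CorpusValidationError(f"record {index}: expected an object", index=index)
    rid = _get_field(record, "id")
    title = _get_field(record, "title")
    abstract = _get_field(record, "abstract")
    for fname, value in (("ID", rid), ("Title", title), ("Abstract", abstract)):
        if value is None or (isinstance(value, str) and not value.strip()):
            raise CorpusValidationError(
                f"record {index}: missing or empty field {fname!r}", index=index
            )
    raw_label = _get_field(record, "label")
    label = Label(raw_label) if raw_label in {l.value for l in Label} else Label.UNKNOWN
    period = _get_field(record, "period")
    return Article(
        id=str(rid),
        title=str(title),
        abstract=str(abstract),
        label=label,
        period=str(period) if period is not None else None,
    )


def read_articles(path: str | Path, format: str | None = None, source_tag: str = "") -> Corpus:
    """Read a corpus from a JSON array file or a JSON-Lines file.

    Parameters
    ----------
    path
        File to read.
    format
        ``"json"`` (top-level array of objects) or ``"jsonl"`` (one object
        per line).  When omitted, inferred from the file suffix
        (``.jsonl``/``.ndjson`` -> jsonl, otherwise json).
    source_tag
        Stored on the corpus for provenance; defaults to the file name.
    """
    path = Path(path)
    if format is None:
        format = "jsonl" if path.suffix.lower() in {".jsonl", ".ndjson"} else "json"
    if format not in {"json", "jsonl"}:
        raise ValueError(f"unknown corpus format {format!r}")

    if format == "json":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        if not isinstance(data, list):
            raise CorpusValidationError("JSON corpus must be a top-level array")
        records = data
    else:
        records = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh):
                line = line.strip()
                if not line:
                    continue
                try:
                    records.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    raise CorpusValidationError(
                        f"line {lineno}: invalid JSON: {exc}", index=lineno
                    ) from exc

    articles = tuple(article_from_record(rec, i) for i, rec in enumerate(records))
    return Corpus(articles, source_tag or path.name)


def write_articles(corpus: Corpus, path: str | Path, format: str | None = None) -> None:
    """Write a corpus as a JSON array or JSON-Lines, preserving order."""
    path = Path(path)
    if format is None:
        format = "jsonl" if path.suffix.lower() in {".jsonl", ".ndjson"} else "json"
    records = [_article_to_record(a) for a in corpus]
    with open(path, "w", encoding="utf-8") as fh:
        if format == "json":
            json.dump(records, fh, indent=1)
            fh.write("\n")
        elif format == "jsonl":
            for rec in records:
                fh.write(json.dumps(rec) + "\n")
        else:
            raise ValueError(f"unknown corpus format {format!r}")


def _article_to_record(a: Article) -> dict:
    rec = {"ID": a.id, "Title": a.title, "Abstract": a.abstract}
    if a.label is not Label.UNKNOWN:
        rec["Label"] = a.label.value
    if a.period is not None:
        rec["Period"] = a.period
    return rec


def split_corpus(
    corpus: Corpus | Sequence[Article], n_train: int, fold_size: int
) -> SplitPlan:
    """Partition a corpus into train block, sequential folds, and leftover.

    The first ``n_train`` articles form the training block; the rest are
    chunked in order into folds of exactly ``fold_size``.  A trailing chunk
    shorter than ``fold_size`` goes to ``leftover``.

    Raises
    ------
    ValueError
        If the corpus holds fewer than ``n_train + fold_size`` articles
        (no full calibration fold could be formed).
    """
    if n_train <= 0 or fold_size <= 0:
        raise ValueError("n_train and fold_size must be positive")
    articles = tuple(corpus)
    if len(articles) < n_train + fold_size:
        raise ValueError(
            f"corpus of {len(articles)} articles cannot supply "
            f"{n_train} training articles plus one fold of {fold_size}"
        )
    train = articles[:n_train]
    rest = articles[n_train:]
    n_folds = len(rest) // fold_size
    folds = tuple(
        rest[i * fold_size : (i + 1) * fold_size] for i in range(n_folds)
    )
    leftover = rest[n_folds * fold_size :]
    return SplitPlan(train=train, folds=folds, leftover=leftover,
                     n_train=n_train, fold_size=fold_size)


def filter_by_period(corpus: Corpus, period: str | None) -> Corpus:
    """Keep only articles whose period tag equals ``period`` (order preserved).

    ``period=None`` returns the input unchanged; an empty result is allowed.
    Periods are opaque metadata tags (e.g. ``"2010-2014"``), not parsed dates.
    """
    if period is None:
        return corpus
    return Corpus(
        tuple(a for a in corpus if a.period == period),
        source_tag=corpus.source_tag,
    )


def concat_corpora(corpora: Iterable[Corpus], source_tag: str = "") -> Corpus:
    """Concatenate corpora in order (ids must stay unique)."""
    articles: list[Article] = []
    for c in corpora:
        articles.extend(c.articles)
    return Corpus(tuple(articles), source_tag)
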