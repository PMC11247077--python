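"""Bigram TF-IDF scoring and selection.

The scoring follows the printed formulation exactly:

    tf(t, d)     = occurrences of bigram t in d / total bigram occurrences in d
    idf(t, D)    = ln( N / (1 + df(t, D)) )
    tf-idf(t, d) = tf(t, d) * idf(t, D)

with N the number of documents and df the number of documents containing t.
Note the ``1 + df`` smoothing in the denominator only: idf can be negative
(e.g. a bigram present in every document of a single-document set scores
ln(1/2)).  That behaviour is kept deliberately; ``idf_floor_at_zero``
clamps it for callers who prefer the conventional non-negative variant.

Selection keeps bigrams with document frequency >= ``min_df`` (default 2,
suppressing hapax noise) and optionally the ``top_k`` by best per-document
tf-idf, ordered deterministically (score descending, then lexicographic).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from .preprocess import Bigram, TokenizedDoc, consecutive_bigrams


@dataclass(frozen=True)
class FeatureConfig:
    min_df: int = 2
    top_k: int | None = None
    idf_floor_at_zero: bool = False
    sentence_scope_bigrams: bool = True


DEFAULT_FEATURE_CONFIG = FeatureConfig()


@dataclass(frozen=True)
class BigramEntry:
    """Scores of one bigram across the document set."""

    bigram: Bigram
    df: int
    idf: float
    tf: tuple[float, ...]       # per document, in input order
    tfidf: tuple[float, ...]    # per document, in input order

    @property
    def max_tfidf(self) -> float:
        return max(self.tfidf)


@dataclass(frozen=True)
class BigramTable:
    """Selected bigrams with their scores; seeds term-graph construction.

    ``entries`` is ordered by descending best per-document tf-idf, ties
    broken lexicographically, so identical corpora and configs always
    produce identical tables.
    """

    entries: tuple[BigramEntry, ...]
    n_documents: int

    def __len__(self) -> int:
        return len(self.entries)

    def bigrams(self) -> list[Bigram]:
        return [e.bigram for e in self.entries]

    def as_dict(self) -> dict[Bigram, BigramEntry]:
        return {e.bigram: e for e in self.entries}


def term_frequency(t: Bigram, d: TokenizedDoc, sentence_scope: bool = True) -> float:
    """Occurrences of bigram ``t`` in ``d`` over total bigram occurrences in ``d``."""
    stream = consecutive_bigrams(d, sentence_scope=sentence_scope)
    if not stream:
        raise ValueError(f"document {d.article_id!r} has no bigram occurrences")
    return stream.count(t) / len(stream)


def document_frequency(t: Bigram, docs: Sequence[TokenizedDoc],
                       sentence_scope: bool = True) -> int:
    """Number of documents whose bigram stream contains ``t``."""
    return sum(1 for d in docs if t in set(consecutive_bigrams(d, sentence_scope)))


def inverse_document_frequency(
    t: Bigram | None,
    docs: Sequence[TokenizedDoc] | None = None,
    *,
    n_documents: int | None = None,
    df: int | None = None,
    floor_at_zero: bool = False,
    sentence_scope: bool = True,
) -> float:
    """idf(t, D) = ln(N / (1 + df(t, D))); may be negative.

    Either pass the bigram and the document set, or ``n_documents`` and
    ``df`` directly.
    """
    if df is None or n_documents is None:
        if docs is None or t is None:
            raise ValueError("pass (t, docs) or (n_documents=, df=)")
        n_documents = len(docs)
        df = document_frequency(t, docs, sentence_scope)
    if n_documents < 1:
        raise ValueError("document set must be non-empty")
    value = math.log(n_documents / (1 + df))
    return max(0.0, value) if floor_at_zero else value


def tfidf_bigrams(
    training_docs: Sequence[TokenizedDoc],
    config: FeatureConfig = DEFAULT_FEATURE_CONFIG,
) -> BigramTable:
    """Score every bigram of the training documents and select the table.

    Raises on an empty document set or when no document yields a bigram.
    Documents with no bigram occurrences contribute tf = 0 for all terms.
    """
    if not training_docs:
        raise ValueError("training document set is empty")
    n = len(training_docs)
    streams = [
        consecutive_bigrams(d, sentence_scope=config.sentence_scope_bigrams)
        for d in training_docs
    ]
    if not any(streams):
        raise ValueError("no document contains a bigram occurrence")

    per_doc_counts: list[Counter] = [Counter(s) for s in streams]
    per_doc_totals = [len(s) for s in streams]
    df_counter: Counter = Counter()
    for counts in per_doc_counts:
        df_counter.update(counts.keys())

    entries: list[BigramEntry] = []
    for bigram, df in df_counter.items():
        if df < config.min_df:
            continue
        idf = inverse_document_frequency(
            None, n_documents=n, df=df, floor_at_zero=config.idf_floor_at_zero
        )
        tf = tuple(
            (per_doc_counts[i][bigram] / per_doc_totals[i]) if per_doc_totals[i] else 0.0
            for i in range(n)
        )
        tfidf = tuple(v * idf for v in tf)
        entries.append(BigramEntry(bigram=bigram, df=df, idf=idf, tf=tf, tfidf=tfidf))

    entries.sort(key=lambda e: (-e.max_tfidf, e.bigram))
    if config.top_k is not None:
        entries = entries[: config.top_k]
    return BigramTable(entries=tuple(entries), n_documents=n)
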