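"""Text normalisation: sentence tokenization, stopword removal, bigram streams.

Abstracts are lowercased, split into sentences, stripped of punctuation and
stopwords, and turned into streams of consecutive word pairs (bigrams).
Bigrams never cross sentence boundaries by default, since sentence
tokenization precedes pairing.  The pre-stopword token count is kept as
``raw_word_count`` because the calibration ratio divides bigram matches by
the total number of words of the article.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._stopwords import ENGLISH_STOPWORDS
from .corpus_io import Article

Bigram = tuple[str, str]

_SENTENCE_SPLIT = re.compile(r"(?<=[.!?;])\s+")
_WORD = re.compile(r"[a-z0-9][a-z0-9'\-]*")


@dataclass(frozen=True)
class PreprocessConfig:
    """Tokenizer settings.

    Attributes
    ----------
    stopwords : frozenset of str
        Words removed from content tokens (standard English list by default).
    lowercase : bool
        Case-fold before tokenizing so bigram identity is surface-form stable.
    sentence_scope_bigrams : bool
        When True, word pairs never span a sentence boundary.
    word_count_mode : str
        ``"raw"`` divides calibration ratios by the pre-stopword token count;
        ``"content"`` divides by the post-stopword count.
    """

    stopwords: frozenset[str] = ENGLISH_STOPWORDS
    lowercase: bool = True
    sentence_scope_bigrams: bool = True
    word_count_mode: str = "raw"

    def __post_init__(self) -> None:
        if self.word_count_mode not in {"raw", "content"}:
            raise ValueError("word_count_mode must be 'raw' or 'content'")


DEFAULT_CONFIG = PreprocessConfig()


@dataclass(frozen=True)
class TokenizedDoc:
    """A tokenized article: sentences of content tokens plus word counts."""

    article_id: str
    sentences: tuple[tuple[str, ...], ...]
    raw_word_count: int

    @property
    def content_tokens(self) -> tuple[str, ...]:
        return tuple(tok for sent in self.sentences for tok in sent)

    @property
    def content_word_count(self) -> int:
        return sum(len(s) for s in self.sentences)

    def word_count(self, mode: str = "raw") -> int:
        if mode == "raw":
            return self.raw_word_count
        if mode == "content":
            return self.content_word_count
        raise ValueError("mode must be 'raw' or 'content'")


def tokenize_text(
    text: str, config: PreprocessConfig = DEFAULT_CONFIG, article_id: str = ""
) -> TokenizedDoc:
    """Tokenize raw text into sentence-scoped content tokens.

    The text is (optionally) lowercased, split into sentences on terminal
    punctuation, reduced to word tokens with punctuation stripped, and
    filtered against the stopword list.  ``raw_word_count`` counts word
    tokens *before* stopword removal.
    """
    if not text or not text.strip():
        raise ValueError(f"empty text for article {article_id!r}")
    if config.lowercase:
        text = text.lower()
    sentences: list[tuple[str, ...]] = []
    raw_count = 0
    for raw_sentence in _SENTENCE_SPLIT.split(text):
        words = _WORD.findall(raw_sentence if config.lowercase else raw_sentence.lower())
        if not words:
            continue
        raw_count += len(words)
        content = tuple(w for w in words if w not in config.stopwords)
        sentences.append(content)
    return TokenizedDoc(article_id=article_id, sentences=tuple(sentences),
                        raw_word_count=raw_count)


def tokenize_document(
    article: Article, config: PreprocessConfig = DEFAULT_CONFIG
) -> TokenizedDoc:
    """Tokenize an article's abstract (see :func:`tokenize_text`)."""
    if not article.abstract or not article.abstract.strip():
        raise ValueError(f"article {article.id!r} has an empty abstract")
    return tokenize_text(article.abstract, config, article_id=article.id)


def tokenize_corpus(
    articles: Iterable[Article], config: PreprocessConfig = DEFAULT_CONFIG
) -> list[TokenizedDoc]:
    return [tokenize_document(a, config) for a in articles]


def consecutive_bigrams(
    doc: TokenizedDoc, sentence_scope: bool = True
) -> list[Bigram]:
    """Ordered stream of consecutive content-word pairs of a document.

    Each sentence of L content tokens contributes L-1 pairs; pairs do not
    span sentence boundaries unless ``sentence_scope`` is False, in which
    case the flattened token stream is paired document-wide.
    """
    if sentence_scope:
        return [
            (sent[i], sent[i + 1])
            for sent in doc.sentences
            for i in range(len(sent) - 1)
        ]
    toks = doc.content_tokens
    return [(toks[i], toks[i + 1]) for i in range(len(toks) - 1)]
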