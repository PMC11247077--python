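"""Calibration: per-document contribution ratios, fold means, class bounds.

The bigram-contribution ratio of a document against a class model is the
number of its consecutive-bigram occurrences whose edge lies in the class's
LCC, divided by the document's word count.  Fold means of this ratio over
sequential 100-article folds give each class a data-driven [lower, upper]
band — the min and max of the fold means — used at prediction time as the
range-membership test and, outside both ranges, as endpoints for the
proximity distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean
from typing import Sequence

from .network import LCCModel
from .preprocess import TokenizedDoc, consecutive_bigrams


@dataclass(frozen=True)
class FoldRatioReport:
    """Per-document ratios of one calibration fold and their mean."""

    class_label: str
    fold_index: int
    per_document_ratios: tuple[float, ...]
    fold_mean: float


@dataclass(frozen=True)
class CalibrationRange:
    """[lower, upper] band of a class: min and max of its fold means."""

    class_label: str
    lower: float
    upper: float
    n_folds: int

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")

    def contains(self, point: float) -> bool:
        return self.lower <= point <= self.upper

    @property
    def center(self) -> float:
        return (self.lower + self.upper) / 2


def doc_lcc_ratio(
    doc: TokenizedDoc,
    model: LCCModel,
    *,
    match_mode: str = "edge",
    unique_matches: bool = False,
    word_count_mode: str = "raw",
    sentence_scope: bool = True,
) -> float:
    """Bigram-contribution ratio of one document against a class LCC.

    Parameters
    ----------
    match_mode
        ``"edge"`` counts a bigram when its edge is present in the LCC
        (strict network reading, the default); ``"nodes"`` when both its
        words are LCC nodes.
    unique_matches
        Count each distinct matching bigram once instead of per occurrence.
    word_count_mode
        Denominator: ``"raw"`` (pre-stopword word count, default) or
        ``"content"``.
    """
    n_words = doc.word_count(word_count_mode)
    if n_words < 1:
        raise ValueError(f"document {doc.article_id!r} has zero words")
    if match_mode == "edge":
        matches = model.contains_edge
    elif match_mode == "nodes":
        matches = model.contains_nodes
    else:
        raise ValueError("match_mode must be 'edge' or 'nodes'")
    stream = consecutive_bigrams(doc, sentence_scope=sentence_scope)
    if unique_matches:
        stream = list(dict.fromkeys(stream))
    n_matching = sum(1 for b in stream if matches(b))
    return n_matching / n_words


def fold_ratio_mean(
    fold: Sequence[TokenizedDoc],
    model: LCCModel,
    fold_index: int = 0,
    **ratio_kwargs,
) -> FoldRatioReport:
    """Per-document ratios of one fold and their arithmetic mean."""
    if not fold:
        raise ValueError("calibration fold is empty")
    ratios = tuple(doc_lcc_ratio(d, model, **ratio_kwargs) for d in fold)
    return FoldRatioReport(
        class_label=model.class_label,
        fold_index=fold_index,
        per_document_ratios=ratios,
        fold_mean=fmean(ratios),
    )


def calibrate_ranges(
    reports: Sequence[FoldRatioReport] | Sequence[float],
    class_label: str | None = None,
) -> CalibrationRange:
    """Class bounds from fold means: lower = min, upper = max.

    Accepts either fold reports (all of one class) or bare fold means with
    an explicit ``class_label``.
    """
    if not reports:
        raise ValueError("at least one fold report is required")
    if isinstance(reports[0], FoldRatioReport):
        labels = {r.class_label for r in reports}  # type: ignore[union-attr]
        if len(labels) > 1:
            raise ValueError(f"fold reports mix classes: {sorted(labels)}")
        label = class_label or labels.pop()
        means = [r.fold_mean for r in reports]  # type: ignore[union-attr]
    else:
        if class_label is None:
            raise ValueError("class_label required when passing bare fold means")
        label = class_label
        means = [float(m) for m in reports]  # type: ignore[arg-type]
    return CalibrationRange(
        class_label=label, lower=min(means), upper=max(means), n_folds=len(means)
    )
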