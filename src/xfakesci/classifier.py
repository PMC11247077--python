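"""Multi-mode label prediction: range membership first, proximity fallback.

For a test document the classifier computes one ratio ("point") per class —
the document's bigram-contribution ratio against that class's LCC model —
and decides:

1. exactly one class's calibration range contains its point -> that label;
2. both ranges contain their points -> the class whose range center is
   nearer its point (a case the original ranges never produce, since the
   published bands do not overlap);
3. neither -> the class with the smaller boundary distance
   min(|point - lower|, |point - upper|), i.e. proximity;
4. exact distance ties -> a configurable tie policy, defaulting to the
   publication label (conservative toward not flagging real science).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .calibration import CalibrationRange, doc_lcc_ratio
from .corpus_io import Corpus, Label
from .network import LCCModel
from .preprocess import PreprocessConfig, DEFAULT_CONFIG, TokenizedDoc, tokenize_document

logger = logging.getLogger(__name__)

DecisionPath = str  # {"single_range", "both_ranges", "proximity", "tie_break"}


@dataclass(frozen=True)
class Prediction:
    """Full audit trail of one classification decision."""

    article_id: str
    point: dict[str, float]          # per-class contribution ratio
    in_range: dict[str, bool]
    distance: dict[str, float]       # per-class boundary distance
    predicted_label: str
    decision_path: DecisionPath


def boundary_distance(point: float, range_: CalibrationRange) -> float:
    """Distance from a point to a calibration range; 0 inside the range."""
    if range_.contains(point):
        return 0.0
    return min(abs(point - range_.upper), abs(point - range_.lower))


def decide_label(
    points: Mapping[str, float],
    ranges: Mapping[str, CalibrationRange],
    tie_policy: str = Label.PUBMED.value,
) -> tuple[str, DecisionPath, dict[str, bool], dict[str, float]]:
    """Apply the multi-mode decision rule to per-class points.

    Returns (label, decision_path, in_range flags, boundary distances).
    """
    labels = sorted(points)
    if sorted(ranges) != labels or len(labels) != 2:
        raise ValueError("exactly two classes, each with a point and a range, required")
    in_range = {c: ranges[c].contains(points[c]) for c in labels}
    distance = {c: boundary_distance(points[c], ranges[c]) for c in labels}
    inside = [c for c in labels if in_range[c]]

    if len(inside) == 1:
        return inside[0], "single_range", in_range, distance
    if len(inside) == 2:
        center_gap = {c: abs(points[c] - ranges[c].center) for c in labels}
        a, b = labels
        if center_gap[a] == center_gap[b]:
            logger.warning("both-ranges center-distance tie; using policy %s", tie_policy)
            return tie_policy, "tie_break", in_range, distance
        winner = a if center_gap[a] < center_gap[b] else b
        return winner, "both_ranges", in_range, distance
    # neither in range: proximity (Eq. min over the two datasets' distances)
    a, b = labels
    if distance[a] == distance[b]:
        logger.warning("proximity tie at distance %s; using policy %s",
                       distance[a], tie_policy)
        return tie_policy, "tie_break", in_range, distance
    winner = a if distance[a] < distance[b] else b
    return winner, "proximity", in_range, distance


def classify_document(
    doc: TokenizedDoc,
    models: Mapping[str, LCCModel],
    ranges: Mapping[str, CalibrationRange],
    tie_policy: str = Label.PUBMED.value,
    **ratio_kwargs,
) -> Prediction:
    """Classify one tokenized document against two class models + ranges."""
    if sorted(models) != sorted(ranges) or len(models) != 2:
        raise ValueError("need exactly two classes with both a model and a range")
    points = {c: doc_lcc_ratio(doc, models[c], **ratio_kwargs) for c in models}
    label, path, in_range, distance = decide_label(points, ranges, tie_policy)
    return Prediction(
        article_id=doc.article_id,
        point=points,
        in_range=in_range,
        distance=distance,
        predicted_label=label,
        decision_path=path,
    )


def classify_single_mode(
    doc: TokenizedDoc,
    model: LCCModel,
    range_: CalibrationRange,
    **ratio_kwargs,
) -> tuple[bool, float]:
    """Single-mode variant: one class, one band, an in/out decision.

    Returns (in_range, point).  Carries no proximity fallback — the
    trivial counterpart of the multi-mode rule, exposed for completeness.
    """
    point = doc_lcc_ratio(doc, model, **ratio_kwargs)
    return range_.contains(point), point


def classify_corpus(
    test: Corpus,
    models: Mapping[str, LCCModel],
    ranges: Mapping[str, CalibrationRange],
    tie_policy: str = Label.PUBMED.value,
    preprocess: PreprocessConfig = DEFAULT_CONFIG,
    **ratio_kwargs,
) -> list[Prediction]:
    """Classify every article of a corpus, input order preserved."""
    predictions: list[Prediction] = []
    for article in test:
        try:
            doc = tokenize_document(article, preprocess)
            predictions.append(
                classify_document(doc, models, ranges, tie_policy, **ratio_kwargs)
            )
        except ValueError as exc:
            raise ValueError(f"article {article.id!r}: {exc}") from exc
    return predictions
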