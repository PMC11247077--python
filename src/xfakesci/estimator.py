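"""scikit-learn-style estimator wrapping the full training/prediction pipeline.

``XFakeSciClassifier.fit`` consumes raw abstract texts with class labels,
and per class: tokenizes, scores bigrams with the package's TF-IDF variant,
builds the term graph, prunes to the largest connected component, and
calibrates the [lower, upper] ratio band from sequential folds.  ``predict``
applies the multi-mode decision rule (range membership, then proximity).

The estimator composes with sklearn model selection and pipelines; the
module-level functions of :mod:`xfakesci.classifier` and friends are the
underlying operations.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .calibration import calibrate_ranges, fold_ratio_mean
from .classifier import Prediction, classify_document
from .corpus_io import Article, Label
from .features import FeatureConfig, tfidf_bigrams
from .network import build_term_graph, largest_connected_component
from .preprocess import PreprocessConfig, TokenizedDoc, tokenize_text
from ._stopwords import ENGLISH_STOPWORDS


def _as_text(x) -> str:
    if isinstance(x, Article):
        return x.abstract
    if isinstance(x, TokenizedDoc):
        raise TypeError("pass raw text or Article; tokenization is internal")
    return str(x)


class XFakeSciClassifier(BaseEstimator, ClassifierMixin):
    """Network-driven two-class detector of machine-generated abstracts.

    Per class the first ``n_train`` documents (in input order) build the
    bigram term graph whose largest connected component is the trained
    model; the remaining documents are chunked into sequential calibration
    folds of ``fold_size``, and the min/max of the fold means of the
    bigram-contribution ratio form the class's acceptance band.  A partial
    trailing fold is dropped so every fold mean averages the same number of
    documents.

    Parameters
    ----------
    n_train : int, default=100
        Training documents per class (graph construction).
    fold_size : int, default=100
        Documents per calibration fold.
    min_df : int, default=2
        Minimum document frequency for a bigram to enter the term graph.
    top_k : int or None, default=None
        Optional cap on the number of selected bigrams (best tf-idf first).
    idf_floor_at_zero : bool, default=False
        Clamp negative idf values (the printed formulation allows them).
    word_count_mode : {"raw", "content"}, default="raw"
        Ratio denominator: words before or after stopword removal.
    match_mode : {"edge", "nodes"}, default="edge"
        A bigram contributes when its edge is in the LCC, or merely when
        both its words are LCC nodes.
    unique_matches : bool, default=False
        Count each distinct matching bigram once instead of per occurrence.
    sentence_scope_bigrams : bool, default=True
        Bigrams never cross sentence boundaries.
    lowercase : bool, default=True
    tie_policy : str, default="PUBMED"
        Label returned on exact decision ties.
    positive_label : str, default="PUBMED"
        Class reported as positive by downstream evaluation.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Sorted class labels seen in ``fit``.
    models_ : dict
        Per-class :class:`~xfakesci.network.LCCModel`.
    ranges_ : dict
        Per-class :class:`~xfakesci.calibration.CalibrationRange`.
    fold_reports_ : dict
        Per-class list of :class:`~xfakesci.calibration.FoldRatioReport`.
    n_leftover_ : dict
        Per-class count of articles dropped from a partial trailing fold.
    """

    def __init__(
        self,
        n_train: int = 100,
        fold_size: int = 100,
        min_df: int = 2,
        top_k: int | None = None,
        idf_floor_at_zero: bool = False,
        word_count_mode: str = "raw",
        match_mode: str = "edge",
        unique_matches: bool = False,
        sentence_scope_bigrams: bool = True,
        lowercase: bool = True,
        tie_policy: str = Label.PUBMED.value,
        positive_label: str = Label.PUBMED.value,
    ):
        self.n_train = n_train
        self.fold_size = fold_size
        self.min_df = min_df
        self.top_k = top_k
        self.idf_floor_at_zero = idf_floor_at_zero
        self.word_count_mode = word_count_mode
        self.match_mode = match_mode
        self.unique_matches = unique_matches
        self.sentence_scope_bigrams = sentence_scope_bigrams
        self.lowercase = lowercase
        self.tie_policy = tie_policy
        self.positive_label = positive_label

    # -- config plumbing -------------------------------------------------
    def _preprocess_config(self) -> PreprocessConfig:
        return PreprocessConfig(
            stopwords=ENGLISH_STOPWORDS,
            lowercase=self.lowercase,
            sentence_scope_bigrams=self.sentence_scope_bigrams,
            word_count_mode=self.word_count_mode,
        )

    def _feature_config(self) -> FeatureConfig:
        return FeatureConfig(
            min_df=self.min_df,
            top_k=self.top_k,
            idf_floor_at_zero=self.idf_floor_at_zero,
            sentence_scope_bigrams=self.sentence_scope_bigrams,
        )

    def _ratio_kwargs(self) -> dict:
        return dict(
            match_mode=self.match_mode,
            unique_matches=self.unique_matches,
            word_count_mode=self.word_count_mode,
            sentence_scope=self.sentence_scope_bigrams,
        )

    def _tokenize(self, x, i: int) -> TokenizedDoc:
        doc_id = x.id if isinstance(x, Article) else f"doc-{i}"
        return tokenize_text(_as_text(x), self._preprocess_config(), article_id=doc_id)

    # -- sklearn API ------------------------------------------------------
    def fit(self, X: Sequence, y: Sequence) -> "XFakeSciClassifier":
        """Train per-class LCC models and calibration ranges.

        ``X`` is a sequence of abstract texts (or ``Article`` objects); ``y``
        the corresponding class labels.  Exactly two classes are required,
        each with at least ``n_train + fold_size`` documents; input order is
        significant (the first ``n_train`` per class train the graph).
        """
        y = np.asarray([str(label) for label in y], dtype=object)
        if len(y) != len(X):
            raise ValueError("X and y have different lengths")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"exactly two classes required, got {list(self.classes_)}"
            )
        docs = [self._tokenize(x, i) for i, x in enumerate(X)]

        self.models_ = {}
        self.ranges_ = {}
        self.fold_reports_ = {}
        self.n_leftover_ = {}
        fc = self._feature_config()
        rk = self._ratio_kwargs()
        for cls in self.classes_:
            cls_docs = [d for d, label in zip(docs, y) if label == cls]
            if len(cls_docs) < self.n_train + self.fold_size:
                raise ValueError(
                    f"class {cls!r} has {len(cls_docs)} documents; needs at least "
                    f"n_train + fold_size = {self.n_train + self.fold_size}"
                )
            train = cls_docs[: self.n_train]
            rest = cls_docs[self.n_train:]
            n_folds = len(rest) // self.fold_size
            folds = [
                rest[i * self.fold_size: (i + 1) * self.fold_size]
                for i in range(n_folds)
            ]
            self.n_leftover_[cls] = len(rest) - n_folds * self.fold_size

            table = tfidf_bigrams(train, fc)
            graph = build_term_graph(table, class_label=cls)
            model = largest_connected_component(graph)
            reports = [
                fold_ratio_mean(fold, model, fold_index=i, **rk)
                for i, fold in enumerate(folds)
            ]
            self.models_[cls] = model
            self.ranges_[cls] = calibrate_ranges(reports, class_label=cls)
            self.fold_reports_[cls] = reports
        return self

    def predict_detail(self, X: Sequence) -> list[Prediction]:
        """Full per-document decisions (points, ranges hit, distances, path)."""
        check_is_fitted(self, "models_")
        rk = self._ratio_kwargs()
        return [
            classify_document(
                self._tokenize(x, i), self.models_, self.ranges_,
                tie_policy=self.tie_policy, **rk,
            )
            for i, x in enumerate(X)
        ]

    def predict(self, X: Sequence) -> np.ndarray:
        """Predicted class label per document."""
        return np.asarray(
            [p.predicted_label for p in self.predict_detail(X)], dtype=object
        )

    def decision_function(self, X: Sequence) -> np.ndarray:
        """Signed proximity margin toward the positive class.

        Positive values favour ``positive_label`` (the other class's
        boundary distance minus the positive class's).
        """
        check_is_fitted(self, "models_")
        pos = self.positive_label
        (neg,) = [c for c in self.classes_ if c != pos]
        return np.asarray(
            [p.distance[neg] - p.distance[pos] for p in self.predict_detail(X)]
        )
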