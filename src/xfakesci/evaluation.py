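"""Confusion accounting, F1 scoring, and the classical-baseline benchmark.

The positive class is the genuine publication: TP counts publications
recognised as publications, FP counts generated articles misread as
publications.  F1 = 2·TP / (2·TP + FP + FN), reported as a percentage to
two decimals.

``benchmark_baselines`` fits four classical text classifiers — multinomial
naive Bayes, linear- and RBF-kernel support-vector machines, and logistic
regression — on exactly the same bigram TF-IDF features the network model
trains from, and reports each one's confusion counts and F1 on the test
set.  The baselines are treated as black boxes at their library defaults.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import MultinomialNB
from sklearn.svm import SVC, LinearSVC

from .classifier import Prediction
from .corpus_io import Corpus, Label
from .features import BigramTable, FeatureConfig, DEFAULT_FEATURE_CONFIG, tfidf_bigrams
from .preprocess import (
    DEFAULT_CONFIG,
    PreprocessConfig,
    TokenizedDoc,
    consecutive_bigrams,
    tokenize_corpus,
)


@dataclass(frozen=True)
class ConfusionReport:
    """TP/FP/FN/TN counts and F1, positive class = publication."""

    TP: int
    FP: int
    FN: int
    TN: int
    positive_label: str = Label.PUBMED.value

    @property
    def f1_percent(self) -> float:
        return f1_score(self.TP, self.FP, self.FN)

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    def as_dict(self) -> dict:
        return {
            "TP": self.TP, "FP": self.FP, "FN": self.FN, "TN": self.TN,
            "F1": self.f1_percent, "positive_label": self.positive_label,
        }


def f1_score(TP: int, FP: int, FN: int) -> float:
    """F1 = 100 · 2·TP / (2·TP + FP + FN), rounded half-up to two decimals."""
    denom = 2 * TP + FP + FN
    if denom == 0:
        raise ValueError("F1 undefined: no positives in truth or prediction")
    value = Decimal(200 * TP) / Decimal(denom)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def confusion_matrix(
    predictions: Sequence[Prediction] | Sequence[str],
    truth: Sequence[str],
    positive_label: str = Label.PUBMED.value,
) -> ConfusionReport:
    """Count TP/FP/FN/TN with the publication class as positive.

    Accepts either full :class:`Prediction` objects or bare label strings.
    """
    predicted = [
        p.predicted_label if isinstance(p, Prediction) else str(p)
        for p in predictions
    ]
    truth = [str(t) for t in truth]
    if len(predicted) != len(truth):
        raise ValueError(
            f"{len(predicted)} predictions vs {len(truth)} truth labels"
        )
    tp = fp = fn = tn = 0
    for pred, true in zip(predicted, truth):
        if true == positive_label:
            if pred == positive_label:
                tp += 1
            else:
                fn += 1
        else:
            if pred == positive_label:
                fp += 1
            else:
                tn += 1
    return ConfusionReport(TP=tp, FP=fp, FN=fn, TN=tn, positive_label=positive_label)


def _feature_matrix(
    docs: Sequence[TokenizedDoc],
    table: BigramTable,
    sentence_scope: bool = True,
) -> np.ndarray:
    """Per-document tf-idf vector over the training table's bigram vocabulary."""
    index = {e.bigram: j for j, e in enumerate(table.entries)}
    idf = np.array([e.idf for e in table.entries])
    X = np.zeros((len(docs), len(index)))
    for i, doc in enumerate(docs):
        stream = consecutive_bigrams(doc, sentence_scope=sentence_scope)
        if not stream:
            continue
        total = len(stream)
        for bigram in stream:
            j = index.get(bigram)
            if j is not None:
                X[i, j] += 1
        X[i] /= total
    return X * idf


def benchmark_baselines(
    train: Corpus,
    test: Corpus,
    seed: int = 0,
    preprocess: PreprocessConfig = DEFAULT_CONFIG,
    features: FeatureConfig = DEFAULT_FEATURE_CONFIG,
    positive_label: str = Label.PUBMED.value,
) -> dict[str, ConfusionReport]:
    """Fit the four classical baselines and score them on the test corpus.

    Both corpora must carry class labels.  Features are the package's own
    bigram TF-IDF scores over the training vocabulary — the same
    featurization that seeds the network models.  The naive Bayes baseline
    clips negative feature values at zero (the printed idf smoothing can go
    negative, which a multinomial model cannot accept); the other three
    consume the raw matrix.  Deterministic given ``seed``.
    """
    y_train = np.asarray([a.label.value for a in train], dtype=object)
    y_test = [a.label.value for a in test]
    if len(set(y_train)) < 2:
        raise ValueError("training corpus must contain both classes")

    train_docs = tokenize_corpus(train, preprocess)
    test_docs = tokenize_corpus(test, preprocess)
    table = tfidf_bigrams(train_docs, features)
    X_train = _feature_matrix(train_docs, table, features.sentence_scope_bigrams)
    X_test = _feature_matrix(test_docs, table, features.sentence_scope_bigrams)

    estimators = {
        "naive_bayes": MultinomialNB(),
        "linear_svm": LinearSVC(random_state=seed),
        "classical_svm": SVC(kernel="rbf", random_state=seed),
        "logistic_regression": LogisticRegression(max_iter=1000, random_state=seed),
    }
    reports: dict[str, ConfusionReport] = {}
    for name, est in estimators.items():
        Xtr, Xte = (np.clip(X_train, 0, None), np.clip(X_test, 0, None)) \
            if name == "naive_bayes" else (X_train, X_test)
        est.fit(Xtr, y_train)
        pred = [str(p) for p in est.predict(Xte)]
        reports[name] = confusion_matrix(pred, y_test, positive_label)
    return reports
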