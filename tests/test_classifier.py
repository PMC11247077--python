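import random

import pytest

from xfakesci.calibration import CalibrationRange
from xfakesci.classifier import (
    boundary_distance,
    classify_corpus,
    classify_document,
    decide_label,
)
from xfakesci.corpus_io import Article, Corpus, Label
from xfakesci.network import build_term_graph, largest_connected_component
from xfakesci.preprocess import TokenizedDoc

from .oracles import literal_decision


def _range(label, lo, hi):
    return CalibrationRange(label, lo, hi, n_folds=2)


class TestBoundaryDistance:
    def test_outside_distance_to_nearer_endpoint(self):
        assert boundary_distance(0.20, _range("PUBMED", 0.10, 0.11)) == pytest.approx(0.09)

    def test_point_on_lower_bound_is_inside(self):
        assert boundary_distance(0.10, _range("PUBMED", 0.10, 0.30)) == 0.0

    def test_distance_above_range(self):
        assert boundary_distance(0.50, _range("PUBMED", 0.10, 0.30)) == pytest.approx(0.20)


class TestDecideLabel:
    RANGES = {
        "GPT": _range("GPT", 0.25, 0.29),      # generated-class cancer band
        "PUBMED": _range("PUBMED", 0.15, 0.17),
    }

    def test_single_range_membership_wins(self):
        label, path, in_range, _ = decide_label(
            {"GPT": 0.27, "PUBMED": 0.27}, self.RANGES
        )
        assert label == "GPT"
        assert path == "single_range"
        assert in_range == {"GPT": True, "PUBMED": False}

    def test_proximity_fallback_when_outside_both(self):
        label, path, _, dist = decide_label(
            {"GPT": 0.20, "PUBMED": 0.12}, self.RANGES
        )
        assert dist == pytest.approx({"GPT": 0.05, "PUBMED": 0.03})
        assert label == "PUBMED"
        assert path == "proximity"

    def test_exact_distance_tie_uses_policy(self):
        # endpoints representable exactly in binary so both distances are 0.25
        ranges = {"GPT": _range("GPT", 0.75, 1.0), "PUBMED": _range("PUBMED", 0.0, 0.25)}
        label, path, _, _ = decide_label({"GPT": 0.5, "PUBMED": 0.5}, ranges)
        assert label == "PUBMED"  # conservative default
        assert path == "tie_break"
        label, _, _, _ = decide_label({"GPT": 0.5, "PUBMED": 0.5}, ranges,
                                      tie_policy="GPT")
        assert label == "GPT"

    def test_both_ranges_nearest_center_rule(self):
        ranges = {"GPT": _range("GPT", 0.0, 0.4), "PUBMED": _range("PUBMED", 0.0, 0.2)}
        label, path, _, _ = decide_label({"GPT": 0.2, "PUBMED": 0.19}, ranges)
        assert path == "both_ranges"
        assert label == "GPT"  # |0.2-0.2| = 0 < |0.19-0.1|

    def test_two_classes_required(self):
        with pytest.raises(ValueError, match="two classes"):
            decide_label({"GPT": 0.3}, {"GPT": _range("GPT", 0.1, 0.2)})

    def test_agrees_with_literal_case_analysis_on_random_draws(self):
        rng = random.Random(909)
        paths = set()
        for _ in range(2000):
            pa, pb = rng.random(), rng.random()
            lo_a, hi_a = sorted((round(rng.random(), 2), round(rng.random(), 2)))
            lo_b, hi_b = sorted((round(rng.random(), 2), round(rng.random(), 2)))
            ranges = {"A": _range("A", lo_a, hi_a), "B": _range("B", lo_b, hi_b)}
            label, path, _, _ = decide_label({"A": pa, "B": pb}, ranges, tie_policy="A")
            assert label == literal_decision(pa, (lo_a, hi_a), pb, (lo_b, hi_b), "A")
            paths.add(path)
        assert {"single_range", "both_ranges", "proximity"} <= paths


def _two_class_setup():
    gpt_model = largest_connected_component(
        build_term_graph([("g1", "g2"), ("g2", "g3")], "GPT")
    )
    pub_model = largest_connected_component(
        build_term_graph([("p1", "p2"), ("p2", "p3")], "PUBMED")
    )
    models = {"GPT": gpt_model, "PUBMED": pub_model}
    ranges = {"GPT": _range("GPT", 0.25, 0.35), "PUBMED": _range("PUBMED", 0.1, 0.2)}
    return models, ranges


class TestClassifyDocument:
    def test_prediction_records_full_audit_trail(self):
        models, ranges = _two_class_setup()
        doc = TokenizedDoc("t1", (("g1", "g2", "g3"), ("x", "y", "z", "w")), 7)
        pred = classify_document(doc, models, ranges)
        assert pred.point["GPT"] == pytest.approx(2 / 7)
        assert pred.point["PUBMED"] == 0.0
        assert pred.predicted_label == "GPT"
        assert pred.decision_path == "single_range"
        assert pred.in_range == {"GPT": True, "PUBMED": False}
        assert all(v >= 0 for v in pred.distance.values())

    def test_missing_range_is_a_configuration_error(self):
        models, ranges = _two_class_setup()
        doc = TokenizedDoc("t1", (("g1", "g2"),), 2)
        with pytest.raises(ValueError, match="two classes"):
            classify_document(doc, models, {"GPT": ranges["GPT"]})


def test_single_mode_in_out_decision():
    models, ranges = _two_class_setup()
    from xfakesci.classifier import classify_single_mode
    inside = TokenizedDoc("t1", (("g1", "g2", "g3"), ("x", "y", "z", "w")), 7)
    in_range, point = classify_single_mode(inside, models["GPT"], ranges["GPT"])
    assert in_range and point == pytest.approx(2 / 7)
    outside = TokenizedDoc("t2", (("x", "y", "z"),), 3)
    in_range, point = classify_single_mode(outside, models["GPT"], ranges["GPT"])
    assert not in_range and point == 0.0


class TestClassifyCorpus:
    def test_empty_corpus_gives_empty_predictions(self):
        models, ranges = _two_class_setup()
        assert classify_corpus(Corpus(()), models, ranges) == []

    def test_singleton_corpus_order_and_totality(self):
        models, ranges = _two_class_setup()
        corpus = Corpus((Article("t1", "t", "g1 g2 g3."),))
        preds = classify_corpus(corpus, models, ranges)
        assert len(preds) == 1
        assert preds[0].article_id == "t1"
        assert preds[0].predicted_label in {"GPT", "PUBMED"}

    def test_every_document_gets_exactly_one_label(self, small_pair):
        models, ranges = _two_class_setup()
        pub, _ = small_pair
        test = Corpus(tuple(list(pub)[:20]))
        preds = classify_corpus(test, models, ranges)
        assert [p.article_id for p in preds] == [a.id for a in test]
        assert all(p.predicted_label in {"GPT", "PUBMED"} for p in preds)

    def test_deterministic(self):
        models, ranges = _two_class_setup()
        corpus = Corpus(tuple(
            Article(f"t{i}", "t", "g1 g2 p1 p2 filler words here.")
            for i in range(5)
        ))
        assert classify_corpus(corpus, models, ranges) == classify_corpus(
            corpus, models, ranges
        )

    def test_tokenization_error_names_the_article(self):
        models, ranges = _two_class_setup()
        corpus = Corpus((Article("bad", "t", "..."),))
        with pytest.raises(ValueError, match="bad"):
            classify_corpus(corpus, models, ranges)
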