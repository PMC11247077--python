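import pytest
from hypothesis import given, strategies as st

from xfakesci.calibration import (
    CalibrationRange,
    calibrate_ranges,
    doc_lcc_ratio,
    fold_ratio_mean,
)
from xfakesci.network import build_term_graph, largest_connected_component
from xfakesci.preprocess import TokenizedDoc


def _model(bigrams, label="GPT"):
    return largest_connected_component(build_term_graph(bigrams, label))


def _doc(tokens, raw=None, doc_id="d"):
    return TokenizedDoc(doc_id, (tuple(tokens),), raw if raw is not None else len(tokens))


class TestDocLccRatio:
    def test_matching_occurrences_over_word_count(self):
        # chain a-b-c in the model; doc has 3 matching occurrences, 10 raw words
        model = _model([("a", "b"), ("b", "c")])
        doc = TokenizedDoc("d", (("a", "b"), ("b", "c"), ("a", "b"), ("x", "y")), 10)
        assert doc_lcc_ratio(doc, model) == pytest.approx(0.3)

    def test_disjoint_vocabulary_scores_zero(self):
        model = _model([("a", "b")])
        assert doc_lcc_ratio(_doc(["x", "y", "z"]), model) == 0.0

    def test_multiplicity_vs_unique_matching(self):
        model = _model([("a", "b")])
        doc = TokenizedDoc("d", (("a", "b"), ("a", "b")), 4)
        assert doc_lcc_ratio(doc, model) == pytest.approx(2 / 4)
        assert doc_lcc_ratio(doc, model, unique_matches=True) == pytest.approx(1 / 4)

    def test_node_match_mode_is_looser_than_edge_mode(self):
        # b-c and a-b edges exist; (a, c) matches by nodes but not by edge
        model = _model([("a", "b"), ("b", "c")])
        doc = _doc(["a", "c"])
        assert doc_lcc_ratio(doc, model, match_mode="edge") == 0.0
        assert doc_lcc_ratio(doc, model, match_mode="nodes") == pytest.approx(0.5)

    def test_content_word_count_mode_changes_denominator(self):
        model = _model([("a", "b")])
        doc = TokenizedDoc("d", (("a", "b"),), raw_word_count=8)
        assert doc_lcc_ratio(doc, model, word_count_mode="raw") == pytest.approx(1 / 8)
        assert doc_lcc_ratio(doc, model, word_count_mode="content") == pytest.approx(1 / 2)

    def test_zero_word_document_rejected(self):
        model = _model([("a", "b")])
        with pytest.raises(ValueError, match="zero words"):
            doc_lcc_ratio(TokenizedDoc("d", (), 0), model)

    @given(st.lists(st.sampled_from("abcx"), min_size=1, max_size=12))
    def test_ratio_bounded_by_bigram_capacity(self, tokens):
        """An n-word document has at most n-1 bigram occurrences."""
        model = _model([("a", "b"), ("b", "c"), ("c", "a")])
        n = len(tokens)
        ratio = doc_lcc_ratio(_doc(tokens), model)
        assert 0.0 <= ratio <= (n - 1) / n


class TestFoldRatioMean:
    def test_mean_of_two_ratios(self):
        model = _model([("a", "b")])
        fold = [
            TokenizedDoc("d1", (("a", "b"), ("x", "y"), ("p", "q")), 5),   # 1/5
            TokenizedDoc("d2", (("a", "b"), ("a", "b")), 5),               # 2/5
        ]
        report = fold_ratio_mean(fold, model)
        assert report.per_document_ratios == pytest.approx((0.2, 0.4))
        assert report.fold_mean == pytest.approx(0.3)

    def test_identical_documents_mean_equals_single_ratio(self):
        model = _model([("a", "b")])
        doc = TokenizedDoc("d", (("a", "b"),), 4)
        report = fold_ratio_mean([doc, doc, doc], model)
        assert report.fold_mean == pytest.approx(0.25)

    def test_mean_matches_independent_summation(self):
        import random
        rng = random.Random(303)
        model = _model([("a", "b"), ("b", "c")])
        fold = []
        for i in range(10):
            tokens = tuple(rng.choice("abcz") for _ in range(rng.randint(2, 15)))
            fold.append(TokenizedDoc(f"d{i}", (tokens,), len(tokens)))
        report = fold_ratio_mean(fold, model)
        expected = sum(doc_lcc_ratio(d, model) for d in fold) / len(fold)
        assert report.fold_mean == pytest.approx(expected)

    def test_empty_fold_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fold_ratio_mean([], _model([("a", "b")]))


class TestCalibrateRanges:
    def test_fold_means_to_min_max_bounds(self):
        # published GPT fold means for the Alzheimer's corpus -> (0.27, 0.30)
        r = calibrate_ranges([0.27, 0.30, 0.30, 0.28, 0.28, 0.29], class_label="GPT")
        assert (r.lower, r.upper) == (0.27, 0.30)

    def test_single_fold_degenerates_to_point_range(self):
        r = calibrate_ranges([0.21], class_label="GPT")
        assert r.lower == r.upper == 0.21
        assert r.n_folds == 1

    def test_mixed_class_reports_rejected(self):
        from xfakesci.calibration import FoldRatioReport
        reports = [
            FoldRatioReport("GPT", 0, (0.2,), 0.2),
            FoldRatioReport("PUBMED", 1, (0.1,), 0.1),
        ]
        with pytest.raises(ValueError, match="mix"):
            calibrate_ranges(reports)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError, match="lower"):
            CalibrationRange("GPT", lower=0.3, upper=0.2, n_folds=1)

    @given(st.lists(st.floats(0, 0.99), min_size=1, max_size=12))
    def test_every_fold_mean_lies_within_bounds(self, means):
        r = calibrate_ranges(means, class_label="GPT")
        assert all(r.lower <= m <= r.upper for m in means)
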