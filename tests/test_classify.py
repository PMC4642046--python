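"""Classifier adapters, recall adjustment, tuning, importances."""

import pytest
from hypothesis import given, strategies as st

from eventex.classify import (
    CapabilityError,
    OracleClassifier,
    PredictionRecord,
    SklearnClassifier,
    adjust_recall,
    grouped_importance_report,
    feature_group,
    micro_f_examples,
    positive_count,
    rank_feature_importances,
    tune_parameters,
)
from eventex.features import Example, FeatureSpace


def _ex(i, gold, feats):
    return Example(f"x{i}", gold, feats, ())


class TestOracle:
    def test_returns_gold_classes_with_unit_confidence(self):
        examples = [_ex(0, "A", {"f": 1.0}), _ex(1, "neg", {"g": 1.0})]
        records = OracleClassifier().train(examples).predict(examples)
        assert [r.predicted for r in records] == ["A", "neg"]
        assert records[0].scores["A"] == 1.0

    def test_unlabelled_example_is_an_error(self):
        with pytest.raises(ValueError, match="no gold class"):
            OracleClassifier().predict([_ex(0, None, {"f": 1.0})])


class TestRecallAdjustment:
    def _records(self):
        return [
            PredictionRecord("a", {"neg": 0.8, "Pos": 0.5}, "neg"),
            PredictionRecord("b", {"neg": 0.3, "Pos": 0.7}, "Pos"),
            PredictionRecord("c", {"neg": 0.9, "Pos": 0.1}, "neg"),
        ]

    def test_beta_one_is_identity(self):
        out = adjust_recall(self._records(), 1.0)
        assert [r.predicted for r in out] == ["neg", "Pos", "neg"]

    def test_beta_zero_forces_best_positive_class(self):
        out = adjust_recall(self._records(), 0.0)
        assert all(r.predicted == "Pos" for r in out)

    def test_half_beta_flips_borderline_negative(self):
        # neg 0.8 * 0.5 = 0.4 < 0.5 -> flips to the positive class
        out = adjust_recall(self._records(), 0.5)
        assert out[0].predicted == "Pos"
        assert out[2].predicted == "neg"  # 0.45 > 0.1 stays negative

    def test_beta_outside_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_recall(self._records(), 1.5)

    def test_monotone_positive_count_over_21_point_grid(self):
        records = self._records()
        counts = [
            positive_count(adjust_recall(records, beta))
            for beta in [i / 20 for i in range(21)]
        ]
        assert counts == sorted(counts, reverse=True)

    @given(
        st.lists(
            st.tuples(
                st.floats(-5, 5, allow_nan=False), st.floats(-5, 5, allow_nan=False)
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_monotonicity_holds_for_signed_decision_values(self, pairs):
        records = [
            PredictionRecord(f"e{i}", {"neg": n, "Pos": p}, "neg" if n >= p else "Pos")
            for i, (n, p) in enumerate(pairs)
        ]
        grid = [i / 20 for i in range(21)]
        counts = [positive_count(adjust_recall(records, b)) for b in grid]
        assert counts == sorted(counts, reverse=True)


class TestSklearnAdapter:
    def _separable(self):
        train = [
            _ex(i, "A" if i % 2 else "neg", {"isA": 1.0} if i % 2 else {"isN": 1.0})
            for i in range(20)
        ]
        return train

    def test_train_predict_round_trip(self):
        from sklearn.svm import LinearSVC

        train = self._separable()
        ad = SklearnClassifier(LinearSVC(C=1.0), seed=1).train(train)
        records = ad.predict(train)
        assert micro_f_examples(records, train) == 100.0

    def test_prediction_is_deterministic(self):
        from sklearn.svm import LinearSVC

        train = self._separable()
        a = SklearnClassifier(LinearSVC(C=1.0), seed=1).train(train).predict(train)
        b = SklearnClassifier(LinearSVC(C=1.0), seed=1).train(train).predict(train)
        assert [(r.predicted, r.scores) for r in a] == [(r.predicted, r.scores) for r in b]

    def test_adapter_swap_leaves_examples_untouched(self):
        import copy

        from sklearn.svm import LinearSVC

        train = self._separable()
        before = copy.deepcopy([e.features for e in train])
        SklearnClassifier(LinearSVC(C=1.0), seed=1).train(train).predict(train)
        OracleClassifier().predict(train)
        assert [e.features for e in train] == before


class TestTuning:
    def test_single_point_grid_returns_that_point(self):
        from sklearn.svm import LinearSVC

        train = TestSklearnAdapter()._separable()
        res = tune_parameters(
            train, train,
            lambda: SklearnClassifier(LinearSVC(), seed=1),
            {"C": [1.0]},
        )
        assert res["params"] == {"C": 1.0} and res["beta"] == 1.0

    def test_separable_fixture_reaches_perfect_devel_f(self):
        from sklearn.svm import LinearSVC

        train = TestSklearnAdapter()._separable()
        res = tune_parameters(
            train, train,
            lambda: SklearnClassifier(LinearSVC(), seed=1),
            {"C": [0.001, 1.0, 1000.0]},
        )
        assert res["score"] == 100.0

    def test_monotone_objective_returns_boundary_beta(self):
        # the scaled negative score grows strictly with beta, so an objective
        # penalizing it is strictly decreasing in beta: the grid boundary wins
        class Fixed:
            def train(self, examples, **kw):
                return self

            def predict(self, examples):
                return [PredictionRecord("a", {"neg": 0.8, "Pos": 0.5}, "neg")]

        res = tune_parameters(
            [], [_ex(0, "neg", {})],
            Fixed,
            {},
            beta_grid=[0.0, 0.25, 0.5, 0.75, 1.0],
            objective=lambda recs, exs: -sum(r.scores.get("neg", 0.0) for r in recs),
        )
        assert res["beta"] == 0.0

    def test_empty_grid_is_an_error(self):
        with pytest.raises(ValueError, match="empty grid"):
            tune_parameters([], [], OracleClassifier, {}, beta_grid=None)


class TestImportances:
    def _tree_adapter(self):
        from sklearn.ensemble import ExtraTreesClassifier

        train = [
            _ex(i, "A" if i % 2 else "neg",
                {"trg_txt_a": 1.0, "bow_x": float(i % 2)} if i % 2
                else {"trg_txt_b": 1.0, "bow_x": 0.0})
            for i in range(40)
        ]
        ad = SklearnClassifier(ExtraTreesClassifier(n_estimators=10), seed=1)
        return ad.train(train)

    def test_weights_descending_and_normalized(self):
        ranked = rank_feature_importances(self._tree_adapter())
        weights = [w for _, w in ranked]
        assert weights == sorted(weights, reverse=True)
        assert abs(sum(weights) - 1.0) < 1e-9

    def test_single_feature_model_has_unit_weight(self):
        from sklearn.ensemble import ExtraTreesClassifier

        train = [_ex(i, "A" if i % 2 else "neg", {"only": float(i % 2)}) for i in range(20)]
        ad = SklearnClassifier(ExtraTreesClassifier(n_estimators=5), seed=1).train(train)
        ranked = rank_feature_importances(ad)
        assert ranked[0] == ("only", 1.0)

    def test_grouped_report_partitions_every_feature(self):
        ranked = rank_feature_importances(self._tree_adapter())
        report = grouped_importance_report(ranked)
        assert sum(s.count for s in report.values()) == len(ranked)
        assert set(report) == {feature_group(n) for n, _ in ranked}

    def test_missing_capability_raises(self):
        with pytest.raises(CapabilityError):
            rank_feature_importances(OracleClassifier())
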