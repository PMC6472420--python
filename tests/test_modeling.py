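"""Metrics, cross-validation machinery, and the model/results objects."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kgrepurpose.features import FeatureMatrix, FeatureSchema
from kgrepurpose.modeling import (
    ALGORITHMS,
    ModelSpec,
    RepurposingClassifier,
    accuracy,
    auc,
    auprc,
    classify,
    compare_models,
    cross_validate,
    f1,
    feature_importance,
    fold_assignments,
    kappa,
    kendall_tau_b,
    load_model,
    predict_scores,
    roc_points,
    save_model,
    train,
)

from conftest import oracle_auc, oracle_tau_b

SCHEMA = FeatureSchema.from_labels(
    {"Anatomy", "Physiology"}, {"Cell", "Tissue", "Organism Function"}, "observed"
)


def synthetic_matrix(n=300, delta=2.0, seed=0, n_features=None):
    """Labelled integer matrix with a planted mean shift on one column."""
    rng = np.random.default_rng(seed)
    schema = SCHEMA
    p = len(schema)
    half = n // 2
    X = rng.poisson(5.0, size=(n, p))
    # shift the Physiology group feature for the approved half
    idx = schema.names.index("group:Physiology")
    X[:half, idx] = rng.poisson(5.0 + delta * 5.0, size=half)
    labels = ["approved"] * half + ["terminated"] * (n - half)
    perm = rng.permutation(n)
    return FeatureMatrix(
        schema=schema,
        values=X[perm],
        pair_ids=[f"d{i}|s{i}" for i in range(n)],
        labels=[labels[i] for i in perm],
    )


RF_SMALL = {"n_estimators": 100}


class TestMetrics:
    def test_auc_half_on_mixed_triplet(self):
        # pairs: (90 approved vs 80 terminated) concordant,
        #        (40 approved vs 80 terminated) discordant
        assert auc([90, 80, 40], ["approved", "terminated", "approved"]) == 0.5

    def test_perfect_ranking(self):
        assert auc([90, 80, 10, 5], ["approved", "approved", "terminated", "terminated"]) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 2], ["approved", "approved"])
        with pytest.raises(ValueError):
            auprc([1, 2], ["approved", "approved"])

    def test_confusion_hand_computation(self):
        # TP=40, FN=10, FP=5, TN=45 at the 50 cutoff
        scores = [60] * 40 + [40] * 10 + [60] * 5 + [40] * 45
        labels = ["approved"] * 50 + ["terminated"] * 50
        assert accuracy(scores, labels) == pytest.approx(0.85)
        assert kappa(scores, labels) == pytest.approx(0.70)

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_equals_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 60))
        scores = rng.integers(0, 20, size=n).astype(float)  # many ties
        labels = ["approved" if rng.random() < 0.5 else "terminated" for _ in range(n)]
        if len(set(labels)) < 2:
            labels[0] = "approved"
            labels[1] = "terminated"
        assert auc(scores, labels) == pytest.approx(oracle_auc(scores, labels))

    def test_kappa_zero_under_label_permutation(self):
        rng = np.random.default_rng(0)
        scores = np.repeat([80.0, 20.0], 50)
        vals = []
        for _ in range(100):
            labels = ["approved"] * 50 + ["terminated"] * 50
            rng.shuffle(labels)
            vals.append(kappa(scores, labels))
        assert abs(np.mean(vals)) < 0.05


class TestClassify:
    def test_printed_scores_around_cutoff(self):
        assert classify([52.2, 46.0]) == ["approved", "terminated"]

    def test_exactly_fifty_is_terminated(self):
        assert classify([50.0]) == ["terminated"]

    def test_count_above_cutoff_matches_brute_force(self):
        from kgrepurpose.experiments import load_adpkd_table

        table = load_adpkd_table()
        scores = table.scores()
        assert table.n_above_cutoff(50.0) == sum(1 for s in scores if s > 50.0)


class TestRocPoints:
    def test_perfect_ranking_passes_through_corner(self):
        pts = roc_points([9, 8, 2, 1], ["approved", "approved", "terminated", "terminated"])
        assert (0.0, 1.0) in pts
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_trapezoid_area_equals_auc(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        scores = rng.integers(0, 15, size=n).astype(float)
        labels = ["approved" if rng.random() < 0.4 else "terminated" for _ in range(n)]
        if len(set(labels)) < 2:
            labels[:2] = ["approved", "terminated"]
        pts = np.asarray(roc_points(scores, labels))
        area = np.trapezoid(pts[:, 1], pts[:, 0])
        assert area == pytest.approx(auc(scores, labels))
        # monotone non-decreasing in both coordinates
        assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()

    def test_reversed_scores_reflect_area(self):
        scores = [9.0, 7.0, 5.0, 3.0, 1.0]
        labels = ["approved", "terminated", "approved", "terminated", "terminated"]
        a = auc(scores, labels)
        assert auc([-s for s in scores], labels) == pytest.approx(1 - a)


class TestKendallTau:
    def test_perfect_discordance(self):
        tau, _ = kendall_tau_b([1, 2, 3], [3, 2, 1])
        assert tau == pytest.approx(-1.0)

    def test_length_mismatch_and_ties_rejected(self):
        with pytest.raises(ValueError):
            kendall_tau_b([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            kendall_tau_b([1, 1, 1], [1, 2, 3])

    @given(
        st.lists(st.integers(0, 5), min_size=4, max_size=25),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=60, derandomize=True)
    def test_matches_pair_enumeration_oracle_with_ties(self, x, rnd):
        y = [rnd.randint(0, 5) for _ in x]
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        tau, _ = kendall_tau_b(x, y)
        assert tau == pytest.approx(oracle_tau_b(x, y))


class TestCrossValidation:
    def test_separable_signal_high_auc(self):
        m = synthetic_matrix(n=300, delta=3.0, seed=1)
        rep = cross_validate(
            m, ModelSpec(seed=1, hyperparameters=RF_SMALL), repeats=2, folds=5
        )
        assert rep.means["auc"] >= 99.0
        assert rep.fold_values.shape == (10, 5)

    def test_permuted_labels_null_auc(self):
        m = synthetic_matrix(n=300, delta=0.0, seed=2)
        rep = cross_validate(
            m, ModelSpec(seed=2, hyperparameters=RF_SMALL), repeats=2, folds=5
        )
        assert 45.0 <= rep.means["auc"] <= 55.0

    def test_same_seed_identical_report(self):
        m = synthetic_matrix(n=200, delta=1.0, seed=3)
        spec = ModelSpec(seed=3, hyperparameters=RF_SMALL)
        a = cross_validate(m, spec, repeats=2, folds=4)
        b = cross_validate(m, spec, repeats=2, folds=4)
        assert np.array_equal(a.fold_values, b.fold_values)
        assert a.means == b.means

    def test_class_too_small_rejected(self):
        m = synthetic_matrix(n=30, seed=0)
        m.labels = ["approved"] * 27 + ["terminated"] * 3
        with pytest.raises(ValueError, match="too small"):
            cross_validate(m, ModelSpec(seed=0), repeats=1, folds=5)

    def test_compare_models_shares_folds(self):
        m = synthetic_matrix(n=200, delta=2.0, seed=4)
        specs = [
            ModelSpec("random_forest", RF_SMALL, seed=4),
            ModelSpec("logistic_regression", seed=4),
        ]
        reports = compare_models(m, specs, repeats=1, folds=4, seed=9)
        assert [r.algorithm for r in reports] == ["random_forest", "logistic_regression"]
        # fold fingerprints: assignment derives only from (labels, seed)
        f1_ = fold_assignments(m.labels, 1, 4, 9)
        f2_ = fold_assignments(m.labels, 1, 4, 9)
        for (tr1, te1), (tr2, te2) in zip(f1_, f2_):
            assert np.array_equal(te1, te2) and np.array_equal(tr1, tr2)

    def test_single_spec_equals_cross_validate(self):
        m = synthetic_matrix(n=200, delta=2.0, seed=5)
        spec = ModelSpec("random_forest", RF_SMALL, seed=5)
        solo = cross_validate(m, spec, repeats=1, folds=4, seed=5)
        comp = compare_models(m, [spec], repeats=1, folds=4, seed=5)[0]
        assert np.array_equal(solo.fold_values, comp.fold_values)

    def test_registry_covers_all_algorithms(self):
        m = synthetic_matrix(n=120, delta=2.0, seed=6)
        small = {
            "random_forest": {"n_estimators": 20},
            "neural_network": {"max_iter": 50},
        }
        specs = [ModelSpec(a, small.get(a, {}), seed=6) for a in ALGORITHMS]
        reports = compare_models(m, specs, repeats=1, folds=3, seed=6)
        assert len(reports) == len(ALGORITHMS)
        for r in reports:
            assert 0.0 <= r.means["auc"] <= 100.0


class TestTrainPredict:
    def test_scores_in_range_and_deterministic(self):
        m = synthetic_matrix(n=200, delta=2.0, seed=7)
        spec = ModelSpec(seed=7, hyperparameters=RF_SMALL)
        res1, res2 = train(m, spec), train(m, spec)
        s1, s2 = predict_scores(res1, m), predict_scores(res2, m)
        assert np.array_equal(s1, s2)
        assert (s1 >= 0).all() and (s1 <= 100).all()

    def test_separable_training_accuracy_perfect(self):
        m = synthetic_matrix(n=200, delta=4.0, seed=8)
        res = train(m, ModelSpec(seed=8, hyperparameters=RF_SMALL))
        preds = classify(predict_scores(res, m))
        assert preds == list(m.labels)

    def test_score_equals_mean_of_per_tree_probabilities(self):
        m = synthetic_matrix(n=150, delta=1.0, seed=9)
        res = train(m, ModelSpec(seed=9, hyperparameters={"n_estimators": 25}))
        forest = res.estimator
        pos = list(forest.classes_).index("approved")
        X = m.values.astype(float)
        per_tree = np.stack([t.predict_proba(X)[:, pos] for t in forest.estimators_])
        assert predict_scores(res, m) == pytest.approx(100.0 * per_tree.mean(axis=0))

    def test_vote_scoring_is_tree_fraction(self):
        m = synthetic_matrix(n=150, delta=1.0, seed=10)
        res = train(m, ModelSpec(seed=10, hyperparameters={"n_estimators": 25}))
        votes = res.predict_scores(m, method="vote")
        forest = res.estimator
        pos = list(forest.classes_).index("approved")
        X = m.values.astype(float)
        expected = 100.0 * np.stack(
            [t.predict(X) == pos for t in forest.estimators_]
        ).mean(axis=0)
        assert votes == pytest.approx(expected)

    def test_schema_mismatch_rejected(self):
        m = synthetic_matrix(n=100, delta=1.0, seed=11)
        res = train(m, ModelSpec(seed=11, hyperparameters=RF_SMALL))
        other_schema = FeatureSchema.from_labels({"Anatomy"}, {"Cell"}, "observed")
        other = FeatureMatrix(
            schema=other_schema,
            values=np.zeros((2, 3), dtype=int),
            pair_ids=["a|b", "c|d"],
        )
        with pytest.raises(ValueError, match="schema"):
            predict_scores(res, other)

    def test_single_class_training_rejected(self):
        m = synthetic_matrix(n=50, seed=12)
        m.labels = ["approved"] * 50
        with pytest.raises(ValueError):
            RepurposingClassifier(m, ModelSpec(seed=0))

    def test_save_load_round_trip(self, tmp_path):
        m = synthetic_matrix(n=100, delta=2.0, seed=13)
        res = train(m, ModelSpec(seed=13, hyperparameters=RF_SMALL))
        save_model(res, tmp_path / "model.joblib")
        loaded = load_model(tmp_path / "model.joblib")
        assert loaded.schema == res.schema
        assert np.array_equal(predict_scores(loaded, m), predict_scores(res, m))


class TestImportance:
    def test_planted_signal_feature_ranked_first(self):
        m = synthetic_matrix(n=400, delta=3.0, seed=14)
        res = train(m, ModelSpec(seed=14, hyperparameters=RF_SMALL))
        report = feature_importance(res)
        top = report.top(1)[0]
        assert top[0] == "group:Physiology"
        assert top[1] == pytest.approx(100.0)

    def test_constant_feature_zero_importance(self):
        m = synthetic_matrix(n=200, delta=2.0, seed=15)
        m.values[:, m.schema.names.index("type:Tissue")] = 7  # zero variance
        res = train(m, ModelSpec(seed=15, hyperparameters=RF_SMALL))
        assert feature_importance(res).scores["type:Tissue"] == 0.0

    def test_top_k_listing_length(self):
        m = synthetic_matrix(n=100, delta=1.0, seed=16)
        res = train(m, ModelSpec(seed=16, hyperparameters=RF_SMALL))
        assert len(res.feature_importance().top(3)) == 3

    def test_importance_needs_capable_algorithm(self):
        m = synthetic_matrix(n=100, delta=1.0, seed=17)
        res = train(m, ModelSpec("knn", seed=17))
        with pytest.raises(ValueError, match="importance"):
            feature_importance(res)

    def test_summary_mentions_algorithm_and_features(self):
        m = synthetic_matrix(n=100, delta=1.0, seed=18)
        res = train(m, ModelSpec(seed=18, hyperparameters=RF_SMALL))
        text = res.summary()
        assert "random_forest" in text and "direct_path" in str(res.schema.names)
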