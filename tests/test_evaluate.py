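"""Classifier battery, output scaling, ROC machinery, nested CV."""

import numpy as np
import pandas as pd
import pytest

import toxsig as ts
from toxsig.data import zscore_features
from toxsig.evaluate import (
    ALGORITHMS,
    ROCCurve,
    WeightedVotingModel,
    evaluate_fold,
    nested_cv_evaluate,
    optimal_cutoff,
    scale_output,
    threshold_average_roc,
    train_classifier,
    weighted_voting_score,
)


def _separable_toy():
    """Two genes, 3 + 3 compounds, cleanly separated clusters."""
    values = np.array(
        [[2.0, 2.2, 1.8, -2.0, -2.1, -1.9],
         [1.5, 1.7, 1.6, -1.5, -1.6, -1.4]]
    )
    matrix = ts.FoldChangeMatrix.from_arrays(values, ["g1", "g2"], list("abcdef"))
    labels = ts.CompoundLabelSet(
        {c: ("NGC" if c in "abc" else "NC") for c in "abcdef"}
    )
    return matrix, labels


class TestWeightedVoting:
    def test_single_positive_vote_saturates(self):
        model = WeightedVotingModel()
        model.a_, model.b_ = np.array([1.0]), np.array([0.0])
        assert weighted_voting_score(model, np.array([2.0])) == pytest.approx(1.0)

    def test_hand_summed_votes(self):
        model = WeightedVotingModel()
        model.a_, model.b_ = np.array([1.0, 1.0]), np.array([0.0, 0.0])
        # votes +2 and -1 -> PS = (2 - 1) / (2 + 1)
        assert weighted_voting_score(model, np.array([2.0, -1.0])) == pytest.approx(
            1.0 / 3.0
        )

    def test_all_on_the_boundary_gives_zero(self):
        model = WeightedVotingModel()
        model.a_, model.b_ = np.array([1.0, 2.0]), np.array([0.5, -0.5])
        assert weighted_voting_score(model, np.array([0.5, -0.5])) == 0.0


class TestOutputScaling:
    def test_weighted_voting_linear_map(self):
        assert scale_output("wv", -1.0) == 0.0
        assert scale_output("wv", 1.0) == 1.0
        assert scale_output("wv", 0.0) == 0.5

    def test_knn_fraction_of_neighbors(self):
        assert scale_output("knn", 3, knn_k=5) == pytest.approx(0.6)
        with pytest.raises(ValueError, match="x <= k"):
            scale_output("knn", 6, knn_k=5)

    def test_svm_logistic_midpoint(self):
        assert scale_output("svm", 0.0) == pytest.approx(0.5)
        assert scale_output("svm", 100.0) == pytest.approx(1.0)


class TestTrainClassifier:
    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_separable_toy_scores_split_at_half(self, algorithm):
        matrix, labels = _separable_toy()
        ids, y = labels.analysis_view(matrix.compound_ids)
        feats = zscore_features(matrix, ["g1", "g2"], ids)
        clf = train_classifier(algorithm, feats, y, seed=0)
        scores = clf.score_compounds(matrix, ids)
        assert (scores[np.asarray(y) == 1] >= 0.5).all()
        assert (scores[np.asarray(y) == 0] < 0.5).all()
        assert ((scores >= 0.0) & (scores <= 1.0)).all()

    def test_single_class_training_is_an_error(self):
        matrix, labels = _separable_toy()
        ids, y = labels.analysis_view(matrix.compound_ids)
        feats = zscore_features(matrix, ["g1"], ids)
        with pytest.raises(ValueError, match="degenerate"):
            train_classifier("svm", feats, np.ones_like(y))

    def test_random_forest_is_deterministic_under_seed(self):
        matrix, labels = _separable_toy()
        ids, y = labels.analysis_view(matrix.compound_ids)
        feats = zscore_features(matrix, ["g1", "g2"], ids)
        a = train_classifier("rf", feats, y, seed=11).score_compounds(matrix, ids)
        b = train_classifier("rf", feats, y, seed=11).score_compounds(matrix, ids)
        assert (a == b).all()

    @pytest.mark.parametrize("algorithm", ["wv", "knn"])
    def test_label_inversion_reflects_scores_exactly(self, algorithm):
        matrix, labels = _separable_toy()
        ids, y = labels.analysis_view(matrix.compound_ids)
        feats = zscore_features(matrix, ["g1", "g2"], ids)
        fwd = train_classifier(algorithm, feats, y, seed=0).score_compounds(matrix, ids)
        rev = train_classifier(algorithm, feats, 1 - y, seed=0).score_compounds(
            matrix, ids
        )
        assert np.allclose(fwd.to_numpy(), 1.0 - rev.to_numpy(), atol=1e-12)

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_label_inversion_reverses_the_roc(self, algorithm, small_sim):
        matrix, labels, _ = small_sim
        sig = ts.extract_sr_signature(matrix, labels)
        ids, y = labels.analysis_view(matrix.compound_ids)
        feats = zscore_features(matrix, sig.gene_ids[:10], ids)
        fwd = train_classifier(algorithm, feats, y, seed=0).score_compounds(matrix, ids)
        rev = train_classifier(algorithm, feats, 1 - y, seed=0).score_compounds(
            matrix, ids
        )
        auc_fwd = ROCCurve.from_scores(fwd.to_numpy(), y).auc
        auc_rev = ROCCurve.from_scores(rev.to_numpy(), 1 - y).auc
        assert auc_fwd == pytest.approx(auc_rev, abs=0.02)


class TestROCMachinery:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_fold_auc_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.choice(np.linspace(0, 1, 7), size=30)  # ties included
        y = rng.integers(0, 2, size=30)
        if len(set(y.tolist())) < 2:
            y[0] = 1 - y[0]
        curve = ROCCurve.from_scores(scores, y)
        pos, neg = scores[y == 1], scores[y == 0]
        wins = sum((a > b) + 0.5 * (a == b) for a in pos for b in neg)
        assert curve.auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-9)

    def test_averaging_identical_curves_is_idempotent(self):
        y = np.array([1, 1, 0, 0, 1, 0])
        s = np.array([0.9, 0.7, 0.6, 0.2, 0.5, 0.4])
        curve = ROCCurve.from_scores(s, y)
        avg = threshold_average_roc([curve, curve, curve])
        f, t = curve.at_thresholds(avg.thresholds)
        assert np.allclose(avg.fpr, f) and np.allclose(avg.tpr, t)
        assert avg.auc == pytest.approx(curve.auc, abs=1e-9)

    def test_average_lies_between_perfect_and_random(self):
        y = np.array([1, 1, 1, 0, 0, 0])
        perfect = ROCCurve.from_scores(np.array([0.9, 0.8, 0.7, 0.3, 0.2, 0.1]), y)
        random_ish = ROCCurve.from_scores(np.array([0.9, 0.3, 0.7, 0.8, 0.2, 0.6]), y)
        avg = threshold_average_roc([perfect, random_ish])
        grid = avg.thresholds
        t_perfect = perfect.at_thresholds(grid)[1]
        t_rand = random_ish.at_thresholds(grid)[1]
        assert (avg.tpr <= np.maximum(t_perfect, t_rand) + 1e-12).all()
        assert (avg.tpr >= np.minimum(t_perfect, t_rand) - 1e-12).all()

    def test_averaged_auc_matches_trapezoid_oracle(self):
        rng = np.random.default_rng(4)
        curves = []
        for _ in range(3):
            y = rng.integers(0, 2, size=20)
            y[:2] = [0, 1]
            curves.append(ROCCurve.from_scores(rng.random(20), y))
        avg = threshold_average_roc(curves)
        # independent trapezoid integration over the averaged points
        oracle = 0.0
        for i in range(1, len(avg.fpr)):
            oracle += (avg.fpr[i] - avg.fpr[i - 1]) * (avg.tpr[i] + avg.tpr[i - 1]) / 2
        assert avg.auc == pytest.approx(oracle, abs=1e-9)


class TestOptimalCutoff:
    def test_separated_scores_take_the_gap_midpoint(self):
        scores = np.array([0.9, 0.8, 0.4, 0.3, 0.2])
        y = np.array([1, 1, 0, 0, 0])
        cutoff = optimal_cutoff(scores, y)
        assert 0.4 < cutoff <= 0.8
        assert cutoff == pytest.approx(0.6)

    def test_identical_scores_return_the_minimum(self):
        assert optimal_cutoff(np.full(4, 0.5), np.array([1, 0, 1, 0])) == 0.5

    def test_prefers_the_most_sensitive_tie(self):
        scores = np.array([0.9, 0.5, 0.5, 0.1])
        y = np.array([1, 1, 0, 0])
        cutoff = optimal_cutoff(scores, y)
        # J is maximal both at >=0.9 and >=0.5-ish regions; lower wins
        assert cutoff < 0.9


class TestNestedCV:
    def test_fixed_perfect_single_gene_signature_is_perfect(self, small_sim):
        matrix, labels, truth = small_sim
        planted = sorted(truth.genes_with_role("primary_specific"))[0]
        sig = ts.Signature([planted], [1.0], {"method": "fixed"})
        report = nested_cv_evaluate(matrix, labels, sig, algorithms=["wv"], seed=0)
        assert report.per_classifier["wv"].mean_auc == pytest.approx(1.0)

    def test_sr_source_separates_strongly(self, small_sim):
        matrix, labels, _ = small_sim
        report = nested_cv_evaluate(
            matrix, labels, "sr", algorithms=["pam", "wv", "rf"], seed=0
        )
        for name in ("pam", "wv", "rf"):
            assert report.per_classifier[name].mean_auc >= 0.9
        assert "Nested cross-validation" in report.summary()
        table = report.auc_table()
        assert set(table["algorithm"]) == {"pam", "wv", "rf"}

    def test_no_leakage_from_outer_test_compounds(self, small_sim):
        matrix, labels, _ = small_sim
        train_ids = matrix.compound_ids[:7] + matrix.compound_ids[9:16]
        test_ids = matrix.compound_ids[7:9] + matrix.compound_ids[16:]
        # corrupt the held-out compounds' values entirely
        corrupted_values = matrix.values.copy()
        cols = [matrix.compound_ids.index(c) for c in test_ids]
        corrupted_values[:, cols] = 123.0
        corrupted = ts.FoldChangeMatrix.from_arrays(
            corrupted_values, matrix.gene_ids, matrix.compound_ids
        )
        fold_a = evaluate_fold(matrix, labels, train_ids, test_ids, "sr",
                               ["wv", "pam"], seed=3)
        fold_b = evaluate_fold(corrupted, labels, train_ids, test_ids, "sr",
                               ["wv", "pam"], seed=3)
        assert fold_a["signature"].gene_ids == fold_b["signature"].gene_ids
        for algorithm in ("wv", "pam"):
            clf_a = fold_a["algorithms"][algorithm]["classifier"]
            clf_b = fold_b["algorithms"][algorithm]["classifier"]
            sa = clf_a.score_compounds(matrix, test_ids)
            sb = clf_b.score_compounds(matrix, test_ids)
            assert np.allclose(sa.to_numpy(), sb.to_numpy(), atol=1e-12)
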