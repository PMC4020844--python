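"""Specificity Ratio: absolute fold-change stats, shrinkage, ROC filter."""

import numpy as np
import pandas as pd
import pytest

import toxsig as ts
from toxsig.sr import (
    SRConfig,
    extract_sr_signature,
    gene_roc_scores,
    mean_abs_foldchange,
    shrink_standard_deviations,
    specificity_scores,
)


def _matrix(rows, genes, compounds):
    return ts.FoldChangeMatrix.from_arrays(np.asarray(rows, float), genes, compounds)


def _labels(compounds, n_primary):
    return ts.CompoundLabelSet(
        {c: ("NGC" if i < n_primary else "NC") for i, c in enumerate(compounds)}
    )


def _loop_shrinkage(x):
    """Independent re-implementation of the shrink-t pooling, plain loops."""
    x = np.asarray(x, float)
    n = x.shape[1]
    v = np.array([np.var(row, ddof=1) for row in x])
    v0 = float(np.median(v))
    var_hat = []
    for row in x:
        w = (row - row.mean()) ** 2
        var_hat.append(n / (n - 1) ** 3 * ((w - w.mean()) ** 2).sum())
    denom = ((v - v0) ** 2).sum()
    lam = 1.0 if denom == 0 else min(1.0, sum(var_hat) / denom)
    sd_star = np.sqrt(lam * v0 + (1 - lam) * v)
    return v, v0, lam, sd_star


class TestMeanAbs:
    def test_sign_blind_mean(self):
        matrix = _matrix([[2.0, -2.0, 2.0, 0.0, 0.0, 0.0]], ["g1"], list("abcdef"))
        stats = mean_abs_foldchange(matrix, _labels(list("abcdef"), 3))
        assert stats.mean_abs_primary["g1"] == pytest.approx(2.0)

    def test_zero_gene(self):
        matrix = _matrix([[0.0] * 6], ["g1"], list("abcdef"))
        stats = mean_abs_foldchange(matrix, _labels(list("abcdef"), 3))
        assert stats.mean_abs_primary["g1"] == 0.0
        assert stats.var_abs_primary["g1"] == 0.0

    def test_hand_sample_variance(self):
        matrix = _matrix([[0.1, 0.2, 0.3, 0.0, 0.0, 0.0]], ["g1"], list("abcdef"))
        stats = mean_abs_foldchange(matrix, _labels(list("abcdef"), 3))
        assert stats.mean_abs_primary["g1"] == pytest.approx(0.2)
        assert stats.var_abs_primary["g1"] == pytest.approx(0.01)


class TestShrinkage:
    def test_hand_worked_example(self):
        abs_fc = pd.DataFrame(
            [[0.1, 0.2, 0.3], [1.0, 2.0, 3.0], [0.5, 0.5, 0.5]],
            index=["g1", "g2", "g3"],
        )
        sh = shrink_standard_deviations(abs_fc)
        assert sh.target == pytest.approx(0.01)
        assert sh.pooling == pytest.approx(0.250025 / 0.9802, abs=1e-10)
        assert sh.sd_star["g2"] == pytest.approx(
            np.sqrt(sh.pooling * 0.01 + (1 - sh.pooling) * 1.0), abs=1e-12
        )
        assert sh.sd_star["g2"] == pytest.approx(0.8646, abs=1e-4)

    def test_identical_variances_fully_pool(self):
        abs_fc = pd.DataFrame(
            [[0.1, 0.2, 0.3], [1.1, 1.2, 1.3]], index=["g1", "g2"]
        )
        sh = shrink_standard_deviations(abs_fc)
        assert sh.pooling == 1.0
        assert np.allclose(sh.sd_star, np.sqrt(sh.target))

    def test_two_compound_class_forces_full_pooling(self):
        abs_fc = pd.DataFrame([[0.1, 0.5], [1.0, 3.0]], index=["g1", "g2"])
        sh = shrink_standard_deviations(abs_fc)
        assert sh.forced and sh.pooling == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_reimplementation(self, seed):
        rng = np.random.default_rng(seed)
        x = np.abs(rng.normal(size=(60, 7)))
        sh = shrink_standard_deviations(pd.DataFrame(x))
        v, v0, lam, sd_star = _loop_shrinkage(x)
        assert sh.pooling == pytest.approx(lam, abs=1e-10)
        assert np.allclose(sh.sd_star.to_numpy(), sd_star, atol=1e-10)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_moderated_variance_is_a_convex_combination(self, seed):
        rng = np.random.default_rng(seed)
        x = np.abs(rng.normal(size=(40, 5)))
        sh = shrink_standard_deviations(pd.DataFrame(x))
        assert 0.0 <= sh.pooling <= 1.0
        var_star = sh.sd_star.to_numpy() ** 2
        lo = np.minimum(sh.variances.to_numpy(), sh.target)
        hi = np.maximum(sh.variances.to_numpy(), sh.target)
        assert ((var_star >= lo - 1e-12) & (var_star <= hi + 1e-12)).all()


class TestSpecificityScores:
    def test_formula_composition(self, small_sim):
        matrix, labels, _ = small_sim
        sub = matrix.subset_genes(matrix.gene_ids[:50])
        spec = specificity_scores(sub, labels)
        stats = mean_abs_foldchange(sub, labels)
        expected = (stats.mean_abs_primary - stats.mean_abs_secondary) / (
            spec.shrinkage_primary.sd_star + spec.shrinkage_secondary.sd_star
        )
        assert np.allclose(spec.scores.to_numpy(), expected.to_numpy(), atol=1e-12)

    def test_secondary_specific_gene_scores_negative(self):
        matrix = _matrix(
            [[0.05, -0.02, 0.01, 2.0, -2.2, 1.9],
             [0.5, -0.4, 0.3, 0.2, -0.5, 0.4]],
            ["confounder", "noise"],
            list("abcdef"),
        )
        spec = specificity_scores(matrix, _labels(list("abcdef"), 3))
        assert spec.scores["confounder"] < 0.0

    def test_equal_deregulation_scores_zero(self):
        matrix = _matrix(
            [[1.0, 1.2, 0.8, -1.0, -1.2, -0.8],
             [0.5, 0.1, 0.3, 0.2, 0.4, 0.6]],
            ["shared", "noise"],
            list("abcdef"),
        )
        spec = specificity_scores(matrix, _labels(list("abcdef"), 3))
        assert spec.scores["shared"] == pytest.approx(0.0, abs=1e-12)

    def test_scale_equivariance_of_ranking_and_filter(self, small_sim):
        matrix, labels, _ = small_sim
        sub = matrix.subset_genes(matrix.gene_ids[:80])
        scaled = ts.FoldChangeMatrix.from_arrays(
            sub.values * 3.7, sub.gene_ids, sub.compound_ids
        )
        a = specificity_scores(sub, labels).scores
        b = specificity_scores(scaled, labels).scores
        assert list(a.sort_values(ascending=False).index) == list(
            b.sort_values(ascending=False).index
        )
        qa = gene_roc_scores(sub, labels)["q"]
        qb = gene_roc_scores(scaled, labels)["q"]
        assert np.allclose(qa.to_numpy(), qb.to_numpy())


class TestGeneROC:
    def test_consistent_downregulation_scores_zero(self):
        matrix = _matrix(
            [[-2.0, -1.5, -1.8, 0.1, -0.2, 0.0, 0.3]],
            ["g1"],
            [f"c{i}" for i in range(7)],
        )
        roc = gene_roc_scores(matrix, _labels(matrix.compound_ids, 3))
        assert roc.loc["g1", "auc"] == 0.0
        assert roc.loc["g1", "q"] == 1.0

    def test_tied_distributions_score_half(self):
        matrix = _matrix([[0.5, -0.5, 0.5, -0.5]], ["g1"], list("abcd"))
        roc = gene_roc_scores(matrix, _labels(list("abcd"), 2))
        assert roc.loc["g1", "auc"] == pytest.approx(0.5)
        assert roc.loc["g1", "q"] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.choice([-1.0, -0.5, 0.0, 0.5, 1.0], size=(25, 9))  # many ties
        matrix = _matrix(values, [f"g{i}" for i in range(25)],
                         [f"c{i}" for i in range(9)])
        labels = _labels(matrix.compound_ids, 4)
        roc = gene_roc_scores(matrix, labels)
        for g in range(25):
            f1, f2 = values[g, :4], values[g, 4:]
            wins = sum((a > b) + 0.5 * (a == b) for a in f1 for b in f2)
            assert roc.iloc[g]["auc"] == pytest.approx(wins / 20.0, abs=1e-9)

    def test_null_genes_average_half(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=(2000, 20))
        matrix = _matrix(values, [f"g{i}" for i in range(2000)],
                         [f"c{i}" for i in range(20)])
        roc = gene_roc_scores(matrix, _labels(matrix.compound_ids, 9))
        assert roc["auc"].mean() == pytest.approx(0.5, abs=0.02)


class TestExtraction:
    def test_half_cutoff_is_a_no_op(self, small_sim):
        matrix, labels, _ = small_sim
        sig = extract_sr_signature(
            matrix, labels, SRConfig(preselect_n=40, roc_cutoff=0.5)
        )
        assert len(sig) == 40

    def test_maximal_cutoff_keeps_only_perfect_separators(self, small_sim):
        matrix, labels, truth = small_sim
        sig = extract_sr_signature(
            matrix, labels, SRConfig(preselect_n=100, roc_cutoff=1.0)
        )
        roc = gene_roc_scores(matrix, labels)
        assert (roc.loc[sig.gene_ids, "q"] == 1.0).all()

    def test_filter_removes_inconsistent_decoys_keeps_planted(self, small_sim):
        matrix, labels, truth = small_sim
        sig = extract_sr_signature(matrix, labels, SRConfig(preselect_n=100))
        chosen = set(sig.gene_ids)
        assert not chosen & truth.genes_with_role("inconsistent")
        planted = truth.genes_with_role("primary_specific")
        assert len(chosen & planted) >= 45

    def test_empty_after_filter_advises_lower_cutoff(self):
        rng = np.random.default_rng(0)
        matrix = _matrix(rng.normal(0, 0.1, size=(30, 20)),
                         [f"g{i}" for i in range(30)],
                         [f"c{i}" for i in range(20)])
        labels = _labels(matrix.compound_ids, 9)
        with pytest.raises(ValueError, match="lower roc_cutoff"):
            extract_sr_signature(matrix, labels, SRConfig(preselect_n=5,
                                                          roc_cutoff=1.0))

    def test_provenance_records_pooling_and_cutoff(self, small_sim):
        matrix, labels, _ = small_sim
        result = ts.SpecificityRatio(matrix, labels).fit()
        prov = result.signature.provenance
        assert prov["roc_cutoff"] == 0.9
        assert 0.0 <= prov["lambda_primary"] <= 1.0
        assert "Specificity Ratio" in result.summary()
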