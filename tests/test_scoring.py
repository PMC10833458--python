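import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from autonomy.io import ExpressionMatrix, GeneSignature
from autonomy.scoring import (composite_score, modified_zscore, roc_auc,
                              score_and_classify, welch_t)
from autonomy.simulate import SimConfig, simulate_expression
from oracles import pair_count_auc, welch_textbook


class TestModifiedZscore:
    def test_centred_at_threshold(self):
        assert modified_zscore(3.0, sthr=3.0, stddev=1.0) == 0.0

    def test_three_sd_above_threshold_is_one(self):
        assert modified_zscore(3.0 + 3 * 0.7, sthr=3.0, stddev=0.7) == pytest.approx(1.0)

    def test_direct_formula(self):
        assert modified_zscore(5.0, sthr=3.0, stddev=1.0) == pytest.approx(2 / 3)

    def test_zero_stddev_rejected(self):
        with pytest.raises(ValueError):
            modified_zscore(1.0, sthr=0.0, stddev=0.0)

    def test_shift_invariance_through_threshold(self, rng):
        # shifting all of a gene's values shifts SThr with them: z unchanged
        from autonomy.stepminer import gene_threshold

        vals = rng.normal(4, 1, size=20)
        for shift in (0.0, 5.0, -2.5):
            m = ExpressionMatrix(values=pd.DataFrame(
                [vals + shift], index=["g"], columns=[f"s{i}" for i in range(20)]))
            z = modified_zscore(vals + shift, gene_threshold(m, "g"),
                                np.std(vals + shift, ddof=1))
            if shift == 0.0:
                base = z
            np.testing.assert_allclose(z, base, atol=1e-10)


class TestCompositeScore:
    def test_signed_subtraction_of_down_genes(self, tiny_matrix, two_gene_signature):
        signed = composite_score(tiny_matrix, two_gene_signature, mode="signed")
        total = composite_score(tiny_matrix, two_gene_signature, mode="sum_all")
        from autonomy.scoring import gene_zscores

        z1 = gene_zscores(tiny_matrix, "g1")
        z2 = gene_zscores(tiny_matrix, "g2")
        np.testing.assert_allclose(signed.to_numpy(), z1 - z2)
        np.testing.assert_allclose(total.to_numpy(), z1 + z2)

    def test_single_gene_signature_is_that_genes_zscores(self, tiny_matrix):
        from autonomy.scoring import gene_zscores

        sig = GeneSignature(name="one", entries=[("g1", 1)])
        np.testing.assert_allclose(
            composite_score(tiny_matrix, sig).to_numpy(),
            gene_zscores(tiny_matrix, "g1"))

    def test_flipping_every_direction_negates_signed_score(self, tiny_matrix):
        sig = GeneSignature(name="s", entries=[("g1", 1), ("g2", -1), ("g4", 1)])
        flipped = GeneSignature(name="f", entries=[("g1", -1), ("g2", 1), ("g4", -1)])
        np.testing.assert_allclose(
            composite_score(tiny_matrix, sig).to_numpy(),
            -composite_score(tiny_matrix, flipped).to_numpy())

    def test_missing_genes_dropped_with_warning(self, tiny_matrix, caplog):
        sig = GeneSignature(name="s", entries=[("g1", 1), ("absent", 1)])
        with caplog.at_level("WARNING"):
            scores = composite_score(tiny_matrix, sig)
        assert "absent" in caplog.text
        assert len(scores) == 4

    def test_all_genes_missing_is_an_error(self, tiny_matrix):
        sig = GeneSignature(name="s", entries=[("x", 1), ("y", -1)])
        with pytest.raises(ValueError, match="no usable genes"):
            composite_score(tiny_matrix, sig)

    def test_planted_signature_separates_groups(self):
        wins = 0
        for seed in range(30):
            m, sig, groups = simulate_expression(SimConfig(seed=seed, n_genes=100))
            scores = composite_score(m, sig)
            if (scores[groups == "autonomous"].mean()
                    > scores[groups == "control"].mean()):
                wins += 1
        assert wins == 30


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_inverted_labels_give_zero(self):
        assert roc_auc([1, 2, 3, 4], [1, 1, 0, 0]) == 0.0

    def test_ties_counted_half(self):
        assert roc_auc([1, 1, 2], [0, 1, 1]) == pytest.approx(
            pair_count_auc([1, 1, 2], [0, 1, 1]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.integers(2, 12), st.integers(0, 2 ** 32 - 1))
    def test_equals_pair_enumeration(self, n, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 5, size=n).astype(float)  # many ties
        labels = np.zeros(n, dtype=int)
        labels[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
        if labels.sum() in (0, n):
            return
        assert roc_auc(scores, labels) == pytest.approx(
            pair_count_auc(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=20)
        labels = (rng.random(20) < 0.5).astype(int)
        if labels.sum() in (0, 20):
            labels[0] = 1 - labels[0]
        base = roc_auc(scores, labels)
        assert roc_auc(np.exp(scores), labels) == pytest.approx(base)
        assert roc_auc(3 * scores + 7, labels) == pytest.approx(base)


class TestWelchT:
    def test_identical_groups(self):
        t, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == 1.0

    def test_matches_textbook_formula(self):
        t, p = welch_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        t_ref, df_ref, p_ref = welch_textbook([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(t_ref)
        assert p == pytest.approx(p_ref)
        assert df_ref == pytest.approx(4.0)  # equal variances, equal n

    def test_antisymmetric_in_group_order(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(1, 2, 15)
        t_xy, p_xy = welch_t(x, y)
        t_yx, p_yx = welch_t(y, x)
        assert t_xy == pytest.approx(-t_yx)
        assert p_xy == pytest.approx(p_yx)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [2.0, 3.0])


class TestScoreAndClassify:
    def test_planted_signature_auc(self):
        m, sig, _ = simulate_expression(SimConfig(seed=11))
        report = score_and_classify(m, sig, "group", positive="autonomous")
        assert report.auc >= 0.95
        assert report.direction == "up"
        assert report.p < 1e-6

    def test_missing_signature_errors(self, tiny_matrix):
        sig = GeneSignature(name="s", entries=[("zz", 1)])
        with pytest.raises(ValueError, match="zz"):
            score_and_classify(tiny_matrix, sig, "group")

    def test_sample_permutation_invariance(self):
        m, sig, _ = simulate_expression(SimConfig(seed=5, n_genes=80,
                                                  n_per_group=10))
        report = score_and_classify(m, sig, "group", positive="autonomous")
        perm = np.random.default_rng(0).permutation(m.n_samples)
        shuffled = ExpressionMatrix(
            values=m.values.iloc[:, perm],
            annotations=m.annotations)
        report2 = score_and_classify(shuffled, sig, "group", positive="autonomous")
        assert report2.auc == pytest.approx(report.auc)
        assert report2.t == pytest.approx(report.t)
        assert report2.p == pytest.approx(report.p)

    def test_ordering_sorts_scores(self):
        m, sig, _ = simulate_expression(SimConfig(seed=3, n_genes=60,
                                                  n_per_group=8))
        report = score_and_classify(m, sig, "group")
        ordered = report.scores.loc[report.ordering].to_numpy()
        assert np.all(np.diff(ordered) >= 0)
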