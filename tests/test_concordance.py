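"""Binary recoding, Cohen's kappa and McNemar's test for predictor pairs."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

import mutclust as mc
from mutclust.concordance import RatingMatrix

SCHEME = {
    "Tolerated": "benign",
    "Neutral": "benign",
    "Probably Damaging": "effect",
    "Disease Causing": "effect",
    "Deleterious": "effect",
}


def matrix_from(calls: dict, scheme=SCHEME) -> RatingMatrix:
    return RatingMatrix(calls=pd.DataFrame(calls), scheme=scheme)


class TestRecode:
    def test_vocabulary_maps_to_binary(self):
        m = matrix_from(
            {"A": ["Probably Damaging", "Tolerated"], "B": ["Disease Causing", "Neutral"]}
        )
        binary = mc.recode_binary(m)
        assert binary["A"].tolist() == [1.0, 0.0]
        assert binary["B"].tolist() == [1.0, 0.0]

    def test_unmapped_label_raises_with_name(self):
        m = matrix_from({"A": ["Mystery Call"]})
        with pytest.raises(KeyError, match="Mystery Call"):
            mc.recode_binary(m)

    def test_missing_calls_stay_missing(self):
        m = matrix_from({"A": ["Tolerated", None], "B": [None, "Deleterious"]})
        binary = mc.recode_binary(m)
        assert binary.isna().sum().sum() == 2

    def test_all_missing_column_excluded_from_pairs(self):
        m = matrix_from(
            {
                "A": ["Tolerated", "Deleterious"],
                "B": ["Tolerated", "Deleterious"],
                "C": [None, None],
            }
        )
        pairs = mc.pairwise_concordance(m)
        assert {(p.rater_a, p.rater_b) for p in pairs} == {("A", "B")}


class TestKappa:
    def test_perfect_agreement_with_mixed_marginals(self):
        assert mc.cohen_kappa(5, 0, 0, 5) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # p_o = 0.8, p_e = 0.52 -> kappa = 0.28/0.48
        assert mc.cohen_kappa(25, 5, 5, 15) == pytest.approx(0.28 / 0.48)

    def test_independence_structured_table_is_zero(self):
        assert mc.cohen_kappa(9, 21, 21, 49) == pytest.approx(0.0)

    def test_undefined_when_chance_agreement_is_one(self):
        assert mc.cohen_kappa(10, 0, 0, 0) is None

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a, b, c, d = rng.integers(0, 10, size=4)
            if a + b + c + d == 0:
                continue
            assert mc.cohen_kappa(a, b, c, d) == mc.cohen_kappa(a, c, b, d)

    def test_matches_sklearn_on_reconstructed_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 8, size=4)
            va = [1] * (a + b) + [0] * (c + d)
            vb = [1] * a + [0] * b + [1] * c + [0] * d
            assert mc.cohen_kappa(a, b, c, d) == pytest.approx(
                cohen_kappa_score(va, vb)
            )

    def test_empty_table_is_an_error(self):
        with pytest.raises(ValueError):
            mc.cohen_kappa(0, 0, 0, 0)


class TestMcNemar:
    def test_single_discordant_pair(self):
        stat, p = mc.mcnemar_test(1, 0)
        assert stat == pytest.approx(1.0)
        assert p == pytest.approx(0.3173, abs=5e-5)

    def test_two_against_one(self):
        stat, p = mc.mcnemar_test(2, 1)
        assert stat == pytest.approx(1 / 3)
        assert p == pytest.approx(0.5637, abs=5e-5)

    def test_balanced_discordance_is_null(self):
        for k in (1, 4, 25):
            stat, p = mc.mcnemar_test(k, k)
            assert stat == 0.0 and p == pytest.approx(1.0)

    def test_not_computable_without_discordance(self):
        assert mc.mcnemar_test(0, 0) == (None, None)

    def test_symmetric_in_discordant_counts(self):
        for b, c in [(3, 7), (1, 9), (12, 5)]:
            assert mc.mcnemar_test(b, c) == mc.mcnemar_test(c, b)

    def test_chi2_closed_form_for_all_small_tables(self):
        """Statsmodels (asymptotic, uncorrected) agrees to 4 decimals for b+c <= 50."""
        for b in range(0, 51):
            for c in range(0, 51 - b):
                if b + c == 0:
                    continue
                stat, p = mc.mcnemar_test(b, c)
                ref = sm_mcnemar(
                    [[0, b], [c, 0]], exact=False, correction=False
                )
                assert stat == pytest.approx(float(ref.statistic), abs=1e-10)
                assert p == pytest.approx(float(ref.pvalue), abs=1e-4)


class TestPairwise:
    def test_identical_raters(self):
        m = matrix_from(
            {
                "A": ["Deleterious"] * 6 + ["Tolerated"] * 4,
                "B": ["Deleterious"] * 6 + ["Tolerated"] * 4,
            }
        )
        (pair,) = mc.pairwise_concordance(m)
        assert pair.kappa == pytest.approx(1.0)
        assert pair.percent_agreement == pytest.approx(1.0)
        assert pair.mcnemar_stat is None  # no discordant pairs

    def test_three_raters_emit_three_pairs(self):
        calls = {r: ["Deleterious", "Tolerated"] for r in "ABC"}
        pairs = mc.pairwise_concordance(matrix_from(calls))
        assert [(p.rater_a, p.rater_b) for p in pairs] == [
            ("A", "B"), ("A", "C"), ("B", "C"),
        ]

    def test_generator_agreement_is_recovered(self):
        a, b = mc.simulate_rating_pairs(
            4000, mc.RaterModel(0.6, 0.6, 0.8), seed=13
        )
        labels = np.array(["Tolerated", "Deleterious"])
        m = matrix_from({"A": labels[a], "B": labels[b]})
        (pair,) = mc.pairwise_concordance(m)
        se = np.sqrt(0.8 * 0.2 / 4000)
        assert abs(pair.percent_agreement - 0.8) < 4 * se

    def test_single_rater_is_an_error(self):
        with pytest.raises(ValueError, match="two raters"):
            mc.pairwise_concordance(matrix_from({"A": ["Tolerated"]}))
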