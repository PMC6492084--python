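"""Accuracy rates, exact McNemar, Cohen's kappa, bands and Walker posteriors."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteoconcord.concordance import (ConfusionSummary, accuracy_rates,
                                      agreement_band, cohens_kappa,
                                      confusion_summary, mcnemar_chi2,
                                      mcnemar_exact, per_trait_confusions,
                                      prob_female_given_score,
                                      rates_from_counts, round_half_up,
                                      score_distribution)
from osteoconcord.traits import TRAIT_CATALOG, SexCategory


def exact_mcnemar_oracle(b: int, c: int) -> float:
    """Two-sided p by full enumeration of the Binomial(b+c, 1/2) support."""
    n = b + c
    if n == 0:
        return 1.0
    center = n / 2.0
    p = sum(math.comb(n, k) for k in range(n + 1)
            if abs(k - center) >= abs(b - center) - 1e-12) / 2.0**n
    return min(1.0, p)


class TestConfusionSummary:
    def test_tally_with_collapse_and_indeterminate(self):
        macro = {f"f{i}": SexCategory.F for i in range(14)}
        macro["f14"] = SexCategory.PF          # collapses to F
        macro["fwrong"] = SexCategory.M
        macro["famb"] = SexCategory.I
        macro.update({f"m{i}": SexCategory.M for i in range(29)})
        genetic = {s: ("F" if s.startswith("f") else "M") for s in macro}
        cs = confusion_summary(macro, genetic)
        assert cs.female == (15, 1, 1)
        assert cs.male == (29, 0, 0)
        assert cs.table_2x2.tolist() == [[15, 1], [0, 29]]
        assert cs.discordant == (1, 0)

    def test_all_indeterminate_gives_zero_table(self):
        macro = {"a": SexCategory.I, "b": SexCategory.I}
        cs = confusion_summary(macro, {"a": "F", "b": "M"})
        assert cs.table_2x2.sum() == 0

    def test_empty_intersection_is_error(self):
        with pytest.raises(ValueError):
            confusion_summary({"a": SexCategory.F}, {"b": "F"})


class TestAccuracyRates:
    @pytest.mark.parametrize("counts,acc,raw", [
        ((45, 2, 2), 95.7, 91.8),
        ((48, 2, 2), 96.0, 92.3),
        ((40, 14, 1), 97.6, 72.7),
    ])
    def test_reference_rates(self, counts, acc, raw):
        rep = rates_from_counts(*counts)
        assert round_half_up(rep.accuracy, 1) == acc
        assert round_half_up(rep.raw_accuracy, 1) == raw

    def test_all_indeterminate(self):
        rep = rates_from_counts(0, 5, 0)
        assert math.isnan(rep.accuracy)
        assert rep.raw_accuracy == 0.0

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_accuracy_dominates_raw(self, correct, indet, incorrect):
        if correct + indet + incorrect == 0:
            return
        rep = rates_from_counts(correct, indet, incorrect)
        if correct + incorrect == 0:
            assert math.isnan(rep.accuracy)
        elif indet == 0:
            assert rep.accuracy == rep.raw_accuracy
        else:
            assert rep.accuracy >= rep.raw_accuracy

    def test_sex_weighted_pooling(self):
        cs = ConfusionSummary(female=(8, 0, 2), male=(30, 0, 0))
        rates = accuracy_rates(cs, weighting="sex_weighted")
        assert rates["pooled"].accuracy == pytest.approx((80 + 100) / 2)
        unweighted = accuracy_rates(cs)["pooled"].accuracy
        assert unweighted == pytest.approx(95.0)


class TestMcNemar:
    @pytest.mark.parametrize("b,c,p", [(2, 0, 0.5), (5, 1, 0.21875),
                                       (3, 3, 1.0), (0, 0, 1.0)])
    def test_examples(self, b, c, p):
        assert mcnemar_exact(b, c) == pytest.approx(p)

    def test_symmetry_and_enumeration_oracle(self):
        for b in range(13):
            for c in range(13 - b):
                p = mcnemar_exact(b, c)
                assert p == pytest.approx(mcnemar_exact(c, b))
                assert p == pytest.approx(exact_mcnemar_oracle(b, c))
                assert 0.0 <= p <= 1.0

    def test_against_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        for b, c in [(2, 0), (5, 1), (7, 3), (0, 4)]:
            table = [[0, b], [c, 0]]
            expected = sm_mcnemar(table, exact=True).pvalue
            assert mcnemar_exact(b, c) == pytest.approx(expected)

    def test_chi2_variant(self):
        assert mcnemar_chi2(30, 10) < 0.01
        assert mcnemar_chi2(0, 0) == 1.0


class TestKappa:
    @pytest.mark.parametrize("table,k", [
        ([[16, 2], [0, 28]], 0.907),
        ([[15, 5], [1, 31]], 0.747),
        ([[18, 0], [1, 22]], 0.951),
        ([[10, 0], [0, 10]], 1.0),
    ])
    def test_reference_tables(self, table, k):
        assert round_half_up(cohens_kappa(table), 3) == k

    def test_zero_on_product_of_marginals(self):
        # independence tables built exactly as outer products
        for r, c in [((2, 3), (4, 1)), ((1, 1), (1, 1)), ((5, 2), (3, 3))]:
            table = np.outer(r, c)
            assert cohens_kappa(table) == pytest.approx(0.0, abs=1e-12)

    def test_label_swap_invariance(self):
        t = np.array([[16, 2], [5, 28]])
        swapped = t[::-1, ::-1]
        assert cohens_kappa(t) == pytest.approx(cohens_kappa(swapped))

    def test_against_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        t = np.array([[16, 2], [1, 28]])
        y1 = [0] * 18 + [1] * 29
        y2 = [0] * 16 + [1] * 2 + [0] * 1 + [1] * 28
        assert cohens_kappa(t) == pytest.approx(cohen_kappa_score(y1, y2))

    def test_degenerate_single_cell(self):
        assert math.isnan(cohens_kappa([[5, 0], [0, 0]]))
        with pytest.raises(ValueError):
            cohens_kappa([[0, 0], [0, 0]])


class TestBands:
    @pytest.mark.parametrize("k,band", [
        (0.907, "almost perfect"), (0.747, "substantial"), (-0.5, "poor"),
        (0.0, "slight"), (0.20, "slight"), (0.205, "fair"), (0.41, "moderate"),
        (0.60, "moderate"), (0.605, "substantial"), (0.80, "substantial"),
        (0.805, "almost perfect"), (1.0, "almost perfect"),
    ])
    def test_cut_points_on_two_decimal_grid(self, k, band):
        assert agreement_band(k) == band


class TestWalkerPosterior:
    @pytest.mark.parametrize("pf,pm,expected", [
        (52.6, 7.4, 0.88), (5.3, 29.6, 0.15), (10.0, 0.0, 1.0),
    ])
    def test_examples(self, pf, pm, expected):
        assert round_half_up(prob_female_given_score(pf, pm), 2) == expected

    def test_complement_sums_to_one(self):
        for pf, pm in [(52.6, 7.4), (1.0, 99.0), (33.3, 33.3)]:
            assert (prob_female_given_score(pf, pm)
                    + prob_female_given_score(pm, pf)) == pytest.approx(1.0)

    def test_undefined_when_no_mass(self):
        assert math.isnan(prob_female_given_score(0.0, 0.0))


class TestScoreDistribution:
    def test_percentage_rows(self):
        scores = pd.DataFrame({
            "sample_id": [f"f{i}" for i in range(19)],
            "trait": "sciatic_notch",
            "harmonized": [1] * 5 + [2] * 10 + [3] * 3 + [5] * 1,
        })
        genetic = {s: "F" for s in scores["sample_id"]}
        dist = score_distribution(scores, genetic)
        f = dist.set_index("score")["pct_female"]
        assert f[1] == pytest.approx(100 * 5 / 19)
        assert f[2] == pytest.approx(100 * 10 / 19)
        assert f[4] == 0.0
        assert dist["pct_male"].isna().all()  # no males observed
        assert dist["prob_female"].isna().all()

    def test_single_value_and_missing_sex(self):
        scores = pd.DataFrame({"sample_id": ["a", "b"],
                               "trait": "glabella", "harmonized": [3, 3]})
        dist = score_distribution(scores, {"a": "F", "b": "M"})
        row = dist[(dist["score"] == 3)]
        assert row["pct_female"].item() == 100.0
        assert row["pct_male"].item() == 100.0
        assert row["prob_female"].item() == pytest.approx(0.5)


def test_per_trait_confusions_roundtrip():
    scores = pd.DataFrame({
        "sample_id": ["a", "b", "c", "d"],
        "trait": "ventral_arc",
        "harmonized": [1, 5, 3, 5],
    })
    genetic = {"a": "F", "b": "F", "c": "M", "d": "M"}
    cs = per_trait_confusions(scores, genetic, TRAIT_CATALOG)["ventral_arc"]
    assert cs.female == (1, 0, 1)
    assert cs.male == (1, 1, 0)
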