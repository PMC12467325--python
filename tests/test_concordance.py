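"""Agreement statistics: kappa, dichotomisation, Spearman, Wilcoxon, Shapiro-Wilk."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from hsiquant import (
    PairedScores,
    build_report,
    cohen_kappa,
    dichotomise_allred,
    dichotomise_hscore,
    shapiro_wilk,
    spearman_rho,
    wilcoxon_signed_rank,
)
from hsiquant.concordance import (
    Dichotomy,
    agreement_table,
    wilcoxon_exact_enumeration,
)
from hsiquant import reference_data as ref


def _expand(table):
    """Contingency table -> paired label vectors."""
    a, b = [], []
    for i, row in enumerate(table):
        for j, count in enumerate(row):
            a += [i] * int(count)
            b += [j] * int(count)
    return np.array(a), np.array(b)


class TestCohenKappa:
    def test_study_table_gives_substantial_agreement(self):
        kappa, band = cohen_kappa(ref.TABLE1_COUNTS)
        assert kappa == pytest.approx(0.677, abs=0.001)
        assert band == "substantial"

    def test_perfect_agreement(self):
        kappa, band = cohen_kappa([[10, 0], [0, 10]])
        assert kappa == 1.0 and band == "near-perfect"

    def test_degenerate_concentrated_table(self):
        kappa, _ = cohen_kappa([[5, 0], [0, 0]])
        assert kappa == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa([[3, -1], [0, 2]])

    @given(st.lists(st.integers(0, 20), min_size=4, max_size=4))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_label_expansion_oracle_and_is_symmetric(self, counts):
        table = np.array(counts).reshape(2, 2)
        if table.sum() == 0:
            return
        kappa, _ = cohen_kappa(table)
        kappa_t, _ = cohen_kappa(table.T)
        assert kappa == pytest.approx(kappa_t, abs=1e-12)  # symmetry
        a, b = _expand(table)
        if len(np.unique(np.concatenate([a, b]))) > 1:
            expected = cohen_kappa_score(a, b)
            if not np.isnan(expected):
                assert kappa == pytest.approx(expected, abs=1e-10)
        # kappa == 1 exactly when the off-diagonal is empty (non-degenerate Pe)
        po = np.trace(table) / table.sum()
        pe = (table.sum(1) * table.sum(0)).sum() / table.sum() ** 2
        if pe < 1 - 1e-12:
            assert (kappa == 1.0) == (table[0, 1] + table[1, 0] == 0)


class TestDichotomisation:
    @pytest.mark.parametrize("score,expected",
                             [(0, Dichotomy.LOW), (6, Dichotomy.LOW), (7, Dichotomy.HIGH),
                              (8, Dichotomy.HIGH)])
    def test_allred_split_at_six_seven(self, score, expected):
        assert dichotomise_allred(score) is expected

    def test_allred_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dichotomise_allred(9)

    def test_pooled_mean_reproduces_reference_category_columns(self):
        values = {m: ref.SIX_CASE_SCORES[f"h_{m}"].to_numpy()
                  for m in ("visual", "digital", "hsi")}
        cats = dichotomise_hscore(values, pooling="pooled_all")
        assert cats["visual"].tolist() == ref.PRINTED_CATEGORIES[("H", "visual")]
        assert cats["digital"].tolist() == ref.PRINTED_CATEGORIES[("H", "digital")]

    def test_equal_values_are_all_low(self):
        cats = dichotomise_hscore({"m": np.full(5, 150.0)})
        assert set(cats["m"]) == {int(Dichotomy.LOW)}


class TestSpearman:
    def test_identity_and_reversal(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        assert spearman_rho(x, x)[0] == pytest.approx(1.0)
        assert spearman_rho(x, -x)[0] == pytest.approx(-1.0)

    def test_ties_match_average_rank_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.integers(0, 5, 12).astype(float)
            y = rng.integers(0, 5, 12).astype(float)
            if np.unique(x).size < 2 or np.unique(y).size < 2:
                continue
            rho, _ = spearman_rho(x, y)
            oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
            assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_input_reports_undefined(self):
        rho, p = spearman_rho(np.ones(5), np.arange(5.0))
        assert np.isnan(rho) and np.isnan(p)


class TestWilcoxon:
    def test_identical_pairs_degenerate_convention(self):
        x = np.arange(6.0)
        assert wilcoxon_signed_rank(x, x) == (0.0, 1.0)

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(12):
            x = rng.integers(0, 8, 6).astype(float)  # small ints force ties
            y = rng.integers(0, 8, 6).astype(float)
            stat, p = wilcoxon_signed_rank(x, y, mode="exact")
            stat_o, p_o = wilcoxon_exact_enumeration(x, y)
            assert stat == stat_o
            assert p == pytest.approx(p_o, abs=1e-12)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(8):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            _, p = wilcoxon_signed_rank(x, y, mode="exact")
            expected = stats.wilcoxon(x, y, mode="exact").pvalue
            assert p == pytest.approx(expected, abs=1e-12)

    def test_six_case_visual_vs_digital_is_one_sided_extreme(self):
        """All six visual-digital differences share a sign, so exact p = 2/64."""
        x = ref.SIX_CASE_SCORES["h_visual"].to_numpy()
        y = ref.SIX_CASE_SCORES["h_digital"].to_numpy()
        _, p = wilcoxon_signed_rank(x, y, mode="exact")
        assert p == pytest.approx(2 / 64, abs=1e-12)

    def test_normal_approximation_close_to_exact_at_n15(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        _, p_exact = wilcoxon_signed_rank(x, y, mode="exact")
        _, p_approx = wilcoxon_signed_rank(x, y, mode="normal_approx")
        assert abs(p_exact - p_approx) < 0.05


class TestShapiroWilk:
    def test_skewed_mixture_rejected_normal_sample_not(self):
        rng = np.random.default_rng(4)
        skewed = np.concatenate([np.zeros(45), np.full(5, 10.0)])
        skewed += rng.normal(0, 1e-3, 50)
        assert shapiro_wilk(skewed)[1] < 0.05
        w, _ = shapiro_wilk(rng.normal(size=50))
        assert w > 0.9

    def test_contract_violations(self):
        with pytest.raises(ValueError):
            shapiro_wilk(np.array([1.0, 2.0]))
        w, p = shapiro_wilk(np.full(10, 3.0))
        assert np.isnan(w) and np.isnan(p)


class TestBuildReport:
    def test_self_comparison_is_perfect_agreement(self):
        h = PairedScores([1, 2, 3, 4], {"a": [10, 220, 300, 40], "b": [10, 220, 300, 40]}, "H")
        allred = PairedScores([1, 2, 3, 4], {"a": [2, 7, 8, 3], "b": [2, 7, 8, 3]}, "Allred")
        report = build_report(h, allred)
        for kappa, _band in report.kappa.values():
            assert kappa == 1.0
        for rho, _p in report.spearman.values():
            assert rho == pytest.approx(1.0)
        for _stat, p in report.wilcoxon.values():
            assert p == 1.0

    def test_reference_six_cases_reproduce_pairwise_kappas(self):
        methods = ("visual", "digital", "hsi")
        h = PairedScores(
            list(ref.SIX_CASE_SCORES.index),
            {m: ref.SIX_CASE_SCORES[f"h_{m}"].to_numpy() for m in methods},
            "H",
        )
        allred = PairedScores(
            list(ref.SIX_CASE_SCORES.index),
            {m: ref.SIX_CASE_SCORES[f"allred_{m}"].to_numpy() for m in methods},
            "Allred",
        )
        report = build_report(h, allred)
        assert report.kappa[("Allred", "visual", "digital")][0] == pytest.approx(0.40, abs=0.005)
        assert report.kappa[("Allred", "digital", "hsi")][0] == pytest.approx(0.40, abs=0.005)
        assert report.means[("H", "visual")] == pytest.approx(206.67, abs=0.01)
        frame = report.to_frame()
        assert len(frame) == 6  # three pairs x two score types

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            PairedScores([1, 2], {"a": [1.0, np.nan]})


class TestAgreementTable:
    def test_counts(self):
        table = agreement_table([1, 1, 2, 2], [1, 2, 2, 2], categories=[1, 2])
        np.testing.assert_array_equal(table, [[1, 1], [0, 2]])
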