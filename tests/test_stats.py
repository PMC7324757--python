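"""Comparative statistics: Holm, Dunnett, fold ratios, rank concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from qconpipe import (
    anova_dunnett,
    compare_to_recipient,
    holm_adjust,
    log2_fold_change,
    method_fold,
    rank_concordance,
)


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_down(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.04]), [0.02, 0.04])
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.02, 0.03]), [0.03, 0.04, 0.04]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(holm_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_matches_statsmodels_and_dominates_raw(self, pvals):
        ours = holm_adjust(pvals)
        theirs = multipletests(pvals, method="holm")[1]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)
        assert (ours >= np.asarray(pvals) - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


class TestLog2FoldChange:
    def test_identical_groups(self):
        assert log2_fold_change([2.0, 2.0], [2.0, 2.0]) == 0.0

    @pytest.mark.parametrize("fold, expected", [(3.0, 1.585), (2.0, 1.0)])
    def test_known_folds(self, fold, expected):
        base = [1.0, 1.1, 0.9]
        boosted = [fold * v for v in base]
        assert log2_fold_change(boosted, base) == pytest.approx(expected, abs=1e-3)

    def test_antisymmetric(self):
        a, b = [3.0, 3.3], [1.0, 1.2]
        assert log2_fold_change(a, b) == pytest.approx(-log2_fold_change(b, a))

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            log2_fold_change([0.0, 0.0], [1.0])


class TestDunnett:
    def test_identical_groups_give_p_one(self):
        g = [1.0, 2.0, 3.0]
        res = anova_dunnett([g, g, g], n_mc=5000, seed=0)
        assert (res.p_adjusted == 1.0).all()

    def test_single_treatment_reduces_to_t_test(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 6), rng.normal(0.8, 1, 6)
        res = anova_dunnett([a, b], n_mc=200_000, seed=1)
        t = sps.ttest_ind(b, a)
        assert res.p_adjusted[0] == pytest.approx(t.pvalue, abs=0.01)

    def test_matches_scipy_dunnett(self):
        rng = np.random.default_rng(12)
        control = rng.normal(0, 1, 8)
        t1, t2, t3 = (rng.normal(mu, 1, 8) for mu in (0.2, 1.0, 2.0))
        res = anova_dunnett([control, t1, t2, t3], n_mc=200_000, seed=2)
        ref = sps.dunnett(t1, t2, t3, control=control)
        np.testing.assert_allclose(res.p_adjusted, ref.pvalue, atol=0.01)

    def test_adjusted_p_monotone_in_t_and_above_raw(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(mu, 1, 5) for mu in (0.0, 0.3, 1.5, 3.0)]
        res = anova_dunnett(groups, n_mc=50_000, seed=4)
        order = np.argsort(np.abs(res.t_statistics))
        assert (np.diff(res.p_adjusted[order]) <= 0).all()
        # many-to-one adjustment can only inflate the marginal p
        raw_ps = [sps.ttest_ind(g, groups[0]).pvalue for g in groups[1:]]
        assert (res.p_adjusted >= np.array(raw_ps) - 0.02).all()

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            anova_dunnett([[1.0, 2.0]])


class TestMethodFold:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(658.5, 75.1, 8.8), (451.3, 13.1, 34.5), (5.0, 5.0, 1.0)],
    )
    def test_published_folds(self, a, b, expected):
        assert round(method_fold(a, b), 1) == expected

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.01, 1e4), st.floats(0.01, 1e4))
    def test_reciprocal_product_is_one(self, a, b):
        assert method_fold(a, b) * method_fold(b, a) == pytest.approx(1.0, rel=1e-12)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            method_fold(1.0, 0.0)


class TestRankConcordance:
    def test_identical_rankings(self):
        r = rank_concordance([1, 2, 3, 4], [1, 2, 3, 4])
        assert r.rho == pytest.approx(1.0)
        assert r.discordant_pairs == ()

    def test_exact_reversal(self):
        r = rank_concordance([1, 2, 3], [3, 2, 1], bottom_k=2)
        assert r.rho == pytest.approx(-1.0)

    def test_low_abundance_discordance_of_ibaq_ranking(self, table2):
        # the iBAQ ranking inverts the three least-abundant panel members
        r = rank_concordance(
            table2["rank_qconcat"],
            table2["rank_ibaq"],
            bottom_k=3,
            labels=list(table2["protein"]),
        )
        flat = {p for pair in r.discordant_pairs for p in pair}
        assert flat == {"RPE1", "RPI1", "TPI1"}
        assert r.rho > 0.9  # overall ranking agreement remains strong

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rank_concordance([1, 2], [1, 2, 3])


class TestCompareToRecipient:
    @pytest.fixture(scope="class")
    def strain_table(self):
        rng = np.random.default_rng(0)
        rows = []
        folds = {"UVM4": 1.0, "St1": 3.0, "HA5": 1.0}
        for protein, base in (("SBP1", 10.0), ("rbcL", 1000.0)):
            for strain, fold in folds.items():
                level = base * (fold if protein == "SBP1" else 1.0)
                for rep in range(1, 7):
                    rows.append(
                        {
                            "strain": strain,
                            "protein": protein,
                            "replicate": rep,
                            "value": level * rng.lognormal(0, 0.03),
                        }
                    )
        return pd.DataFrame(rows)

    def test_detects_only_the_overexpressed_protein(self, strain_table):
        out = compare_to_recipient(strain_table, control="UVM4", alpha=0.01)
        hit = out[(out["protein"] == "SBP1") & (out["strain"] == "St1")].iloc[0]
        assert hit["significant"]
        assert hit["log2_fc"] == pytest.approx(np.log2(3), abs=0.15)
        others = out[~((out["protein"] == "SBP1") & (out["strain"] == "St1"))]
        assert not others["significant"].any()

    def test_significance_flag_matches_alpha(self, strain_table):
        out = compare_to_recipient(strain_table, control="UVM4", alpha=0.01)
        assert (out["significant"] == (out["p_adjusted"] < 0.01)).all()

    def test_missing_control_rejected(self, strain_table):
        with pytest.raises(ValueError):
            compare_to_recipient(strain_table, control="nope")
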