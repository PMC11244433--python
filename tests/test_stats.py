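import itertools

import numpy as np
import pandas as pd
import pytest

from traitpart import (compact_letter_display, contribution_percentages,
                       one_way_anova, ss_decompose, tukey_hsd)


class TestOneWayAnova:
    def test_hand_example_significant(self):
        res = one_way_anova({"T1": [1, 2], "T2": [3, 4]})
        assert res.ss_between == pytest.approx(4.0)
        assert res.ss_within == pytest.approx(1.0)
        assert res.f_stat == pytest.approx(8.0)
        assert (res.df_between, res.df_within) == (1, 2)

    def test_hand_example_weak(self):
        res = one_way_anova({"A": [1, 3], "B": [2, 4]})
        assert res.ss_between == pytest.approx(1.0)
        assert res.ss_within == pytest.approx(4.0)
        assert res.f_stat == pytest.approx(0.5)

    def test_identical_groups(self):
        res = one_way_anova({"T1": [1, 2], "T2": [1, 2]})
        assert res.ss_between == 0.0 and res.f_stat == 0.0

    def test_constant_data_flagged(self):
        res = one_way_anova({"T1": [2, 2], "T2": [2, 2]})
        assert res.degenerate and res.f_stat == 0.0 and res.p_value == 1.0

    def test_zero_within_variance_flagged(self):
        res = one_way_anova({"T1": [1, 1], "T2": [2, 2]})
        assert res.degenerate and np.isinf(res.f_stat) and res.p_value == 0.0

    def test_preconditions(self):
        with pytest.raises(ValueError):
            one_way_anova({"T1": [1, 2]})
        with pytest.raises(ValueError):
            one_way_anova({"T1": [1], "T2": [2]})


class TestTukey:
    def test_two_groups_match_anova(self):
        groups = {"a": [1.0, 2.0, 2.5], "b": [3.0, 4.5, 4.0]}
        pw = tukey_hsd(groups)
        assert pw["p_adj"].iloc[0] == pytest.approx(
            one_way_anova(groups).p_value, abs=1e-6)

    def test_identical_means(self):
        pw = tukey_hsd({"a": [1, 2], "b": [1, 2]})
        assert pw["mean_diff"].iloc[0] == 0.0
        assert pw["p_adj"].iloc[0] == pytest.approx(1.0)

    def test_degenerate_pooled_variance(self):
        pw = tukey_hsd({"a": [1, 1], "b": [2, 2], "c": [1, 1]})
        by = pw.set_index(["level_a", "level_b"])["p_adj"]
        assert by[("a", "b")] == 0.0 and by[("a", "c")] == 1.0

    def test_three_groups_against_reference(self):
        from scipy import stats as sps
        groups = {"A": [1.0, 2.0], "B": [3.0, 4.0], "C": [5.0, 6.0]}
        pw = tukey_hsd(groups).set_index(["level_a", "level_b"])["p_adj"]
        ref = sps.tukey_hsd(*groups.values()).pvalue
        assert pw[("A", "B")] == pytest.approx(ref[0, 1], abs=1e-6)
        assert pw[("A", "C")] == pytest.approx(ref[0, 2], abs=1e-6)
        assert pw[("B", "C")] == pytest.approx(ref[1, 2], abs=1e-6)


def pairwise_frame(pvals):
    rows = [{"level_a": a, "level_b": b, "p_adj": p, "mean_diff": 0.0}
            for (a, b), p in pvals.items()]
    return pd.DataFrame(rows)


class TestCompactLetters:
    def test_insert_absorb_hand_case(self):
        pw = pairwise_frame({("A", "B"): 0.01, ("A", "C"): 0.01,
                             ("B", "C"): 0.9})
        letters = compact_letter_display(
            pw, means={"A": 10.0, "B": 5.0, "C": 4.0})
        assert letters == {"A": "a", "B": "b", "C": "b"}

    def test_all_nonsignificant(self):
        pw = pairwise_frame({p: 0.5 for p in
                             itertools.combinations("ABC", 2)})
        assert set(compact_letter_display(pw).values()) == {"a"}

    def test_all_significant(self):
        pw = pairwise_frame({p: 0.001 for p in
                             itertools.combinations("ABC", 2)})
        letters = compact_letter_display(
            pw, means={"A": 3.0, "B": 2.0, "C": 1.0})
        assert letters == {"A": "a", "B": "b", "C": "c"}

    def test_overlapping_chain_needs_two_letters(self):
        """A>B>C with only the extremes different: B shares with both."""
        pw = pairwise_frame({("A", "B"): 0.3, ("B", "C"): 0.3,
                             ("A", "C"): 0.01})
        letters = compact_letter_display(
            pw, means={"A": 3.0, "B": 2.0, "C": 1.0})
        assert set(letters["B"]) == {"a", "b"}
        assert not set(letters["A"]) & set(letters["C"])

    @pytest.mark.parametrize("seed", range(30))
    def test_random_patterns_are_consistent(self, seed):
        """Shared letters reconstruct the significance pattern exactly
        (the display routine verifies this internally and would raise)."""
        rng = np.random.default_rng(seed)
        levels = list("ABCDE")
        pvals = {pair: float(rng.choice([0.01, 0.5]))
                 for pair in itertools.combinations(levels, 2)}
        pw = pairwise_frame(pvals)
        means = {lv: float(rng.normal()) for lv in levels}
        letters = compact_letter_display(pw, means=means)
        for (a, b), p in pvals.items():
            shared = set(letters[a]) & set(letters[b])
            assert bool(shared) == (p >= 0.05)


def means_frame(specific, fixed, treatments):
    """Community-means table (one trait, one scheme) + plot table."""
    plots = [f"P{i}" for i in range(len(specific))]
    means = pd.DataFrame({
        "plot_id": plots, "trait": "H", "scheme": "CWM",
        "specific": specific, "fixed": fixed,
        "intra": np.asarray(specific) - np.asarray(fixed)})
    plot_df = pd.DataFrame({"plot_id": plots, "treatment": treatments})
    return means, plot_df


class TestDecomposition:
    def test_hand_worked_two_treatment_fixture(self):
        means, plots = means_frame([3, 3, 5, 5], [2, 2, 3, 3],
                                   ["T1", "T1", "T2", "T2"])
        d = ss_decompose(means, plots, "H", "CWM")
        b = d.ss["between"]
        assert b["specific"] == pytest.approx(4.0)
        assert b["fixed"] == pytest.approx(1.0)
        assert b["intra"] == pytest.approx(1.0)
        assert b["cov"] == pytest.approx(2.0)
        d = contribution_percentages(d)
        assert (d.percent_fixed, d.percent_intra, d.percent_cov) == \
            pytest.approx((25.0, 25.0, 50.0))

    def test_intra_zero_forces_cov_zero(self):
        means, plots = means_frame([3, 4, 5, 6], [3, 4, 5, 6],
                                   ["T1", "T1", "T2", "T2"])
        d = ss_decompose(means, plots, "H", "CWM")
        for stratum in ("between", "within", "total"):
            assert d.ss[stratum]["intra"] == 0.0
            assert d.ss[stratum]["cov"] == pytest.approx(0.0, abs=1e-12)
            assert d.ss[stratum]["fixed"] == pytest.approx(
                d.ss[stratum]["specific"])

    def test_negative_covariation_fixture(self):
        """Fixed and intra profiles oppose -> negative covariation, and
        the three percentages still sum to the explained share."""
        fixed = np.array([1.0, 1.0, 3.0, 3.0])
        intra = np.array([2.0, 2.0, 1.0, 1.0])
        means, plots = means_frame(fixed + intra, fixed,
                                   ["T1", "T1", "T2", "T2"])
        d = contribution_percentages(ss_decompose(means, plots, "H", "CWM"))
        assert d.percent_cov < 0
        total = d.ss["total"]["specific"]
        explained = d.ss["between"]["specific"]
        assert d.percent_fixed + d.percent_intra + d.percent_cov == \
            pytest.approx(100.0 * explained / total)

    def test_explained_denominator_option(self):
        means, plots = means_frame([3, 3.5, 5, 5.5], [2, 2.5, 3, 3.5],
                                   ["T1", "T1", "T2", "T2"])
        d = contribution_percentages(ss_decompose(means, plots, "H", "CWM"),
                                     denominator="explained")
        assert d.percent_fixed + d.percent_intra + d.percent_cov == \
            pytest.approx(100.0)

    def test_degenerate_total_flagged(self):
        means, plots = means_frame([2, 2, 2, 2], [1, 1, 1, 1],
                                   ["T1", "T1", "T2", "T2"])
        d = contribution_percentages(ss_decompose(means, plots, "H", "CWM"))
        assert d.percent_degenerate and np.isnan(d.percent_fixed)

    def test_fewer_than_two_treatments_rejected(self):
        means, plots = means_frame([1, 2], [1, 1], ["T1", "T1"])
        with pytest.raises(ValueError):
            ss_decompose(means, plots, "H", "CWM")

    def test_plot_order_invariance(self):
        rng = np.random.default_rng(8)
        spec = rng.normal(10, 2, 12)
        fix = rng.normal(9, 1, 12)
        trts = ["T1"] * 4 + ["T2"] * 4 + ["T3"] * 4
        means, plots = means_frame(spec, fix, trts)
        d1 = ss_decompose(means, plots, "H", "CWM")
        perm = rng.permutation(12)
        d2 = ss_decompose(means.iloc[perm].reset_index(drop=True),
                          plots, "H", "CWM")
        for stratum in ("between", "within", "total"):
            for comp in ("specific", "fixed", "intra", "cov"):
                assert d1.ss[stratum][comp] == pytest.approx(
                    d2.ss[stratum][comp], abs=1e-9)
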