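"""RNA-ChIP correlation, classification, groups, and set comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cyclemark as cm
from cyclemark.integrate import GROUP_LABELS, correlation_groups


class TestCorrelateRnaChip:
    def test_identical_profiles_give_rho_one(self, default_design):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(rng.normal(size=(3, 18)), index=list("abc"),
                            columns=default_design.sample_ids)
        rec = cm.correlate_rna_chip(vals, vals, default_design, antibody="K4")
        assert np.allclose(rec["rho"], 1.0)
        assert (rec["class"] == "high").all()

    def test_polii_exclusion_gives_17_pairs(self):
        design = cm.default_design()  # (12 h, Epi2) excluded for polII
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(rng.normal(size=(2, 18)), index=list("ab"),
                            columns=design.sample_ids)
        rec = cm.correlate_rna_chip(vals, vals, design, antibody="polII")
        assert (rec["n_pairs"] == 17).all()

    def test_hand_derived_rho(self, default_design):
        design = cm.TimeCourseDesign(time_points_hours=(0, 3),
                                     replicates=("A", "B"))
        rna = pd.DataFrame([[1, 2, 3, 4]], index=["g"],
                           columns=design.sample_ids, dtype=float)
        chip = pd.DataFrame([[10, 30, 20, 40]], index=["g"],
                            columns=design.sample_ids, dtype=float)
        rec = cm.correlate_rna_chip(rna, chip, design, antibody="K4")
        assert rec.loc["g", "rho"] == pytest.approx(0.8)

    def test_too_few_pairs_gives_missing(self):
        design = cm.TimeCourseDesign(time_points_hours=(0, 3, 6),
                                     replicates=("A",))
        rna = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"],
                           columns=design.sample_ids)
        rec = cm.correlate_rna_chip(rna, rna, design, antibody="x")
        assert np.isnan(rec.loc["g", "rho"])
        assert rec.loc["g", "class"] is None

    def test_monotone_transform_invariance(self, default_design):
        rng = np.random.default_rng(2)
        rna = pd.DataFrame(rng.normal(size=(4, 18)),
                           index=list("abcd"), columns=default_design.sample_ids)
        chip = pd.DataFrame(rng.normal(size=(4, 18)),
                            index=list("abcd"), columns=default_design.sample_ids)
        r1 = cm.correlate_rna_chip(rna, chip, default_design, "K4")
        r2 = cm.correlate_rna_chip(np.exp(rna), chip ** 3, default_design, "K4")
        assert np.allclose(r1["rho"], r2["rho"])
        assert (r1["class"] == r2["class"]).all()


class TestClassifyCorrelation:
    @pytest.mark.parametrize("rho,expected", [
        (0.47, "high"),      # CCNB1-like Pol II correlation
        (0.2, "middle"),     # boundary: strict inequalities
        (-0.2, "middle"),
        (-0.5, "low"),
        (0.21, "high"),
        (float("nan"), None),
    ])
    def test_thresholds(self, rho, expected):
        assert cm.classify_correlation(rho) == expected


class TestCorrelationGroups:
    def test_all_class_pairs_partition(self):
        """Enumerate all 9 class pairs: the mapping is total and matches
        the five printed group definitions."""
        expected = {
            ("high", "high"): "both_high",
            ("high", "middle"): "polII_only_high",
            ("high", "low"): "polII_only_high",
            ("middle", "high"): "K4_only_high",
            ("low", "high"): "K4_only_high",
            ("low", "low"): "both_low",
            ("middle", "middle"): "middle",
            ("middle", "low"): "middle",
            ("low", "middle"): "middle",
        }
        for (p, k), want in expected.items():
            got = correlation_groups(pd.Series({"g": p}), pd.Series({"g": k}))
            assert got["g"] == want, (p, k)

    def test_missing_class_ungrouped(self):
        got = correlation_groups(pd.Series({"g": "high"}),
                                 pd.Series({"g": None}))
        assert pd.isna(got["g"])

    def test_groups_partition_simulated_records(self, default_design):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(200)]
        pol = pd.Series(rng.choice(["high", "middle", "low"], 200), index=genes)
        k4 = pd.Series(rng.choice(["high", "middle", "low"], 200), index=genes)
        groups = correlation_groups(pol, k4)
        assert groups.notna().all()
        assert set(groups.unique()) <= set(GROUP_LABELS)
        assert groups.value_counts().sum() == 200


class TestPhaseSignalComparison:
    def test_identical_groups(self):
        vals = pd.Series(np.r_[np.arange(6.0), np.arange(6.0)],
                         index=[f"g{i}" for i in range(12)])
        labels = pd.Series(["S"] * 6 + ["G2"] * 6, index=vals.index)
        table = cm.phase_signal_comparison(vals, labels)
        row = table[table["phase"] == "G2"].iloc[0]
        assert row["statistic"] == pytest.approx(0.0)
        assert row["p_adj"] == pytest.approx(1.0)

    def test_welch_and_bonferroni_numbers(self):
        vals = pd.Series([1, 2, 3, 4, 5, 6.0],
                         index=[f"g{i}" for i in range(6)])
        labels = pd.Series(["S"] * 3 + ["G2/M"] * 3, index=vals.index)
        table = cm.phase_signal_comparison(vals, labels, family_size=4)
        row = table[table["phase"] == "G2/M"].iloc[0]
        assert row["statistic"] == pytest.approx(3.674, abs=1e-3)
        assert row["df"] == pytest.approx(4.0)
        assert row["p_adj"] == pytest.approx(min(1.0, 0.02131 * 4), abs=1e-4)

    def test_small_phase_not_computable(self):
        vals = pd.Series([1.0, 2.0, 3.0, 9.0], index=list("abcd"))
        labels = pd.Series(["S", "S", "S", "G2"], index=vals.index)
        table = cm.phase_signal_comparison(vals, labels)
        row = table[table["phase"] == "G2"].iloc[0]
        assert np.isnan(row["statistic"])

    def test_anova_row_present(self):
        rng = np.random.default_rng(4)
        vals = pd.Series(rng.normal(size=30), index=[f"g{i}" for i in range(30)])
        labels = pd.Series(["S"] * 10 + ["G2"] * 10 + ["M/G1"] * 10,
                           index=vals.index)
        table = cm.phase_signal_comparison(vals, labels)
        assert (table["method"] == "one_way_anova").sum() == 1


class TestCompareCorrelationSets:
    def test_all_zero_rho_set(self):
        rho = pd.Series(np.zeros(20), index=[f"g{i}" for i in range(20)])
        per_set, _ = cm.compare_correlation_sets(rho, {"CC": list(rho.index)})
        assert per_set.iloc[0]["t"] == pytest.approx(0.0)
        assert per_set.iloc[0]["p"] == pytest.approx(1.0)

    def test_identical_sets_pairwise_p_one(self):
        rng = np.random.default_rng(5)
        rho = pd.Series(rng.normal(size=30), index=[f"g{i}" for i in range(30)])
        sets = {"A": list(rho.index), "B": list(rho.index)}
        _, pairwise = cm.compare_correlation_sets(rho, sets)
        assert pairwise.iloc[0]["p"] == pytest.approx(1.0)

    def test_empty_set_warns_and_skips(self):
        rho = pd.Series([0.1, 0.2], index=["a", "b"])
        with pytest.warns(UserWarning):
            per_set, _ = cm.compare_correlation_sets(
                rho, {"A": ["a", "b"], "B": ["zzz"]})
        assert list(per_set["set"]) == ["A"]

    def test_cumulative_distribution(self):
        rho = pd.Series([0.3, -0.1, 0.5], index=list("abc"))
        cdf = cm.cumulative_distribution(rho, ["a", "b", "c"])
        assert list(cdf["rho"]) == [-0.1, 0.3, 0.5]
        assert list(cdf["cumfrac"]) == pytest.approx([1 / 3, 2 / 3, 1.0])


class TestLncrnaCandidates:
    BIO = pd.Series({"l1": "lncRNA", "l2": "lncRNA", "l3": "lncRNA",
                     "pc": "protein_coding"})

    @staticmethod
    def _records(rows):
        df = pd.DataFrame(rows, columns=["gene_id", "rho"]).set_index("gene_id")
        df["class"] = [cm.classify_correlation(r) for r in df["rho"]]
        return df

    def test_both_high_ranks_first(self):
        pol = self._records([("l1", 0.5), ("l2", 0.9), ("pc", 0.9)])
        k4 = self._records([("l1", 0.45), ("l2", 0.1), ("pc", 0.9)])
        cand = cm.select_lncrna_candidates(["l1", "l2", "pc"], self.BIO, pol, k4)
        assert list(cand.index) == ["l1", "l2"]  # both-high before higher rho
        assert cand.loc["l1", "both_high"]
        assert not cand.loc["l2", "both_high"]

    def test_protein_coding_excluded(self):
        pol = self._records([("pc", 0.9)])
        k4 = self._records([("pc", 0.9)])
        cand = cm.select_lncrna_candidates(["pc"], self.BIO, pol, k4)
        assert cand.empty

    def test_non_cyclic_lncrna_excluded(self):
        pol = self._records([("l1", 0.9), ("l3", 0.9)])
        k4 = self._records([("l1", 0.9), ("l3", 0.9)])
        cand = cm.select_lncrna_candidates(["l1"], self.BIO, pol, k4)
        assert list(cand.index) == ["l1"]

    def test_highly_correlated_flag_is_or(self):
        pol = self._records([("l1", 0.5), ("l2", 0.0)])
        k4 = self._records([("l1", -0.1), ("l2", 0.6)])
        cand = cm.select_lncrna_candidates(["l1", "l2"], self.BIO, pol, k4)
        assert cand["highly_correlated"].all()


@settings(derandomize=True, max_examples=60, deadline=None)
@given(rho=st.floats(-1.0, 1.0))
def test_classification_total_on_valid_rho(rho):
    assert cm.classify_correlation(rho) in {"high", "middle", "low"}
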