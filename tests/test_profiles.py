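"""Distribution summaries, Gram split, temporal trends, chemotype subsets."""

import math

import numpy as np
import pandas as pd
import pytest

from abxspace.activity import ActivityMatrix
from abxspace.profiles import (
    ChemotypeSpec,
    GramAnnotation,
    PropertyRange,
    charge_class_counts,
    chemotype_subsets,
    compare_sets,
    default_chemotypes,
    gram_split,
    summarize,
    temporal_profile,
)
from abxspace.standardize import standardize


class TestSummarize:
    def test_odd_sample(self):
        s = summarize([1, 2, 3])
        assert s.median == 2 and s.mean == 2 and s.n == 3

    def test_even_sample_midpoint_median(self):
        assert summarize([1, 2, 3, 4]).median == 2.5

    def test_range_percentage_by_hand(self):
        s = summarize([300, 400, 600], "mw", (PropertyRange("mw_lt_500", hi=500, hi_strict=True),))
        assert s.percent_in_range["mw_lt_500"] == pytest.approx(66.7, abs=0.05)

    def test_missing_values_excluded_and_counted(self):
        s = summarize([1.0, None, float("nan"), 3.0])
        assert s.n == 2 and s.n_missing == 2 and s.median == 2.0

    def test_empty_flagged_undefined(self):
        s = summarize([], "mw", (PropertyRange("mw_lt_500", hi=500),))
        assert s.n == 0 and not s.defined
        assert math.isnan(s.median)
        assert math.isnan(s.percent_in_range["mw_lt_500"])

    def test_histogram_counts_sum_to_n(self):
        s = summarize(list(np.linspace(100, 900, 57)), "mw")
        assert s.hist_counts.sum() == 57


class TestChargeClassCounts:
    def test_all_neutral(self):
        sms = [standardize(s, str(i)) for i, s in enumerate(["CCO", "c1ccccc1", "CC(=O)NC"])]
        assert charge_class_counts(sms) == {
            "acidic": 0, "basic": 0, "neutral": 3, "zwitterionic": 0}

    def test_partition_sums_to_set_size(self):
        smiles = ["CCO", "NCC(=O)O", "OC(=O)c1ccccc1", "NCc1ccccc1", "c1ccncc1"]
        sms = [standardize(s, str(i)) for i, s in enumerate(smiles)]
        counts = charge_class_counts(sms)
        assert sum(counts.values()) == len(smiles)
        assert counts["zwitterionic"] >= 1

    def test_empty_set_all_zero(self):
        assert charge_class_counts([]) == {
            "acidic": 0, "basic": 0, "neutral": 0, "zwitterionic": 0}


class TestGramSplit:
    def _matrix(self, entries, organisms):
        return ActivityMatrix("antibacterial", entries, organisms)

    def test_gram_positive_only(self):
        m = self._matrix({("C1", "A1"): "A"}, {"A1": "Staphylococcus aureus"})
        pos, neg = gram_split(m)
        assert pos == {"C1"} and neg == set()

    def test_active_in_both_classes(self):
        m = self._matrix({("C1", "A1"): "A", ("C1", "A2"): "A"},
                         {"A1": "Escherichia coli", "A2": "Staphylococcus aureus"})
        pos, neg = gram_split(m)
        assert pos == {"C1"} and neg == {"C1"}

    def test_unclassified_organism_ignored(self):
        m = self._matrix({("C1", "A1"): "A"}, {"A1": "Mycoplasma genitalium"})
        pos, neg = gram_split(m)
        assert pos == set() and neg == set()

    def test_inactive_in_class_excluded(self):
        # active overall, but its only Gram-negative record is inactive
        m = self._matrix({("C1", "A1"): "A", ("C1", "A2"): "I"},
                         {"A1": "Staphylococcus aureus", "A2": "Escherichia coli"})
        pos, neg = gram_split(m)
        assert pos == {"C1"} and neg == set()

    def test_order_invariance(self):
        entries = {("C1", "A1"): "A", ("C2", "A2"): "A", ("C1", "A2"): "A"}
        organisms = {"A1": "Staphylococcus aureus", "A2": "Escherichia coli"}
        a = gram_split(self._matrix(entries, organisms))
        b = gram_split(self._matrix(dict(reversed(entries.items())), organisms))
        assert a == b

    def test_lookup_total_and_genus_fallback(self):
        ann = GramAnnotation.default()
        assert ann.classify("Staphylococcus aureus") == "gram_positive"
        assert ann.classify("Klebsiella oxytoca") == "gram_negative"   # genus fallback
        assert ann.classify("Completely unknown bug") == "unclassified"
        assert ann.classify("") == "unclassified"


class TestTemporalProfile:
    def test_constant_property_flat_series(self):
        members = [f"C{i}" for i in range(40)]
        values = {c: 350.0 for c in members}
        years = {c: 2000 + (i % 2) for i, c in enumerate(members)}
        series, missing = temporal_profile(members, values, years, min_n=10)
        assert missing == 0
        assert set(series) == {2000, 2001}
        assert all(s.median == 350.0 for s in series.values())

    def test_step_effect_detected(self):
        members = [f"C{i}" for i in range(60)]
        years = {c: 1990 + (i // 15) for i, c in enumerate(members)}
        values = {c: 300.0 if years[c] < 1992 else 400.0 for c in members}
        series, _ = temporal_profile(members, values, years, min_n=10)
        medians = [series[y].median for y in sorted(series)]
        assert medians == [300.0, 300.0, 400.0, 400.0]

    def test_all_years_missing(self):
        members = ["C1", "C2"]
        series, missing = temporal_profile(members, {"C1": 1.0, "C2": 2.0},
                                           {"C1": None, "C2": None})
        assert series == {} and missing == 2

    def test_small_years_omitted(self):
        members = [f"C{i}" for i in range(12)]
        values = {c: 300.0 for c in members}
        years = {c: 2000 if i < 11 else 2001 for i, c in enumerate(members)}
        series, _ = temporal_profile(members, values, years, min_n=10)
        assert set(series) == {2000}


class TestChemotypeSubsets:
    PENICILLIN = "CC1(C)SC2C(NC(=O)Cc3ccccc3)C(=O)N2C1C(=O)O"

    def test_beta_lactam_matches_penicillin_core(self):
        subsets = chemotype_subsets(
            ["P1", "B1"], {"P1": self.PENICILLIN, "B1": "c1ccccc1"},
            [ChemotypeSpec("beta_lactam", "O=C1[#6][#6]N1", "cell_wall", min_count=1)])
        assert subsets["beta_lactam"].members == {"P1"}

    def test_below_min_count_flagged(self):
        subsets = chemotype_subsets(
            ["P1"], {"P1": self.PENICILLIN},
            [ChemotypeSpec("beta_lactam", "O=C1[#6][#6]N1", "cell_wall", min_count=40)])
        assert subsets["beta_lactam"].below_threshold

    def test_invalid_pattern_names_spec(self):
        spec = ChemotypeSpec("broken", "(((", "cell_wall", min_count=1)
        with pytest.raises(ValueError, match="broken"):
            chemotype_subsets(["P1"], {"P1": "CCO"}, [spec])

    def test_default_specs_load(self):
        names = {s.name for s in default_chemotypes()}
        assert {"beta_lactam", "fluoroquinolone", "oxazolidinone"} <= names

    def test_min_count_must_be_positive(self):
        with pytest.raises(ValueError):
            ChemotypeSpec("x", "C", "cell_wall", min_count=0)


class TestCompareSets:
    def _table(self, mws):
        return pd.DataFrame({
            "mw": mws, "logp": [2.0] * len(mws), "logd74": [1.5] * len(mws),
            "hba": [3] * len(mws), "hbd": [1] * len(mws), "rot_bonds": [4] * len(mws),
            "rings": [2] * len(mws), "tpsa": [60.0] * len(mws),
        }, index=[f"C{i}" for i in range(len(mws))])

    def test_identical_sets_identical_rows(self):
        t = self._table([300, 400, 500])
        report = compare_sets({"S1": t, "S2": t.copy()})
        assert report.loc["S1"].equals(report.loc["S2"])

    def test_median_gap_recovered(self):
        report = compare_sets({"heavy": self._table([500, 520, 540]),
                               "light": self._table([300, 320, 340])})
        gap = report.loc["heavy", "median_mw"] - report.loc["light", "median_mw"]
        assert gap == pytest.approx(200.0)

    def test_single_property_report(self):
        report = compare_sets({"S1": self._table([300])}, properties=("mw",))
        assert "median_mw" in report.columns and "median_tpsa" not in report.columns

    def test_n_matches_set_sizes(self):
        report = compare_sets({"S1": self._table([300, 400]), "S2": self._table([1, 2, 3])})
        assert report.loc["S1", "n"] == 2 and report.loc["S2", "n"] == 3
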