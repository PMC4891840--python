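"""Activity labelling, matrix building and the quantified set definitions."""

import itertools

import numpy as np
import pytest

from abxspace.activity import (
    build_matrix,
    build_sets,
    check_set_invariants,
    classify_compound,
    convert_value,
    label_record,
)
from abxspace.chembl_io import AssayRecord, CompoundRecord, FilterSpec

SPEC = FilterSpec()


def mic(value, units="ug_per_ml", relation="=", cid="C1", aid="A1"):
    return AssayRecord(cid, aid, "antibacterial", "ORGANISM", "Escherichia coli",
                       "MIC", value, units, relation)


class TestLabelRecord:
    @pytest.mark.parametrize("value,expected", [
        (4.0, "A"),            # within the active band
        (8.0, "A"),            # cutoff is inclusive
        (20.0, "SA"),
        (32.0, "SA"),
        (64.0, "I"),           # above the slightly-active band
    ])
    def test_equality_bands(self, value, expected):
        assert label_record(mic(value), SPEC) == expected

    def test_molar_record_converted_with_mw(self):
        # 50 uM at MW 500 -> 50*500/1000 = 25 ug/ml -> slightly active
        assert convert_value(50.0, "uM", "antibacterial", 500.0) == pytest.approx(25.0)
        assert label_record(mic(50.0, units="uM"), SPEC, mol_weight=500.0) == "SA"

    def test_unknown_units_unlabelled(self):
        assert label_record(mic(4.0, units="unknown"), SPEC) is None

    def test_molar_without_mw_unlabelled(self):
        assert label_record(mic(4.0, units="uM"), SPEC, mol_weight=None) is None

    @pytest.mark.parametrize("value,relation,expected", [
        (4.0, "<=", "A"),       # upper bound inside the active band proves A
        (8.0, "<", "A"),
        (16.0, "<=", None),     # bound straddles the boundary: undecidable
        (64.0, ">", "I"),       # lower bound above the band proves I
        (32.0, ">", "I"),
        (32.0, ">=", None),     # >=32 does not prove >32
        (4.0, ">", None),
    ])
    def test_censored_relations_only_assert_what_they_prove(self, value, relation, expected):
        assert label_record(mic(value, relation=relation), SPEC) == expected

    def test_biochemical_bands_in_micromolar(self):
        rec = AssayRecord("C1", "B1", "biochemical", "SINGLE PROTEIN", "",
                          "IC50", 5.0, "uM", "=")
        assert label_record(rec, SPEC) == "A"
        rec2 = AssayRecord("C1", "B1", "biochemical", "SINGLE PROTEIN", "",
                           "IC50", 500.0, "uM", "=")
        assert label_record(rec2, SPEC) == "I"


class TestBuildMatrix:
    MW = {"C1": 300.0, "C2": 300.0}

    def test_single_active_entry(self):
        matrix, counters = build_matrix([mic(4.0)], SPEC, self.MW)
        assert matrix.entries == {("C1", "A1"): "A"}
        assert counters.n_unlabelled == 0

    def test_duplicate_pair_best_label_wins(self):
        matrix, _ = build_matrix([mic(64.0), mic(4.0)], SPEC, self.MW)
        assert matrix.entries == {("C1", "A1"): "A"}

    def test_worst_aggregation_configurable(self):
        matrix, _ = build_matrix([mic(64.0), mic(4.0)], SPEC, self.MW, aggregation="worst")
        assert matrix.entries == {("C1", "A1"): "I"}

    def test_empty_records_empty_matrix(self):
        matrix, _ = build_matrix([], SPEC, self.MW)
        assert matrix.entries == {}

    def test_unknown_compound_counted(self):
        matrix, counters = build_matrix([mic(4.0, cid="GHOST")], SPEC, self.MW)
        assert matrix.entries == {}
        assert counters.n_unknown_compound == 1

    def test_mixed_assay_classes_rejected(self):
        rec = AssayRecord("C1", "B1", "biochemical", "", "", "IC50", 5.0, "uM", "=")
        with pytest.raises(ValueError):
            build_matrix([mic(4.0), rec], SPEC, self.MW)

    def test_csv_roundtrip(self, tmp_path):
        matrix, _ = build_matrix([mic(4.0), mic(64.0, cid="C2", aid="A2")], SPEC, self.MW)
        path = matrix.to_csv(tmp_path / "m.csv")
        from abxspace.activity import ActivityMatrix
        back = ActivityMatrix.from_csv(path, "antibacterial")
        assert back.entries == matrix.entries


def brute_force_classify(vector):
    """Literal evaluation of the two quantified definitions.

    Active(c)   := ∃i: m_i = A  ∧  ∄i': m_i' = I
    Inactive(c) := ∃i: m_i = I  ∧  ∄i': m_i' ≠ I
    over the tested entries of the vector.
    """
    tested = [l for l in vector if l != "-"]
    exists_a = any(l == "A" for l in tested)
    nexists_i = not any(l == "I" for l in tested)
    exists_i = any(l == "I" for l in tested)
    nexists_not_i = not any(l != "I" for l in tested)
    if exists_a and nexists_i:
        return "active"
    if exists_i and nexists_not_i:
        return "inactive"
    return "indeterminate"


class TestClassifyCompound:
    def test_worked_example_vector(self):
        # the schematic compound tested in five assays: A,A,SA,A,SA
        assert classify_compound(["A", "A", "SA", "A", "SA"]) == "active"

    @pytest.mark.parametrize("vector,expected", [
        (["I", "I", "I"], "inactive"),
        (["A", "I"], "indeterminate"),
        (["SA", "SA"], "indeterminate"),
        ([], "indeterminate"),
        (["A"], "active"),
        (["SA", "I"], "indeterminate"),
    ])
    def test_representative_vectors(self, vector, expected):
        assert classify_compound(vector) == expected

    def test_agrees_with_bruteforce_on_all_256_vectors(self):
        symbols = ("A", "SA", "I", "-")
        n_checked = 0
        for raw in itertools.product(symbols, repeat=4):
            tested = [l for l in raw if l != "-"]
            assert classify_compound(tested) == brute_force_classify(raw), raw
            n_checked += 1
        assert n_checked == 256


def _compound(cid, status="not_drug"):
    return CompoundRecord(cid, "CCO", drug_status=status)


class TestBuildSets:
    def _matrices(self, ab_entries, bio_entries):
        from abxspace.activity import ActivityMatrix
        return (ActivityMatrix("antibacterial", dict(ab_entries)),
                ActivityMatrix("biochemical", dict(bio_entries)))

    def test_active_in_both_joins_baaa(self):
        ab, bio = self._matrices({("C1", "A1"): "A"}, {("C1", "B1"): "A"})
        sets = build_sets(ab, bio, [_compound("C1")])
        assert "C1" in sets["AA"] and "C1" in sets["BA"] and "C1" in sets["BAAA"]
        assert "C1" not in sets["BAAI"]

    def test_bio_active_without_ab_record_joins_baai(self):
        ab, bio = self._matrices({}, {("C1", "B1"): "A"})
        sets = build_sets(ab, bio, [_compound("C1")])
        assert sets["BAAI"] == {"C1"} and sets["BAAA"] == set()

    def test_bio_active_with_any_ab_record_excluded_from_baai(self):
        ab, bio = self._matrices({("C1", "A1"): "SA"}, {("C1", "B1"): "A"})
        sets = build_sets(ab, bio, [_compound("C1")])
        assert sets["BAAI"] == set()

    def test_empty_matrices_give_empty_assay_sets(self):
        ab, bio = self._matrices({}, {})
        sets = build_sets(ab, bio, [_compound("C1", "marketed_antibacterial"),
                                    _compound("C2", "marketed_other")])
        for label in ("AA", "AI", "BA", "BI", "BAAA", "BAAI"):
            assert sets[label] == set()
        assert sets["MAD"] == {"C1"} and sets["MOD"] == {"C2"}

    def test_five_compound_toy_universe_by_hand(self):
        # hand-enumerated memberships for every definition
        ab, bio = self._matrices(
            {("C1", "A1"): "A", ("C1", "A2"): "SA",     # AA active
             ("C2", "A1"): "I", ("C2", "A2"): "I",      # AA inactive
             ("C3", "A1"): "A", ("C3", "A2"): "I"},     # indeterminate
            {("C1", "B1"): "A",                          # bio active -> BAAA with C1
             ("C4", "B1"): "A",                          # no ab record -> BAAI
             ("C5", "B1"): "I"},                         # bio inactive
        )
        compounds = [_compound(f"C{i}") for i in range(1, 6)]
        sets = build_sets(ab, bio, compounds)
        assert sets["AA"] == {"C1"}
        assert sets["AI"] == {"C2"}
        assert sets["BA"] == {"C1", "C4"}
        assert sets["BI"] == {"C5"}
        assert sets["BAAA"] == {"C1"}
        assert sets["BAAI"] == {"C4"}

    def test_deterministic(self):
        ab, bio = self._matrices({("C1", "A1"): "A"}, {("C1", "B1"): "A"})
        compounds = [_compound("C1")]
        first = build_sets(ab, bio, compounds)
        second = build_sets(ab, bio, compounds)
        assert first == second


def random_sets(rng):
    """build_sets on a random label matrix pair over a small universe."""
    from abxspace.activity import ActivityMatrix

    n_compounds = rng.integers(1, 12)
    labels = np.array(["A", "SA", "I"])
    compounds = []
    ab_entries, bio_entries = {}, {}
    for i in range(n_compounds):
        cid = f"C{i}"
        status = ("not_drug", "marketed_antibacterial", "marketed_other")[rng.integers(3)]
        compounds.append(_compound(cid, status))
        for aid in range(rng.integers(0, 4)):
            ab_entries[(cid, f"A{aid}")] = str(labels[rng.integers(3)])
        for aid in range(rng.integers(0, 4)):
            bio_entries[(cid, f"B{aid}")] = str(labels[rng.integers(3)])
    ab = ActivityMatrix("antibacterial", ab_entries)
    bio = ActivityMatrix("biochemical", bio_entries)
    return build_sets(ab, bio, compounds)


def test_set_invariants_on_randomized_matrices():
    rng = np.random.default_rng(2024)
    for _ in range(200):
        check_set_invariants(random_sets(rng))
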