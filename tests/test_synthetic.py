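"""The synthetic generator: determinism, design counts, referential integrity."""

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from abxspace.activity import build_matrix, build_sets, label_record
from abxspace.chembl_io import FilterSpec, read_activities, read_compounds
from abxspace.standardize import standardize
from abxspace.synthetic import (
    GeneratorSpec,
    designed_sets,
    generate_activities,
    generate_compounds,
    generate_drug_annotations,
    write_dataset,
)


class TestGenerateCompounds:
    def test_empty_spec(self):
        structures, manifest = generate_compounds(GeneratorSpec(n_compounds=0, seed=1))
        assert structures == [] and manifest.empty

    def test_seeded_determinism_byte_identical(self, tmp_path):
        spec = GeneratorSpec(n_compounds=40, seed=17)
        a = write_dataset(spec, tmp_path / "a")
        b = write_dataset(spec, tmp_path / "b")
        for key in a:
            assert a[key].read_bytes() == b[key].read_bytes()

    def test_salt_fraction_exact(self):
        spec = GeneratorSpec(n_compounds=100, seed=3, salt_fraction=0.2)
        structures, manifest = generate_compounds(spec)
        multi = [s for _, s in structures if "." in s]
        assert len(multi) == 20
        assert (manifest.salt_partner != "").sum() == 20

    def test_structures_parse_and_charge_classes_designed(self):
        _, manifest = generate_compounds(GeneratorSpec(n_compounds=60, seed=5))
        for row in manifest.itertuples():
            assert Chem.MolFromSmiles(row.smiles) is not None
            sm = standardize(row.smiles, row.compound_id)
            assert sm.charge_class == row.charge_class, row.template

    def test_mw_tracks_target(self):
        _, manifest = generate_compounds(GeneratorSpec(n_compounds=120, seed=6))
        achieved = manifest.actual_mw.to_numpy()
        target = manifest.target_mw.to_numpy()
        reachable = achieved >= target - 8   # below-template targets clamp upward
        assert (np.abs(achieved - target)[reachable] <= 8).all()

    def test_year_shift_effect(self):
        spec = GeneratorSpec(n_compounds=300, seed=8, year_shift=(1995, 150.0))
        _, manifest = generate_compounds(spec)
        early = manifest[manifest.year < 1995].actual_mw.median()
        late = manifest[manifest.year >= 1995].actual_mw.median()
        assert late - early > 75

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            GeneratorSpec(salt_fraction=1.5)
        with pytest.raises(ValueError):
            GeneratorSpec(mad_fraction=0.7, mod_fraction=0.6)


class TestGenerateActivities:
    def test_designed_actives_prove_active(self):
        spec = GeneratorSpec(n_compounds=150, seed=9)
        _, manifest = generate_compounds(spec)
        activities = generate_activities(spec, manifest)
        fspec = FilterSpec()
        mw = {}
        for row in manifest.itertuples():
            mw[row.compound_id] = row.actual_mw
        from abxspace.chembl_io import AssayRecord, normalize_units
        design = manifest.set_index("compound_id")
        for row in activities.itertuples():
            rec = AssayRecord(row.compound_id, row.assay_id, row.assay_class,
                              row.target_type, row.organism or "", row.activity_type,
                              float(row.value), normalize_units(row.units),
                              row.relation, int(row.year))
            label = label_record(rec, fspec, mw[row.compound_id])
            key = "ab_design" if row.assay_class == "antibacterial" else "bio_design"
            expected = {"active": "A", "inactive": "I", "slightly": "SA"}[design.loc[row.compound_id, key]]
            assert label == expected

    def test_full_overlap_makes_baaa_equal_aa(self):
        spec = GeneratorSpec(n_compounds=120, seed=10, bio_overlap_fraction=1.0)
        _, manifest = generate_compounds(spec)
        truth = designed_sets(manifest)
        assert truth["BAAA"] == truth["AA"]

    def test_zero_censoring_only_equals(self):
        spec = GeneratorSpec(n_compounds=100, seed=11, censored_fraction=0.0)
        _, manifest = generate_compounds(spec)
        activities = generate_activities(spec, manifest)
        assert set(activities.relation) == {"="}

    def test_unit_mix_respected(self):
        spec = GeneratorSpec(n_compounds=200, seed=12, unit_um_fraction=0.5)
        _, manifest = generate_compounds(spec)
        activities = generate_activities(spec, manifest)
        ab = activities[activities.assay_class == "antibacterial"]
        um_share = (ab.units == "uM").mean()
        assert 0.35 < um_share < 0.65


class TestAnnotationsAndIntegrity:
    def test_mad_fraction_zero_empty_mad(self):
        spec = GeneratorSpec(n_compounds=80, seed=13, mad_fraction=0.0)
        _, manifest = generate_compounds(spec)
        annotations = generate_drug_annotations(spec, manifest)
        assert (annotations.therapeutic_class == "antibacterial").sum() == 0
        assert designed_sets(manifest)["MAD"] == set()

    def test_referential_integrity(self, small_dataset):
        manifest = small_dataset["manifest"]
        ids = set(manifest.compound_id)
        activities = pd.read_csv(small_dataset["paths"]["activities"])
        annotations = pd.read_csv(small_dataset["paths"]["annotations"])
        assert set(activities.compound_id) <= ids
        assert set(annotations.compound_id) == ids

    def test_mad_mod_disjoint_by_construction(self, small_dataset):
        truth = designed_sets(small_dataset["manifest"])
        assert not (truth["MAD"] & truth["MOD"])


class TestEndToEndRecovery:
    def test_designed_memberships_recovered_exactly(self, small_dataset):
        paths = small_dataset["paths"]
        compounds, _ = read_compounds(paths["compounds"], paths["annotations"])
        result = read_activities(paths["activities"])
        from rdkit.Chem import Descriptors
        mw = {}
        for comp in compounds:
            mw[comp.compound_id] = Descriptors.MolWt(
                standardize(comp.structure, comp.compound_id).mol())
        fspec = FilterSpec()
        ab, _ = build_matrix([r for r in result.records if r.assay_class == "antibacterial"],
                             fspec, mw)
        bio, _ = build_matrix([r for r in result.records if r.assay_class == "biochemical"],
                              fspec, mw)
        sets = build_sets(ab, bio, compounds)
        truth = designed_sets(small_dataset["manifest"])
        for label in truth:
            assert sets[label] == truth[label], label
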