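"""Label activity records A/SA/I and build the eight analysis sets."""

from rdkit.Chem import Descriptors

from abxspace import (
    FilterSpec,
    GeneratorSpec,
    build_matrix,
    build_sets,
    classify_compound,
    read_activities,
    read_compounds,
    standardize,
    write_dataset,
)

paths = write_dataset(GeneratorSpec(n_compounds=300, seed=42), "scratch/example_data")
compounds, _ = read_compounds(paths["compounds"], paths["annotations"])
result = read_activities(paths["activities"])
print(f"read {len(result.records)} activity records "
      f"({result.n_excluded_units} with unusable units)")

# molecular weights of the desalted parents drive ug/ml <-> uM conversion
mw = {c.compound_id: Descriptors.MolWt(standardize(c.structure, c.compound_id).mol())
      for c in compounds}

spec = FilterSpec()   # MIC: A <= 8, SA <= 32 ug/ml; IC50: A <= 10, SA <= 100 uM
ab, _ = build_matrix([r for r in result.records if r.assay_class == "antibacterial"], spec, mw)
bio, _ = build_matrix([r for r in result.records if r.assay_class == "biochemical"], spec, mw)
sets = build_sets(ab, bio, compounds)

print("\nset sizes:", {k: len(v) for k, v in sets.items()})
print("\nexample: a compound tested five times as [A, A, SA, A, SA] is",
      classify_compound(["A", "A", "SA", "A", "SA"]))
print("AA/AI are growth-inhibition actives/inactives, BA/BI biochemical ones;")
print("BAAA is active in both, BAAI biochemically active with no antibacterial record.")
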