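"""Three-step standardization: normalization, salt stripping, pH 7.4 ionization."""

from abxspace import standardize

examples = [
    ("sodium benzoate", "[O-]C(=O)c1ccccc1.[Na+]"),
    ("benzylamine HCl", "Cl.NCc1ccccc1"),
    ("glycine (neutral drawing)", "NCC(=O)O"),
    ("nitrobenzene (pentavalent N)", "O=N(=O)c1ccccc1"),
    ("ciprofloxacin", "O=C(O)c1cn(C2CC2)c2cc(N3CCNCC3)c(F)cc2c1=O"),
]

for name, smiles in examples:
    sm = standardize(smiles, name)
    print(f"{name}")
    print(f"  input : {smiles}")
    print(f"  output: {sm.smiles}   [{sm.charge_class}]")
    if sm.ionizable_groups:
        fired = ", ".join(f"{g.rule} (pKa {g.pka})" for g in sm.ionizable_groups)
        print(f"  ionization rules fired: {fired}")
    if sm.provenance:
        print(f"  provenance: {sm.provenance}")
print("\nEach output is a single-component canonical structure at its most")
print("prevalent pH 7.4 form; the charge class feeds the profile tables and")
print("the fired rule pKas feed the logD(7.4) correction.")
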