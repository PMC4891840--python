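Cl hydrochloric_acid
[Cl-] chloride
Br hydrobromic_acid
[Br-] bromide
I hydroiodic_acid
[I-] iodide
F hydrofluoric_acid
[F-] fluoride
[Na+] sodium
[K+] potassium
[Li+] lithium
[Ca+2] calcium
[Mg+2] magnesium
[Zn+2] zinc
[Ba+2] barium
[Al+3] aluminium
N ammonia
[NH4+] ammonium
O water
O=S(=O)(O)O sulfuric_acid
[O-]S(=O)(=O)[O-] sulfate
[O-]S(=O)(=O)O hydrogensulfate
O[N+](=O)[O-] nitric_acid
CC(=O)O acetic_acid
CC(=O)[O-] acetate
Cc1ccc(S(=O)(=O)O)cc1 tosylic_acid
CS(=O)(=O)O methanesulfonic_acid
OC(=O)C(F)(F)F trifluoroacetic_acid
O=C(O)C(=O)O oxalic_acid
O=C(O)C=CC(=O)O maleic_fumaric_acid
OC(C(O)C(=O)O)C(=O)O tartaric_acid
OC(=O)CC(O)(CC(=O)O)C(=O)O citric_acid
O=C(O)CCC(=O)O succinic_acid
O=P(O)(O)O phosphoric_acid
OC=O formic_acid
O=C(O)O carbonic_acid
OS(=O)O sulfurous_acid
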