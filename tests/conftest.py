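import pandas as pd
import pytest

from abxspace.synthetic import TEMPLATES, GeneratorSpec, write_dataset

#: structures spanning the chemotypes the standardizer must handle:
#: every generator template plus salt forms, drawing variants and
#: pre-ionized inputs.
FIXTURE_SMILES = [smi for _, smi, _ in TEMPLATES] + [
    "C1=CC=CC=C1",                       # kekulized benzene
    "O=[N+]([O-])c1ccccc1",              # nitrobenzene, charge-separated
    "OC(=O)c1ccccc1",                    # benzoic acid
    "[O-]C(=O)c1ccccc1.[Na+]",           # sodium benzoate
    "Cl.NCc1ccccc1",                     # benzylamine hydrochloride
    "NCC(=O)O",                          # glycine, neutral drawing
    "[NH3+]CC(=O)[O-]",                  # glycine, zwitterion drawing
    "O=C(O)c1cn(C2CC2)c2cc(N3CCNCC3)c(F)cc2c1=O",   # ciprofloxacin
    "CC(=O)NS(=O)(=O)c1ccc(N)cc1",       # sulfanilamide-like acyl sulfonamide
    "Oc1ccccc1",                         # phenol (stays neutral)
    "c1ccncc1",                          # pyridine (stays neutral)
    "CC(=O)Nc1ccccc1",                   # acetanilide (amide stays neutral)
    "CCN(CC)CC",                         # triethylamine
    "NC(=N)c1ccccc1",                    # benzamidine
    "CCCCCCCCCC(=O)O",                   # fatty acid
    "C[N+](C)(C)CCO",                    # choline (permanent cation)
]


@pytest.fixture(scope="session")
def fixture_smiles():
    return list(FIXTURE_SMILES)


@pytest.fixture(scope="session")
def small_spec():
    return GeneratorSpec(n_compounds=200, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_spec, tmp_path_factory):
    """A generated 200-compound dataset shared across read-only tests."""
    outdir = tmp_path_factory.mktemp("synthetic")
    paths = write_dataset(small_spec, outdir)
    manifest = pd.read_csv(paths["manifest"])
    return {"spec": small_spec, "paths": paths, "manifest": manifest}
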