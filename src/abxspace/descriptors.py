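"""The nine property descriptors and Morgan fingerprints.

Properties are computed on the standardized pH 7.4 form, except logP
which is evaluated on the neutral parent so that logP and logD(7.4)
remain comparable. logD(7.4) is obtained from logP by the closed-form
Henderson–Hasselbalch correction using the rule pKas recorded by the
standardizer: each deprotonatable acid contributes
log10(1 + 10^(pH − pKa)) and each protonatable base
log10(1 + 10^(pKa − pH)), both subtracted from logP. Descriptor
schemes are the standard open atom/fragment-contribution ones
(Crippen logP, Ertl TPSA, Lipinski N/O-count acceptors and NH/OH
donors); absolute values can differ from commercial calculators, the
distributional comparisons do not depend on that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdFingerprintGenerator, rdMolDescriptors

from .standardize import IonizableGroup, StandardizedMolecule, neutral_parent

PH = 7.4
FP_BITS = 2048
FP_RADIUS = 2          # diameter 4

PROPERTY_NAMES = ("mw", "logp", "logd74", "hba", "hbd", "rot_bonds", "rings", "tpsa")


@dataclass(frozen=True)
class PropertyVector:
    compound_id: str
    mw: float
    logp: float
    logd74: float
    hba: int
    hbd: int
    rot_bonds: int
    rings: int
    tpsa: float
    charge_class: str

    def as_dict(self) -> dict:
        return {
            "compound_id": self.compound_id, "mw": self.mw, "logp": self.logp,
            "logd74": self.logd74, "hba": self.hba, "hbd": self.hbd,
            "rot_bonds": self.rot_bonds, "rings": self.rings, "tpsa": self.tpsa,
            "charge_class": self.charge_class,
        }


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary Morgan fingerprint."""

    bits: np.ndarray     # uint8 0/1, length 2048

    def __post_init__(self):
        if self.bits.shape != (FP_BITS,):
            raise ValueError(f"fingerprint must have exactly {FP_BITS} bits")

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


def compute_logd74(logp: float, ionizable_groups: list[IonizableGroup], ph: float = PH) -> float:
    """Closed-form logD at the given pH from logP and rule pKas."""
    correction = 0.0
    for group in ionizable_groups:
        if group.action == "deprotonate":      # acid
            correction += math.log10(1.0 + 10.0 ** (ph - group.pka))
        else:                                  # base
            correction += math.log10(1.0 + 10.0 ** (group.pka - ph))
    return logp - correction


def compute_properties(standardized: StandardizedMolecule) -> PropertyVector:
    """Compute the nine-property vector for one standardized molecule."""
    mol = standardized.mol()
    if mol is None:
        raise ValueError(f"{standardized.compound_id}: unparsable standardized structure")
    parent = Chem.MolFromSmiles(neutral_parent(standardized.smiles))
    logp = Crippen.MolLogP(parent)
    return PropertyVector(
        compound_id=standardized.compound_id,
        mw=Descriptors.MolWt(mol),
        logp=logp,
        logd74=compute_logd74(logp, standardized.ionizable_groups),
        hba=rdMolDescriptors.CalcNumLipinskiHBA(mol),
        hbd=rdMolDescriptors.CalcNumLipinskiHBD(mol),
        rot_bonds=rdMolDescriptors.CalcNumRotatableBonds(mol),
        rings=rdMolDescriptors.CalcNumRings(mol),
        tpsa=Descriptors.TPSA(mol),
        charge_class=standardized.charge_class,
    )


_FP_GENERATOR = rdFingerprintGenerator.GetMorganGenerator(radius=FP_RADIUS, fpSize=FP_BITS)


def compute_fingerprint(standardized: StandardizedMolecule | str) -> Fingerprint:
    """2048-bit Morgan (ECFP-like, diameter 4) fingerprint."""
    smiles = standardized.smiles if isinstance(standardized, StandardizedMolecule) else standardized
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError(f"cannot fingerprint empty or unparsable structure {smiles!r}")
    bv = _FP_GENERATOR.GetFingerprint(mol)
    bits = np.zeros(FP_BITS, dtype=np.uint8)
    bits[list(bv.GetOnBits())] = 1
    return Fingerprint(bits=bits)


def properties_table(vectors: list[PropertyVector]) -> pd.DataFrame:
    """One row per compound, columns as in the property vector."""
    return pd.DataFrame([v.as_dict() for v in vectors]).set_index("compound_id")
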