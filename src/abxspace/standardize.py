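"""Three-step structure standardization and pH 7.4 charge-class assignment.

Before any property is computed every structure passes through

1. representation normalization — a consistent aromatic form and a
   single canonical drawing of groups such as nitro (the pentavalent
   and charge-separated forms collapse to one),
2. salt stripping — components on a configurable list of known
   counter-ions are removed and, if several components remain, the
   largest (most heavy atoms) is kept,
3. ionization at pH 7.4 — a data-driven table of SMARTS rules
   deprotonates acidic groups (carboxylic, sulfonic and phosphonic
   acids, tetrazoles, acyl sulfonamides) and protonates basic ones
   (aliphatic amines, amidines, guanidines); borderline groups such as
   phenols, anilines and pyridines are left neutral by default.

The result carries a charge class (acidic / basic / neutral /
zwitterionic) read off the ionized form, the list of ionizable groups
that fired (with their rule pKas, used later for the logD correction)
and a provenance record of every change applied. Standardization is
idempotent and independent of input atom ordering.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")
logger = logging.getLogger(__name__)

CHARGE_CLASSES = ("acidic", "basic", "neutral", "zwitterionic")


class StandardizationError(ValueError):
    def __init__(self, compound_id: str, message: str):
        self.compound_id = compound_id
        super().__init__(f"{compound_id}: {message}")


@dataclass(frozen=True)
class IonizationRule:
    name: str
    smarts: str
    atom_index: int
    action: str          # deprotonate | protonate
    pka: float

    def pattern(self):
        patt = Chem.MolFromSmarts(self.smarts)
        if patt is None:
            raise ValueError(f"invalid SMARTS in rule {self.name}: {self.smarts}")
        return patt


@dataclass(frozen=True)
class IonizableGroup:
    """One ionization-rule firing: feeds the logD(7.4) correction."""
    rule: str
    action: str
    pka: float


@dataclass
class StandardizedMolecule:
    compound_id: str
    smiles: str                                  # canonical, single component, pH 7.4 form
    charge_class: str
    ionizable_groups: list[IonizableGroup] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)


def _load_rules(path: str | Path | None = None) -> list[IonizationRule]:
    if path is None:
        source = resources.files("abxspace.data").joinpath("ionization_rules.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    rules = []
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        rules.append(IonizationRule(
            name=row["name"], smarts=row["smarts"],
            atom_index=int(row["atom_index"]), action=row["action"],
            pka=float(row["pka"]),
        ))
    return rules


def _load_salts(path: str | Path | None = None) -> set[str]:
    if path is None:
        text = resources.files("abxspace.data").joinpath("salts.smi").read_text()
    else:
        text = Path(path).read_text()
    salts = set()
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        smiles = line.split()[0]
        mol = Chem.MolFromSmiles(smiles)
        if mol is not None:
            salts.add(Chem.MolToSmiles(mol))
    return salts


_DEFAULT_RULES: list[IonizationRule] | None = None
_DEFAULT_SALTS: set[str] | None = None


def default_rules() -> list[IonizationRule]:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = _load_rules()
    return _DEFAULT_RULES


def default_salts() -> set[str]:
    global _DEFAULT_SALTS
    if _DEFAULT_SALTS is None:
        _DEFAULT_SALTS = _load_salts()
    return _DEFAULT_SALTS


load_rules = _load_rules
load_salts = _load_salts


# -- step 1: representation normalization ------------------------------------

def normalize_representation(structure: str | Chem.Mol, compound_id: str = "?") -> str:
    """Return the canonical SMILES with a consistent representation.

    Aromatic rings are perceived and written in aromatic form; common
    functional-group drawing variants (e.g. pentavalent vs
    charge-separated nitro) collapse to one canonical form.
    """
    if isinstance(structure, Chem.Mol):
        mol = structure
    else:
        mol = Chem.MolFromSmiles(structure)
        if mol is None:
            # tolerate valence drawings that the normalizer fixes (nitro)
            raw = Chem.MolFromSmiles(structure, sanitize=False)
            if raw is None:
                raise StandardizationError(compound_id, f"unparsable structure {structure!r}")
            try:
                mol = rdMolStandardize.Cleanup(raw)
            except Exception as exc:  # pragma: no cover - rdkit-internal failures
                raise StandardizationError(compound_id, f"cannot normalize: {exc}")
            if mol is None:
                raise StandardizationError(compound_id, f"cannot normalize {structure!r}")
            return Chem.MolToSmiles(mol)
    mol = rdMolStandardize.Normalize(mol)
    return Chem.MolToSmiles(mol)


# -- step 2: salt stripping ---------------------------------------------------

def strip_salts(
    structure: str,
    salt_list: set[str] | None = None,
) -> tuple[str, list[str], bool]:
    """Remove known counter-ion components; keep the largest remainder.

    Returns (kept_smiles, stripped_components, all_components_were_salts).
    Never returns an empty structure: when every component is on the
    salt list the largest one is kept and flagged.
    """
    salts = salt_list if salt_list is not None else default_salts()
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"unparsable structure {structure!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        return Chem.MolToSmiles(frags[0]), [], False

    components = [(Chem.MolToSmiles(f), f.GetNumHeavyAtoms()) for f in frags]
    kept = [(s, n) for s, n in components if s not in salts]
    stripped = [s for s, _ in components if s in salts]
    all_salts = not kept
    if all_salts:
        kept = components
        stripped = []
        logger.warning("all components are known salts; keeping the largest: %s", structure)
    if len(kept) > 1:
        # keep the largest; ties broken by canonical SMILES for determinism
        largest = max(kept, key=lambda t: (t[1], t[0]))
        stripped.extend(s for s, _ in kept if s != largest[0])
        kept = [largest]
    return kept[0][0], stripped, all_salts


# -- step 3: ionization at pH 7.4 ---------------------------------------------

def ionize_at_ph74(
    structure: str,
    rules: list[IonizationRule] | None = None,
) -> tuple[str, list[IonizableGroup]]:
    """Set the most prevalent ionization state at pH 7.4 by SMARTS rules.

    Reversible protonation states present in the input are first
    neutralized (so the step is idempotent), then each rule fires on
    the atoms it matches: acids lose a proton, bases gain one. When two
    rules claim the same atom the first rule in the table wins and a
    warning is logged. Returns the ionized canonical SMILES plus the
    fired groups.
    """
    rules = rules if rules is not None else default_rules()
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"unparsable structure {structure!r}")
    mol = rdMolStandardize.Uncharger().uncharge(mol)
    Chem.SanitizeMol(mol)

    claimed: set[int] = set()
    fired: list[IonizableGroup] = []
    plan: list[tuple[int, IonizationRule]] = []
    for rule in rules:
        patt = rule.pattern()
        seen_here: set[int] = set()
        for match in mol.GetSubstructMatches(patt):
            idx = match[rule.atom_index]
            if idx in seen_here:
                continue
            seen_here.add(idx)
            if idx in claimed:
                logger.warning("rule %s skipped on atom %d: already claimed", rule.name, idx)
                continue
            claimed.add(idx)
            plan.append((idx, rule))
    for idx, rule in plan:
        atom = mol.GetAtomWithIdx(idx)
        n_h = atom.GetTotalNumHs()
        if rule.action == "deprotonate":
            if n_h < 1:
                continue
            atom.SetFormalCharge(atom.GetFormalCharge() - 1)
            atom.SetNumExplicitHs(n_h - 1)
            atom.SetNoImplicit(True)
        elif rule.action == "protonate":
            atom.SetFormalCharge(atom.GetFormalCharge() + 1)
            atom.SetNumExplicitHs(n_h + 1)
            atom.SetNoImplicit(True)
        else:
            raise ValueError(f"unknown rule action {rule.action!r}")
        fired.append(IonizableGroup(rule=rule.name, action=rule.action, pka=rule.pka))
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol), fired


def neutral_parent(smiles: str) -> str:
    """The neutralized form of a standardized structure (for logP)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable structure {smiles!r}")
    mol = rdMolStandardize.Uncharger().uncharge(mol)
    return Chem.MolToSmiles(mol)


# -- charge class --------------------------------------------------------------

def assign_charge_class(structure: str | Chem.Mol) -> str:
    """Classify the pH 7.4 form as acidic/basic/neutral/zwitterionic.

    An anionic centre whose charge is not balanced by an adjacent
    cationic atom (so internally charge-separated groups like nitro do
    not count) marks the molecule acidic; an unbalanced cationic centre
    marks it basic; both together make a zwitterion.
    """
    mol = structure if isinstance(structure, Chem.Mol) else Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError("unparsable structure")
    has_anion = has_cation = False
    for atom in mol.GetAtoms():
        charge = atom.GetFormalCharge()
        if charge == 0:
            continue
        neighbor_charges = [n.GetFormalCharge() for n in atom.GetNeighbors()]
        if charge < 0 and not any(c > 0 for c in neighbor_charges):
            has_anion = True
        elif charge > 0 and not any(c < 0 for c in neighbor_charges):
            has_cation = True
    if has_anion and has_cation:
        return "zwitterionic"
    if has_anion:
        return "acidic"
    if has_cation:
        return "basic"
    return "neutral"


# -- the composed three-step procedure -----------------------------------------

def standardize(
    structure: str,
    compound_id: str = "?",
    salt_list: set[str] | None = None,
    rules: list[IonizationRule] | None = None,
) -> StandardizedMolecule:
    """Run the full three-step standardization on one structure.

    Composition: representation normalization, then salt stripping,
    then pH 7.4 ionization, then charge-class assignment. Provenance
    records only the steps that actually changed the structure, so an
    already-standard molecule comes back with empty provenance.
    """
    provenance: dict = {}
    normalized = normalize_representation(structure, compound_id)
    input_canonical = None
    raw_mol = Chem.MolFromSmiles(structure)
    if raw_mol is not None:
        input_canonical = Chem.MolToSmiles(raw_mol)
    if normalized != input_canonical:
        provenance["normalized"] = True

    try:
        stripped, removed, all_salts = strip_salts(normalized, salt_list)
    except ValueError as exc:
        raise StandardizationError(compound_id, str(exc))
    if removed:
        provenance["stripped_salts"] = removed
    if all_salts:
        provenance["all_components_salts"] = True

    ionized, fired = ionize_at_ph74(stripped, rules)
    if ionized != stripped:
        provenance["ionization_changed"] = True

    mol = Chem.MolFromSmiles(ionized)
    if mol is None or mol.GetNumAtoms() == 0:
        raise StandardizationError(compound_id, "standardization produced an empty structure")
    if len(Chem.GetMolFrags(mol)) != 1:
        raise StandardizationError(compound_id, "multiple components survived standardization")

    return StandardizedMolecule(
        compound_id=compound_id,
        smiles=ionized,
        charge_class=assign_charge_class(mol),
        ionizable_groups=fired,
        provenance=provenance,
    )
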