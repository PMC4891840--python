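"""ChEMBL-like synthetic fixtures with known ground truth.

The generator emits the three flat files the readers consume — a
SMILES+ID structure file, an activity table and a drug-annotation
table — plus a manifest recording every design decision it made, so
the whole pipeline can be exercised and checked without downloading
ChEMBL.

Structures are assembled from a fixed template library spanning
neutral, acidic, basic and zwitterionic chemotypes (including
beta-lactam, fluoroquinolone and oxazolidinone cores for the
chemotype analysis); molecular weight is tuned per compound by
homologous alkyl-chain extension toward a target drawn around the
configured per-group median, which makes designed medians recoverable
to within the chain lattice (±7 Da) plus order-statistic noise.
Activity labels are constructed decisively — no record sits near a
cutoff boundary — so designed set memberships are recovered exactly;
the statistical tolerance is confined to the property summaries.
Measurements mix µg/ml and µM units (with the conversion baked in),
censored relation qualifiers, Gram-positive/negative/unclassified
assay organisms and per-year publication dates. The same spec and
seed always reproduce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from .standardize import standardize

CH2 = 14.0266          # mass of one methylene unit, Da
MAX_CHAIN = 30

#: (template name, SMILES, designed charge class). Every SMILES starts
#: with an sp3 carbon so that prefixing "C"s extends an alkyl chain.
TEMPLATES: tuple[tuple[str, str, str], ...] = (
    ("alkylbenzene",      "CCc1ccccc1",                                        "neutral"),
    ("aryl_ester",        "CCOC(=O)c1ccc(OC)cc1",                              "neutral"),
    ("anilide",           "CCC(=O)Nc1ccc(Cl)cc1",                              "neutral"),
    ("benzimidazole",     "CCOc1ccc2[nH]c(C)nc2c1",                            "neutral"),
    ("aryl_sulfone",      "CCS(=O)(=O)c1ccccc1",                               "neutral"),
    ("oxazolidinone",     "CC(=O)NCC1CN(c2ccc(N3CCOCC3)c(F)c2)C(=O)O1",        "neutral"),
    ("benzoic_acid",      "CCc1ccc(C(=O)O)cc1",                                "acidic"),
    ("profen",            "CCC(C)c1ccc(C(C)C(=O)O)cc1",                        "acidic"),
    ("aryl_tetrazole",    "CCc1ccc(-c2nnn[nH]2)cc1",                           "acidic"),
    ("acyl_sulfonamide",  "CCC(=O)NS(=O)(=O)c1ccccc1",                         "acidic"),
    ("penicillin",        "CC1(C)SC2C(NC(=O)Cc3ccccc3)C(=O)N2C1C(=O)O",        "acidic"),
    ("benzylamine",       "CCc1ccc(CN)cc1",                                    "basic"),
    ("aminoamide",        "CCN(CC)CCNC(=O)c1ccccc1",                           "basic"),
    ("piperidine",        "CCC1CCNCC1",                                        "basic"),
    ("arylpiperazine",    "CCN1CCN(c2ccccc2)CC1",                              "basic"),
    ("amino_acid",        "CCC(N)C(=O)O",                                      "zwitterionic"),
    ("fluoroquinolone",   "CCN1CCN(c2cc3c(cc2F)c(=O)c(C(=O)O)cn3C3CC3)CC1",    "zwitterionic"),
    ("amino_benzoic",     "CCC(CN)c1ccc(C(=O)O)cc1",                           "zwitterionic"),
)

GRAM_POSITIVE_ORGANISMS = (
    "Staphylococcus aureus", "Enterococcus faecalis", "Streptococcus pneumoniae",
    "Bacillus subtilis",
)
GRAM_NEGATIVE_ORGANISMS = (
    "Escherichia coli", "Klebsiella pneumoniae", "Pseudomonas aeruginosa",
    "Acinetobacter baumannii",
)
UNCLASSIFIED_ORGANISMS = ("Mycoplasma genitalium", "Chlamydia trachomatis")

MOD_THERAPEUTIC_CLASSES = ("cardiovascular", "oncology", "cns", "antiviral", "metabolic")


@dataclass
class GeneratorSpec:
    """All knobs of the synthetic study: sizes, mixes, effect designs."""

    n_compounds: int = 600
    seed: int = 0
    # marketed-drug annotation fractions (disjoint by construction)
    mad_fraction: float = 0.05
    mod_fraction: float = 0.15
    # activity design over research (non-drug) compounds
    ab_active_fraction: float = 0.35
    ab_inactive_fraction: float = 0.10
    bio_overlap_fraction: float = 0.25        # of antibacterial actives -> also biochemically active (BAAA)
    bio_active_untested_fraction: float = 0.30  # of ab-untested research -> biochemically active only (BAAI)
    bio_inactive_fraction: float = 0.10       # of ab-untested research -> biochemically inactive only
    slightly_active_fraction: float = 0.05    # of research -> only SA antibacterial records
    censored_fraction: float = 0.20           # records with a decisive <=/> qualifier
    unit_um_fraction: float = 0.30            # antibacterial records expressed in uM
    second_record_fraction: float = 0.30      # ab actives with a second assay record
    # organism mix for antibacterial assays
    gram_pos_fraction: float = 0.50
    gram_neg_fraction: float = 0.40
    # structures
    salt_fraction: float = 0.15
    charge_mix: dict[str, float] = field(default_factory=lambda: {
        "neutral": 0.55, "acidic": 0.15, "basic": 0.20, "zwitterionic": 0.10})
    charge_mix_mad: dict[str, float] = field(default_factory=lambda: {
        "neutral": 0.25, "acidic": 0.30, "basic": 0.20, "zwitterionic": 0.25})
    charge_mix_mod: dict[str, float] = field(default_factory=lambda: {
        "neutral": 0.50, "acidic": 0.15, "basic": 0.30, "zwitterionic": 0.05})
    # molecular-weight design (Da)
    mw_median_research: float = 385.0
    mw_median_mad: float = 420.0
    mw_median_mod: float = 320.0
    mw_sd: float = 60.0
    # publication years
    year_range: tuple[int, int] = (1975, 2015)
    year_shift: tuple[int, float] | None = None   # (year, +delta Da) step effect

    def __post_init__(self):
        for name in ("mad_fraction", "mod_fraction", "ab_active_fraction",
                     "ab_inactive_fraction", "bio_overlap_fraction",
                     "bio_active_untested_fraction", "bio_inactive_fraction",
                     "slightly_active_fraction", "censored_fraction",
                     "unit_um_fraction", "gram_pos_fraction",
                     "gram_neg_fraction", "salt_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_compounds < 0:
            raise ValueError("n_compounds must be non-negative")
        if self.mad_fraction + self.mod_fraction > 1.0:
            raise ValueError("mad_fraction + mod_fraction must not exceed 1")
        if self.gram_pos_fraction + self.gram_neg_fraction > 1.0:
            raise ValueError("gram fractions must not exceed 1")


_TEMPLATE_MW: dict[str, float] | None = None


def _template_mw() -> dict[str, float]:
    global _TEMPLATE_MW
    if _TEMPLATE_MW is None:
        _TEMPLATE_MW = {
            name: Descriptors.MolWt(Chem.MolFromSmiles(smi)) for name, smi, _ in TEMPLATES
        }
    return _TEMPLATE_MW


def _extend_chain(smiles: str, n_units: int) -> str:
    """Prefix n methylene units onto the template's leading alkyl chain."""
    return "C" * n_units + smiles


def _pick_class(rng: np.random.Generator, mix: dict[str, float]) -> str:
    classes = sorted(mix)
    probs = np.array([mix[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    return classes[rng.choice(len(classes), p=probs)]


def _sodium_salt_form(parent_smiles: str) -> str | None:
    """Sodium salt of an acidic parent: ionized anion + [Na+]."""
    from .standardize import ionize_at_ph74
    ionized, fired = ionize_at_ph74(parent_smiles)
    if not any(g.action == "deprotonate" for g in fired):
        return None
    return ionized + ".[Na+]"


def generate_compounds(spec: GeneratorSpec) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Build the structure list and the ground-truth manifest.

    Returns ``(structures, manifest)`` where structures is a list of
    (compound_id, SMILES-as-written) pairs (salt-bearing records are
    multi-component) and the manifest records each compound's template,
    designed charge class, role, activity design, year and target
    molecular weight.
    """
    rng = np.random.default_rng([spec.seed, 0])
    n = spec.n_compounds
    template_mw = _template_mw()
    by_class: dict[str, list[tuple[str, str]]] = {}
    for name, smi, cls in TEMPLATES:
        by_class.setdefault(cls, []).append((name, smi))

    # roles: exact counts from shuffled indices
    n_mad = round(spec.mad_fraction * n)
    n_mod = round(spec.mod_fraction * n)
    order = rng.permutation(n)
    roles = np.array(["research"] * n, dtype=object)
    roles[order[:n_mad]] = "mad"
    roles[order[n_mad:n_mad + n_mod]] = "mod"

    research_idx = [i for i in range(n) if roles[i] == "research"]
    m = len(research_idx)
    shuffled = list(rng.permutation(research_idx))
    n_ab_active = round(spec.ab_active_fraction * m)
    n_ab_inactive = round(spec.ab_inactive_fraction * m)
    ab_active = shuffled[:n_ab_active]
    ab_inactive = shuffled[n_ab_active:n_ab_active + n_ab_inactive]
    untested_pool = shuffled[n_ab_active + n_ab_inactive:]

    n_baaa = round(spec.bio_overlap_fraction * len(ab_active))
    baaa = set(ab_active[:n_baaa])
    n_baai = round(spec.bio_active_untested_fraction * len(untested_pool))
    n_bi = round(spec.bio_inactive_fraction * len(untested_pool))
    baai = set(untested_pool[:n_baai])
    bio_inactive = set(untested_pool[n_baai:n_baai + n_bi])
    rest = untested_pool[n_baai + n_bi:]
    n_sa = min(len(rest), round(spec.slightly_active_fraction * m))
    slightly = set(rest[:n_sa])

    ab_design = np.array(["untested"] * n, dtype=object)
    for i in ab_active:
        ab_design[i] = "active"
    for i in ab_inactive:
        ab_design[i] = "inactive"
    for i in slightly:
        ab_design[i] = "slightly"
    bio_design = np.array(["untested"] * n, dtype=object)
    for i in baaa:
        bio_design[i] = "active"
    for i in baai:
        bio_design[i] = "active"
    for i in bio_inactive:
        bio_design[i] = "inactive"

    # designed Gram classes for antibacterial actives
    p_unclassified = max(0.0, 1.0 - spec.gram_pos_fraction - spec.gram_neg_fraction)
    gram_choices = ("gram_positive", "gram_negative", "unclassified")
    gram_probs = np.array([spec.gram_pos_fraction, spec.gram_neg_fraction, p_unclassified])
    gram_probs = gram_probs / gram_probs.sum()

    # salts: exact count
    salt_ids = set(rng.permutation(n)[:round(spec.salt_fraction * n)].tolist())

    rows = []
    structures: list[tuple[str, str]] = []
    for i in range(n):
        role = roles[i]
        if role == "mad":
            mix, mw_median = spec.charge_mix_mad, spec.mw_median_mad
        elif role == "mod":
            mix, mw_median = spec.charge_mix_mod, spec.mw_median_mod
        else:
            mix, mw_median = spec.charge_mix, spec.mw_median_research
        charge_class = _pick_class(rng, mix)

        year = int(rng.integers(spec.year_range[0], spec.year_range[1] + 1))
        target_mw = float(rng.normal(mw_median, spec.mw_sd))
        if spec.year_shift is not None and year >= spec.year_shift[0]:
            target_mw += spec.year_shift[1]

        pool = by_class[charge_class]
        eligible = [t for t in pool if template_mw[t[0]] <= target_mw]
        if eligible:
            tname, tsmi = eligible[rng.integers(len(eligible))]
        else:
            tname, tsmi = min(pool, key=lambda t: template_mw[t[0]])
        k = int(np.clip(round((target_mw - template_mw[tname]) / CH2), 0, MAX_CHAIN))
        parent = _extend_chain(tsmi, k)

        salt_partner = ""
        written = parent
        if i in salt_ids:
            if charge_class in ("basic", "zwitterionic"):
                salt_partner = "Cl"
                written = parent + ".Cl"
            elif charge_class == "acidic" and rng.random() < 0.5:
                sodium = _sodium_salt_form(parent)
                if sodium is not None:
                    salt_partner = "[Na+]"
                    written = sodium
                else:  # pragma: no cover - acidic templates always ionize
                    salt_partner = "O"
                    written = parent + ".O"
            else:
                salt_partner = "O"
                written = parent + ".O"

        gram_classes: set[str] = set()
        if ab_design[i] == "active":
            gram_classes.add(gram_choices[rng.choice(3, p=gram_probs)])
            if rng.random() < spec.second_record_fraction:
                gram_classes.add(gram_choices[rng.choice(3, p=gram_probs)])

        cid = f"SYN{i:06d}"
        structures.append((cid, written))
        rows.append({
            "compound_id": cid,
            "smiles": written,
            "parent_smiles": Chem.MolToSmiles(Chem.MolFromSmiles(parent)),
            "template": tname,
            "charge_class": charge_class,
            "role": role,
            "ab_design": ab_design[i],
            "bio_design": bio_design[i],
            "year": year,
            "target_mw": round(target_mw, 2),
            "actual_mw": round(Descriptors.MolWt(Chem.MolFromSmiles(parent)), 2),
            "salt_partner": salt_partner,
            "gram_positive_active": "gram_positive" in gram_classes,
            "gram_negative_active": "gram_negative" in gram_classes,
        })
    manifest = pd.DataFrame(rows, columns=[
        "compound_id", "smiles", "parent_smiles", "template", "charge_class",
        "role", "ab_design", "bio_design", "year", "target_mw", "actual_mw",
        "salt_partner", "gram_positive_active", "gram_negative_active",
    ])
    return structures, manifest


def _assay_pools(spec: GeneratorSpec, rng: np.random.Generator):
    """Fixed pools of antibacterial assays (with organisms) and biochemical assays."""
    ab_assays = {"gram_positive": [], "gram_negative": [], "unclassified": []}
    organisms = {
        "gram_positive": GRAM_POSITIVE_ORGANISMS,
        "gram_negative": GRAM_NEGATIVE_ORGANISMS,
        "unclassified": UNCLASSIFIED_ORGANISMS,
    }
    k = 0
    for gram_class, names in organisms.items():
        for name in names:
            for _ in range(2):
                ab_assays[gram_class].append((f"AB{k:04d}", name))
                k += 1
    bio_assays = [(f"BIO{j:04d}", "") for j in range(16)]
    return ab_assays, bio_assays


def _round_value(v: float) -> float:
    return float(f"{v:.4g}")


def generate_activities(spec: GeneratorSpec, manifest: pd.DataFrame) -> pd.DataFrame:
    """Materialize the designed activity labels as decisive assay records.

    Every designed antibacterial active gets at least one record that
    provably labels A under the default cutoffs (value well inside the
    band, or a censored upper bound below the active cutoff); designed
    inactives get only I-proving records; the slightly-active design
    yields only SA records. Units are drawn per the configured
    µg/ml : µM mix with the molar conversion baked in against the
    parent molecular weight; values keep a safety margin from every
    cutoff so that unit round-tripping never flips a label.
    """
    rng = np.random.default_rng([spec.seed, 1])
    ab_assays, bio_assays = _assay_pools(spec, rng)
    mw = {row.compound_id: row.actual_mw for row in manifest.itertuples()}

    records = []

    def add_ab(cid: str, gram_class: str, kind: str, year: int):
        assay_id, organism = ab_assays[gram_class][rng.integers(len(ab_assays[gram_class]))]
        censored = rng.random() < spec.censored_fraction
        if kind == "A":
            value_ug = rng.uniform(0.5, 7.5)
            relation = "<=" if censored else "="
        elif kind == "SA":
            value_ug = rng.uniform(9.5, 30.0)
            relation = "="
        else:  # I
            value_ug = rng.uniform(34.0, 256.0)
            relation = ">" if censored else "="
        if rng.random() < spec.unit_um_fraction:
            units, value = "uM", _round_value(value_ug * 1000.0 / mw[cid])
        else:
            units, value = "ug/ml", _round_value(value_ug)
        records.append({
            "compound_id": cid, "assay_id": assay_id, "assay_class": "antibacterial",
            "target_type": "ORGANISM", "organism": organism, "activity_type": "MIC",
            "value": value, "units": units, "relation": relation, "year": year,
        })

    def add_bio(cid: str, kind: str, year: int):
        assay_id, organism = bio_assays[rng.integers(len(bio_assays))]
        censored = rng.random() < spec.censored_fraction
        if kind == "A":
            value_um = rng.uniform(0.05, 9.5)
            relation = "<=" if censored else "="
        else:
            value_um = rng.uniform(110.0, 1000.0)
            relation = "="
        activity_type = "IC50" if rng.random() < 0.7 else "Ki"
        records.append({
            "compound_id": cid, "assay_id": assay_id, "assay_class": "biochemical",
            "target_type": "SINGLE PROTEIN", "organism": organism,
            "activity_type": activity_type, "value": _round_value(value_um),
            "units": "uM", "relation": relation, "year": year,
        })

    for row in manifest.itertuples():
        year = int(row.year)
        if row.ab_design == "active":
            classes = []
            if row.gram_positive_active:
                classes.append("gram_positive")
            if row.gram_negative_active:
                classes.append("gram_negative")
            if not classes:
                classes.append("unclassified")
            for gram_class in classes:
                add_ab(row.compound_id, gram_class, "A", year)
        elif row.ab_design == "inactive":
            for _ in range(1 + int(rng.random() < spec.second_record_fraction)):
                gram_class = ("gram_positive", "gram_negative", "unclassified")[rng.integers(3)]
                add_ab(row.compound_id, gram_class, "I", year)
        elif row.ab_design == "slightly":
            gram_class = ("gram_positive", "gram_negative")[rng.integers(2)]
            add_ab(row.compound_id, gram_class, "SA", year)
        if row.bio_design == "active":
            add_bio(row.compound_id, "A", year)
        elif row.bio_design == "inactive":
            add_bio(row.compound_id, "I", year)

    return pd.DataFrame(records, columns=[
        "compound_id", "assay_id", "assay_class", "target_type", "organism",
        "activity_type", "value", "units", "relation", "year",
    ])


def generate_drug_annotations(spec: GeneratorSpec, manifest: pd.DataFrame) -> pd.DataFrame:
    """Approval flags: MAD compounds antibacterial, MOD other classes."""
    rng = np.random.default_rng([spec.seed, 2])
    rows = []
    for row in manifest.itertuples():
        if row.role == "mad":
            approved, tclass = 1, "antibacterial"
        elif row.role == "mod":
            approved, tclass = 1, MOD_THERAPEUTIC_CLASSES[rng.integers(len(MOD_THERAPEUTIC_CLASSES))]
        else:
            approved, tclass = 0, ""
        rows.append({
            "compound_id": row.compound_id, "approved": approved,
            "therapeutic_class": tclass, "first_year": int(row.year),
        })
    return pd.DataFrame(rows, columns=["compound_id", "approved", "therapeutic_class", "first_year"])


def designed_sets(manifest: pd.DataFrame) -> dict[str, set[str]]:
    """Ground-truth memberships of the eight analysis sets."""
    def ids(mask) -> set[str]:
        return set(manifest.loc[mask, "compound_id"])

    ab, bio, role = manifest["ab_design"], manifest["bio_design"], manifest["role"]
    return {
        "AA": ids(ab == "active"),
        "AI": ids(ab == "inactive"),
        "BA": ids(bio == "active"),
        "BI": ids(bio == "inactive"),
        "BAAA": ids((ab == "active") & (bio == "active")),
        "BAAI": ids((ab == "untested") & (bio == "active")),
        "MAD": ids(role == "mad"),
        "MOD": ids(role == "mod"),
    }


def write_dataset(spec: GeneratorSpec, outdir: str | Path) -> dict[str, Path]:
    """Generate and write all four files; returns their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    structures, manifest = generate_compounds(spec)
    activities = generate_activities(spec, manifest)
    annotations = generate_drug_annotations(spec, manifest)
    paths = {
        "compounds": outdir / "compounds.smi",
        "activities": outdir / "activities.csv",
        "annotations": outdir / "annotations.csv",
        "manifest": outdir / "manifest.csv",
    }
    with open(paths["compounds"], "w") as fh:
        for cid, smiles in structures:
            fh.write(f"{smiles}\t{cid}\n")
    activities.to_csv(paths["activities"], index=False)
    annotations.to_csv(paths["annotations"], index=False)
    manifest.to_csv(paths["manifest"], index=False)
    return paths
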