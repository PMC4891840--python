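"""Activity labelling matrices and the quantified compound-set definitions.

Every assay measurement is mapped to one of three labels — active (A),
slightly active (SA) or inactive (I) — using concentration cutoff bands
configured per assay class. Two sparse compound × assay matrices (one
for growth-inhibition assays, one for biochemical assays) hold the
labels; untested pairs are simply absent. Compound-level activity then
follows two quantified definitions over a compound's tested entries:

* active:   at least one A and no I,
* inactive: at least one tested entry and every tested entry is I,

and everything else (only SA, or a mix of A and I) is indeterminate.
The eight analysis sets (AA, AI, BA, BI, BAAA, BAAI, MAD, MOD) are
derived from the two matrices plus the marketed-drug annotations.
"""

from __future__ import annotations

import csv
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .chembl_io import AssayRecord, CompoundRecord, FilterSpec

LABELS = ("A", "SA", "I")
_LABEL_RANK = {"A": 2, "SA": 1, "I": 0}   # best-label aggregation order

SET_LABELS = ("AA", "AI", "BA", "BI", "BAAA", "BAAI", "MAD", "MOD")


def convert_value(value: float, units: str, assay_class: str, mol_weight: float | None) -> float | None:
    """Convert a measurement onto its assay class's native scale.

    Antibacterial potency is expressed in µg/ml, biochemical potency in
    µM; conversion between the two uses µM = 1000 × (µg/ml) / MW.
    Returns None when conversion is impossible (unknown units, missing
    molecular weight).
    """
    native = "ug_per_ml" if assay_class == "antibacterial" else "uM"
    if units == native:
        return value
    if units == "unknown" or mol_weight is None or mol_weight <= 0:
        return None
    if native == "ug_per_ml":            # uM -> ug/ml
        return value * mol_weight / 1000.0
    return value * 1000.0 / mol_weight   # ug/ml -> uM


def label_record(
    record: AssayRecord,
    spec: FilterSpec,
    mol_weight: float | None = None,
) -> str | None:
    """Label one measurement A / SA / I, or None when undecidable.

    Relation qualifiers only assert what the censored value proves:
    an upper bound at or below the active cutoff proves A; a lower
    bound above the slightly-active cutoff proves I; bounds that
    straddle a band boundary decide nothing and the record is dropped.
    """
    value = convert_value(record.value, record.units, record.assay_class, mol_weight)
    if value is None:
        return None
    a_max = spec.active_max(record.assay_class)
    s_max = spec.slight_max(record.assay_class)
    rel = record.relation
    if rel == "=":
        if value <= a_max:
            return "A"
        if value <= s_max:
            return "SA"
        return "I"
    if rel in ("<", "<="):
        return "A" if value <= a_max else None
    # rel in (">", ">=")
    if rel == ">" and value >= s_max:
        return "I"
    if rel == ">=" and value > s_max:
        return "I"
    return None


@dataclass
class ActivityMatrix:
    """Sparse compound × assay label map for one assay class."""

    assay_class: str
    entries: dict[tuple[str, str], str] = field(default_factory=dict)
    assay_organisms: dict[str, str] = field(default_factory=dict)

    def compound_vector(self, compound_id: str) -> list[str]:
        """Labels over the assays in which the compound was tested."""
        return [lab for (cid, _), lab in self.entries.items() if cid == compound_id]

    @property
    def compounds(self) -> set[str]:
        return {cid for cid, _ in self.entries}

    @property
    def assays(self) -> set[str]:
        return {aid for _, aid in self.entries}

    def by_compound(self) -> dict[str, dict[str, str]]:
        out: dict[str, dict[str, str]] = defaultdict(dict)
        for (cid, aid), lab in self.entries.items():
            out[cid][aid] = lab
        return dict(out)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["compound_id", "assay_id", "label"])
            for (cid, aid), lab in sorted(self.entries.items()):
                writer.writerow([cid, aid, lab])
        return path

    @classmethod
    def from_csv(cls, path: str | Path, assay_class: str) -> "ActivityMatrix":
        entries = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                entries[(row["compound_id"], row["assay_id"])] = row["label"]
        return cls(assay_class=assay_class, entries=entries)


@dataclass
class MatrixBuildCounters:
    n_records: int = 0
    n_unlabelled: int = 0        # undecidable relation / unknown units
    n_unknown_compound: int = 0


def _aggregate(labels: Sequence[str], rule: str) -> str:
    if rule == "best":
        return max(labels, key=_LABEL_RANK.__getitem__)
    if rule == "worst":
        return min(labels, key=_LABEL_RANK.__getitem__)
    if rule == "majority":
        counts = Counter(labels)
        top = max(counts.values())
        # ties resolved toward the better label
        return max((l for l, c in counts.items() if c == top), key=_LABEL_RANK.__getitem__)
    raise ValueError(f"unknown aggregation rule {rule!r}")


def build_matrix(
    records: Iterable[AssayRecord],
    spec: FilterSpec,
    mol_weights: Mapping[str, float],
    aggregation: str = "best",
) -> tuple[ActivityMatrix, MatrixBuildCounters]:
    """Build one labelled matrix from records of a single assay class.

    Duplicate (compound, assay) measurements are aggregated to a single
    label; by default the best label wins (A > SA > I), matching the
    existential flavour of the active definition. Records for compounds
    absent from ``mol_weights`` are counted and skipped.
    """
    records = list(records)
    classes = {r.assay_class for r in records}
    if len(classes) > 1:
        raise ValueError(f"records mix assay classes: {sorted(classes)}")
    assay_class = classes.pop() if classes else "antibacterial"

    counters = MatrixBuildCounters(n_records=len(records))
    pending: dict[tuple[str, str], list[str]] = defaultdict(list)
    organisms: dict[str, str] = {}
    for rec in records:
        if rec.compound_id not in mol_weights:
            counters.n_unknown_compound += 1
            continue
        label = label_record(rec, spec, mol_weights.get(rec.compound_id))
        if label is None:
            counters.n_unlabelled += 1
            continue
        pending[(rec.compound_id, rec.assay_id)].append(label)
        if rec.organism and rec.assay_id not in organisms:
            organisms[rec.assay_id] = rec.organism

    entries = {key: _aggregate(labs, aggregation) for key, labs in pending.items()}
    return ActivityMatrix(assay_class=assay_class, entries=entries,
                          assay_organisms=organisms), counters


def classify_compound(activity_vector: Sequence[str]) -> str:
    """Classify a compound from its tested labels.

    Returns ``"active"`` when at least one entry is A and none is I,
    ``"inactive"`` when there is at least one tested entry and all are
    I, otherwise ``"indeterminate"`` (includes the empty, untested
    vector).
    """
    labels = list(activity_vector)
    if not labels:
        return "indeterminate"
    has_a = any(l == "A" for l in labels)
    has_i = any(l == "I" for l in labels)
    if has_a and not has_i:
        return "active"
    if has_i and all(l == "I" for l in labels):
        return "inactive"
    return "indeterminate"


def build_sets(
    ab_matrix: ActivityMatrix,
    bio_matrix: ActivityMatrix,
    compounds: Iterable[CompoundRecord],
) -> dict[str, set[str]]:
    """Derive the eight analysis sets from the two matrices plus annotations.

    AA/AI and BA/BI apply the active/inactive definitions within the
    antibacterial and biochemical matrices respectively. BAAA is the
    intersection of the two active sets. BAAI relaxes "biochemically
    active but antibacterially inactive" to "biochemically active with
    no antibacterial record at all". MAD/MOD come from the marketed-drug
    annotations, independent of assay data.
    """
    ab_by_compound = ab_matrix.by_compound()
    bio_by_compound = bio_matrix.by_compound()

    aa = {c for c, labs in ab_by_compound.items() if classify_compound(list(labs.values())) == "active"}
    ai = {c for c, labs in ab_by_compound.items() if classify_compound(list(labs.values())) == "inactive"}
    ba = {c for c, labs in bio_by_compound.items() if classify_compound(list(labs.values())) == "active"}
    bi = {c for c, labs in bio_by_compound.items() if classify_compound(list(labs.values())) == "inactive"}
    baaa = aa & ba
    baai = {c for c in ba if c not in ab_by_compound}
    mad = {c.compound_id for c in compounds if c.drug_status == "marketed_antibacterial"}
    mod = {c.compound_id for c in compounds if c.drug_status == "marketed_other"}
    return {"AA": aa, "AI": ai, "BA": ba, "BI": bi,
            "BAAA": baaa, "BAAI": baai, "MAD": mad, "MOD": mod}


def check_set_invariants(sets: Mapping[str, set[str]]) -> None:
    """Assert the set-algebra invariants every build_sets output obeys."""
    assert not (sets["AA"] & sets["AI"]), "AA and AI must be disjoint"
    assert not (sets["BA"] & sets["BI"]), "BA and BI must be disjoint"
    assert sets["BAAA"] <= sets["AA"] and sets["BAAA"] <= sets["BA"], "BAAA must be in AA and BA"
    assert sets["BAAI"] <= sets["BA"], "BAAI must be biochemically active"
    assert not (sets["BAAI"] & sets["AA"]), "BAAI excludes antibacterial actives"
    assert not (sets["BAAA"] & sets["BAAI"]), "BAAA and BAAI are disjoint"
    assert not (sets["MAD"] & sets["MOD"]), "MAD and MOD must be disjoint"
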