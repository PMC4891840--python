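"""Readers and writers for ChEMBL-style flat exports.

The pipeline consumes three delimited/structure files rather than a live
database: a structure source (SDF or two-column SMILES+ID text), an
activity table (one row per assay measurement) and a drug-annotation
table (approval flag plus therapeutic class). Everything is validated
into the small set of domain records used downstream; rows that cannot
be used are counted, never silently dropped.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

# -- enums (plain strings, validated) ---------------------------------------

ASSAY_CLASSES = ("antibacterial", "biochemical")
UNITS = ("ug_per_ml", "uM", "unknown")
RELATIONS = ("=", "<", "<=", ">", ">=")
DRUG_STATUSES = ("not_drug", "marketed_antibacterial", "marketed_other")

#: case-insensitive unit aliases -> canonical unit
UNIT_ALIASES = {
    "ug/ml": "ug_per_ml",
    "ug/mL": "ug_per_ml",
    "µg/ml": "ug_per_ml",
    "μg/ml": "ug_per_ml",
    "ug.ml-1": "ug_per_ml",
    "ug ml-1": "ug_per_ml",
    "mg/l": "ug_per_ml",
    "mg l-1": "ug_per_ml",
    "ug_per_ml": "ug_per_ml",
    "um": "uM",
    "µm": "uM",
    "μm": "uM",
    "umol/l": "uM",
    "µmol/l": "uM",
    "micromolar": "uM",
}


def normalize_units(raw: str) -> str:
    """Map a free-text unit string onto the canonical unit enum."""
    return UNIT_ALIASES.get(raw.strip().lower(), "unknown")


@dataclass(frozen=True)
class AssayRecord:
    """One raw activity measurement tying a compound to an assay."""

    compound_id: str
    assay_id: str
    assay_class: str            # antibacterial | biochemical
    target_type: str
    organism: str               # may be empty
    activity_type: str          # e.g. MIC, IC50
    value: float
    units: str                  # ug_per_ml | uM | unknown
    relation: str               # = < <= > >=
    year: int | None = None

    def __post_init__(self) -> None:
        if self.assay_class not in ASSAY_CLASSES:
            raise ValueError(f"unknown assay_class {self.assay_class!r}")
        if self.units not in UNITS:
            raise ValueError(f"unknown units {self.units!r}")
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")
        if self.value < 0:
            raise ValueError("activity value must be non-negative")


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    structure: str                       # canonical SMILES (possibly multi-component)
    first_year: int | None = None
    drug_status: str = "not_drug"

    def __post_init__(self) -> None:
        if self.drug_status not in DRUG_STATUSES:
            raise ValueError(f"unknown drug_status {self.drug_status!r}")


@dataclass
class FilterSpec:
    """Activity cutoffs and accepted measurement types per assay class.

    Cutoffs are expressed in each assay class's native scale:
    micrograms-per-millilitre for growth-inhibition (MIC-style) assays
    and micromolar for biochemical potency. An active must sit at or
    below ``active_max``; the slightly-active band runs up to
    ``slight_max``; anything provably above that is inactive.
    """

    antibacterial_active_max: float = 8.0      # ug/ml
    antibacterial_slight_max: float = 32.0     # ug/ml
    biochemical_active_max: float = 10.0       # uM
    biochemical_slight_max: float = 100.0      # uM
    accepted_activity_types: dict[str, frozenset[str]] = field(
        default_factory=lambda: {
            "antibacterial": frozenset({"MIC", "MIC50", "MIC90"}),
            "biochemical": frozenset({"IC50", "Ki", "Kd", "EC50"}),
        }
    )

    def __post_init__(self) -> None:
        if not self.antibacterial_active_max < self.antibacterial_slight_max:
            raise ValueError("antibacterial active_max must be < slight_max")
        if not self.biochemical_active_max < self.biochemical_slight_max:
            raise ValueError("biochemical active_max must be < slight_max")

    def active_max(self, assay_class: str) -> float:
        return (self.antibacterial_active_max if assay_class == "antibacterial"
                else self.biochemical_active_max)

    def slight_max(self, assay_class: str) -> float:
        return (self.antibacterial_slight_max if assay_class == "antibacterial"
                else self.biochemical_slight_max)


@dataclass
class ActivityReadResult:
    records: list[AssayRecord]
    n_input_rows: int
    n_rejected: int                     # malformed rows (with line numbers logged)
    n_excluded_type: int                # activity_type outside the accepted list
    n_excluded_units: int               # unit string not recognized
    rejected_lines: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = len(self.records) + self.n_rejected + self.n_excluded_type + self.n_excluded_units
        assert total == self.n_input_rows, "row accounting must balance"


class DuplicateStructureError(ValueError):
    """Raised when one compound id maps to conflicting structures."""

    def __init__(self, ids: Sequence[str]):
        self.ids = list(ids)
        super().__init__(f"conflicting structures for compound ids: {', '.join(self.ids)}")


# -- structure reading -------------------------------------------------------

def _iter_smiles_file(path: Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            cid = parts[1].strip() if len(parts) > 1 else f"line{lineno}"
            yield cid, smiles


def _iter_sdf_file(path: Path):
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            yield f"sdf_record_{i}", None
            continue
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"sdf_record_{i}"
        yield cid, Chem.MolToSmiles(mol)


def read_compounds(
    structure_source: str | Path,
    annotation_source: str | Path | None = None,
) -> tuple[list[CompoundRecord], int]:
    """Read structures (SDF or SMILES+ID) plus optional drug annotations.

    Returns the parsed compound records and the count of skipped
    (unparsable) structures. Duplicated ids with identical canonical
    structures are merged; conflicting duplicates raise
    :class:`DuplicateStructureError`.
    """
    path = Path(structure_source)
    if not path.exists():
        raise FileNotFoundError(path)

    if path.suffix.lower() == ".sdf":
        entries = _iter_sdf_file(path)
    else:
        entries = _iter_smiles_file(path)

    by_id: dict[str, str] = {}
    order: list[str] = []
    conflicts: list[str] = []
    n_skipped = 0
    for cid, smiles in entries:
        mol = Chem.MolFromSmiles(smiles) if smiles is not None else None
        if mol is None:
            n_skipped += 1
            logger.warning("skipping unparsable structure for id %s", cid)
            continue
        canonical = Chem.MolToSmiles(mol)
        if cid in by_id:
            if by_id[cid] != canonical:
                conflicts.append(cid)
            continue
        by_id[cid] = canonical
        order.append(cid)
    if conflicts:
        raise DuplicateStructureError(sorted(set(conflicts)))
    if n_skipped:
        logger.info("read_compounds: skipped %d unparsable structures", n_skipped)

    annotations = read_annotations(annotation_source) if annotation_source else {}
    records = [
        CompoundRecord(
            compound_id=cid,
            structure=by_id[cid],
            first_year=annotations.get(cid, (None, "not_drug"))[0],
            drug_status=annotations.get(cid, (None, "not_drug"))[1],
        )
        for cid in order
    ]
    return records, n_skipped


def read_annotations(path: str | Path) -> dict[str, tuple[int | None, str]]:
    """Read the drug-annotation table: compound_id -> (first_year, drug_status).

    A compound is ``marketed_antibacterial`` when the approved flag is
    set and the therapeutic class is antibacterial, ``marketed_other``
    for any other approved compound.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: dict[str, tuple[int | None, str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, dialect=_sniff(fh))
        for row in reader:
            cid = row["compound_id"].strip()
            approved = str(row.get("approved", "")).strip().lower() in {"1", "true", "yes"}
            tclass = str(row.get("therapeutic_class", "")).strip().lower()
            year_raw = str(row.get("first_year", "")).strip()
            year = int(year_raw) if year_raw else None
            if not approved:
                status = "not_drug"
            elif tclass == "antibacterial":
                status = "marketed_antibacterial"
            else:
                status = "marketed_other"
            out[cid] = (year, status)
    return out


def _sniff(fh) -> type[csv.Dialect]:
    sample = fh.read(4096)
    fh.seek(0)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;")
    except csv.Error:
        return csv.excel


# -- activity reading --------------------------------------------------------

ACTIVITY_COLUMNS = (
    "compound_id", "assay_id", "assay_class", "target_type", "organism",
    "activity_type", "value", "units", "relation", "year",
)


def read_activities(
    activity_source: str | Path,
    spec: FilterSpec | None = None,
) -> ActivityReadResult:
    """Read the delimited activity table into validated assay records.

    Unit strings are normalized onto the unit enum; rows whose activity
    type is not accepted for their assay class, or whose unit string is
    unrecognized, are excluded and counted. Malformed rows (bad number,
    bad enum) are rejected with their line numbers.
    """
    spec = spec or FilterSpec()
    path = Path(activity_source)
    if not path.exists():
        raise FileNotFoundError(path)

    records: list[AssayRecord] = []
    n_rows = n_rejected = n_excluded_type = n_excluded_units = 0
    rejected_lines: list[int] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, dialect=_sniff(fh))
        missing = set(ACTIVITY_COLUMNS) - set(reader.fieldnames or []) - {"year"}
        if missing:
            raise ValueError(f"activity table missing columns: {sorted(missing)}")
        for lineno, row in enumerate(reader, 2):
            n_rows += 1
            try:
                assay_class = row["assay_class"].strip().lower()
                value = float(row["value"])
                relation = (row.get("relation") or "=").strip() or "="
                year_raw = (row.get("year") or "").strip()
                year = int(year_raw) if year_raw else None
                units = normalize_units(row["units"])
                activity_type = row["activity_type"].strip()
                if assay_class not in ASSAY_CLASSES or relation not in RELATIONS or value < 0:
                    raise ValueError("bad enum or negative value")
            except (ValueError, KeyError, TypeError):
                n_rejected += 1
                rejected_lines.append(lineno)
                logger.warning("rejecting malformed activity row at line %d", lineno)
                continue
            if activity_type not in spec.accepted_activity_types.get(assay_class, frozenset()):
                n_excluded_type += 1
                continue
            if units == "unknown":
                n_excluded_units += 1
                continue
            records.append(AssayRecord(
                compound_id=row["compound_id"].strip(),
                assay_id=row["assay_id"].strip(),
                assay_class=assay_class,
                target_type=(row.get("target_type") or "").strip(),
                organism=(row.get("organism") or "").strip(),
                activity_type=activity_type,
                value=value,
                units=units,
                relation=relation,
                year=year,
            ))
    return ActivityReadResult(
        records=records,
        n_input_rows=n_rows,
        n_rejected=n_rejected,
        n_excluded_type=n_excluded_type,
        n_excluded_units=n_excluded_units,
        rejected_lines=rejected_lines,
    )


def assign_first_years(
    compounds: Iterable[CompoundRecord],
    records: Iterable[AssayRecord],
) -> list[CompoundRecord]:
    """Fill missing ``first_year`` from the earliest assay-record year."""
    earliest: dict[str, int] = {}
    for rec in records:
        if rec.year is None:
            continue
        cur = earliest.get(rec.compound_id)
        if cur is None or rec.year < cur:
            earliest[rec.compound_id] = rec.year
    out = []
    for c in compounds:
        if c.first_year is None and c.compound_id in earliest:
            c = CompoundRecord(c.compound_id, c.structure, earliest[c.compound_id], c.drug_status)
        out.append(c)
    return out


# -- set writing -------------------------------------------------------------

def write_set(
    members: Mapping[str, str] | Sequence[tuple[str, str]],
    path_prefix: str | Path,
) -> tuple[Path, Path]:
    """Write a compound set as a SMILES file plus a membership CSV.

    ``members`` maps compound_id -> SMILES. The SMILES file round-trips
    through :func:`read_compounds` with identical membership and
    canonical structures. Returns (smiles_path, membership_path).
    """
    items = list(members.items()) if isinstance(members, Mapping) else list(members)
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    smi_path = prefix.with_suffix(".smi")
    csv_path = prefix.with_suffix(".csv")
    with open(smi_path, "w") as fh:
        for cid, smiles in items:
            fh.write(f"{smiles}\t{cid}\n")
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["compound_id", "smiles"])
        writer.writerows(items)
    return smi_path, csv_path
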