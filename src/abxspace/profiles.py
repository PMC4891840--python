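"""Stratified distribution statistics and set comparisons.

Produces the per-set summaries that drive the analysis: medians, means
and configured range percentages per property (the Rule-of-5-style
cuts: MW < 500 Da, logP in [0, 5], TPSA < 120 Å²), charge-class
counts, Gram-positive/Gram-negative stratification of antibacterial
actives, per-year temporal profiles and substructure-defined chemotype
subsets. The comparison is descriptive (medians and overlaid
histograms); no significance testing is attached.
"""

from __future__ import annotations

import csv
import math
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .activity import ActivityMatrix, classify_compound
from .standardize import CHARGE_CLASSES, StandardizedMolecule

#: default histogram bin widths per property
DEFAULT_BIN_WIDTHS = {
    "mw": 25.0, "logp": 0.5, "logd74": 0.5, "tpsa": 10.0,
    "hba": 1.0, "hbd": 1.0, "rot_bonds": 1.0, "rings": 1.0,
}


@dataclass(frozen=True)
class PropertyRange:
    """A named half-line or interval, e.g. MW < 500 Da."""

    name: str
    lo: float | None = None
    hi: float | None = None
    lo_strict: bool = False
    hi_strict: bool = False

    def contains(self, value: float) -> bool:
        if self.lo is not None and (value < self.lo or (self.lo_strict and value == self.lo)):
            return False
        if self.hi is not None and (value > self.hi or (self.hi_strict and value == self.hi)):
            return False
        return True


DEFAULT_RANGES: dict[str, tuple[PropertyRange, ...]] = {
    "mw": (PropertyRange("mw_lt_500", hi=500, hi_strict=True),),
    "logp": (PropertyRange("logp_0_to_5", lo=0, hi=5),),
    "tpsa": (PropertyRange("tpsa_lt_120", hi=120, hi_strict=True),),
}


@dataclass
class DistributionSummary:
    property_name: str
    n: int
    n_missing: int
    median: float
    mean: float
    sd: float
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    percent_in_range: dict[str, float] = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return self.n > 0


def summarize(
    values: Iterable[float],
    property_name: str = "value",
    ranges: Sequence[PropertyRange] = (),
    bin_width: float | None = None,
) -> DistributionSummary:
    """Summary statistics over valid (finite) values.

    Missing values (None/NaN) are excluded and counted; the median of
    an even-length sample is the midpoint of the two central values;
    range percentages are computed over valid values only. An empty
    input yields n=0 with NaN statistics.
    """
    raw = list(values)
    arr = np.array([v for v in raw if v is not None and not (isinstance(v, float) and math.isnan(v))],
                   dtype=float)
    n_missing = len(raw) - arr.size
    if arr.size == 0:
        return DistributionSummary(property_name, 0, n_missing, math.nan, math.nan, math.nan,
                                   np.array([]), np.array([]),
                                   {r.name: math.nan for r in ranges})
    width = bin_width or DEFAULT_BIN_WIDTHS.get(property_name, None)
    if width:
        lo = math.floor(arr.min() / width) * width
        hi = math.ceil(arr.max() / width) * width + width
        edges = np.arange(lo, hi + width / 2, width)
    else:
        edges = np.histogram_bin_edges(arr, bins="auto")
    counts, _ = np.histogram(arr, bins=edges)
    pct = {r.name: 100.0 * sum(r.contains(v) for v in arr) / arr.size for r in ranges}
    return DistributionSummary(
        property_name=property_name, n=int(arr.size), n_missing=n_missing,
        median=float(np.median(arr)), mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        hist_edges=edges, hist_counts=counts, percent_in_range=pct,
    )


def charge_class_counts(standardized: Iterable[StandardizedMolecule]) -> dict[str, int]:
    """Counts per charge class; the four counts sum to the set size."""
    counter = Counter(sm.charge_class for sm in standardized)
    return {cls: counter.get(cls, 0) for cls in CHARGE_CLASSES}


# -- Gram stratification -------------------------------------------------------

@dataclass
class GramAnnotation:
    """Total lookup from organism name to Gram class.

    Exact (case-insensitive) species names are matched first, then the
    genus (first word). Unknown names map to ``unclassified``.
    """

    table: dict[str, str] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "GramAnnotation":
        text = resources.files("abxspace.data").joinpath("gram_organisms.tsv").read_text()
        return cls.from_rows(csv.DictReader(text.splitlines(), delimiter="\t"))

    @classmethod
    def from_path(cls, path: str | Path) -> "GramAnnotation":
        with open(path, newline="") as fh:
            return cls.from_rows(csv.DictReader(fh, delimiter="\t"))

    @classmethod
    def from_rows(cls, rows: Iterable[Mapping[str, str]]) -> "GramAnnotation":
        table = {}
        for row in rows:
            table[row["organism"].strip().lower()] = row["gram_class"].strip()
        return cls(table=table)

    def classify(self, organism: str) -> str:
        name = (organism or "").strip().lower()
        if not name:
            return "unclassified"
        if name in self.table:
            return self.table[name]
        genus = name.split()[0]
        return self.table.get(genus, "unclassified")


def gram_split(
    ab_matrix: ActivityMatrix,
    annotation: GramAnnotation | None = None,
) -> tuple[set[str], set[str]]:
    """Antibacterial actives split by assay-organism Gram class.

    A compound joins a class when the active definition holds over its
    labels restricted to assays of that class's organisms; a compound
    active against both classes appears in both sets. Assays with an
    unclassified organism are ignored. Invariant to assay ordering.
    """
    annotation = annotation or GramAnnotation.default()
    assay_gram = {aid: annotation.classify(org) for aid, org in ab_matrix.assay_organisms.items()}
    split: dict[str, set[str]] = {"gram_positive": set(), "gram_negative": set()}
    for gram_class, members in split.items():
        by_compound: dict[str, list[str]] = {}
        for (cid, aid), lab in ab_matrix.entries.items():
            if assay_gram.get(aid) == gram_class:
                by_compound.setdefault(cid, []).append(lab)
        for cid, labels in by_compound.items():
            if classify_compound(labels) == "active":
                members.add(cid)
    return split["gram_positive"], split["gram_negative"]


# -- temporal profile ----------------------------------------------------------

def temporal_profile(
    members: Iterable[str],
    property_values: Mapping[str, float],
    first_year: Mapping[str, int | None],
    property_name: str = "mw",
    min_n: int = 10,
) -> tuple[dict[int, DistributionSummary], int]:
    """Per-year distribution summaries for one property over a set.

    Years with fewer than ``min_n`` valid compounds are omitted.
    Returns (year -> summary, count of members without a usable year).
    """
    by_year: dict[int, list[float]] = {}
    n_missing_year = 0
    for cid in members:
        year = first_year.get(cid)
        value = property_values.get(cid)
        if year is None or value is None:
            n_missing_year += 1
            continue
        by_year.setdefault(int(year), []).append(value)
    series = {
        year: summarize(vals, property_name)
        for year, vals in sorted(by_year.items())
        if len(vals) >= min_n
    }
    return series, n_missing_year


# -- chemotype subsets ---------------------------------------------------------

@dataclass(frozen=True)
class ChemotypeSpec:
    name: str
    smarts: str
    site_of_action: str          # cell_wall | cytoplasmic
    min_count: int = 40

    def __post_init__(self):
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")

    def pattern(self):
        patt = Chem.MolFromSmarts(self.smarts)
        if patt is None:
            raise ValueError(f"invalid SMARTS in chemotype spec {self.name!r}")
        return patt


def default_chemotypes() -> list[ChemotypeSpec]:
    text = resources.files("abxspace.data").joinpath("chemotypes.tsv").read_text()
    return [
        ChemotypeSpec(row["name"], row["smarts"], row["site_of_action"], int(row["min_count"]))
        for row in csv.DictReader(text.splitlines(), delimiter="\t")
    ]


@dataclass
class ChemotypeSubset:
    name: str
    site_of_action: str
    members: set[str]
    below_threshold: bool


def chemotype_subsets(
    members: Iterable[str],
    smiles: Mapping[str, str],
    specs: Sequence[ChemotypeSpec] | None = None,
) -> dict[str, ChemotypeSubset]:
    """Substructure-defined chemotype subsets of a compound set.

    Subsets smaller than their ``min_count`` are flagged below
    threshold and should be excluded from comparison output.
    """
    specs = list(specs) if specs is not None else default_chemotypes()
    patterns = [(spec, spec.pattern()) for spec in specs]
    mols = {cid: Chem.MolFromSmiles(smiles[cid]) for cid in members if cid in smiles}
    out = {}
    for spec, patt in patterns:
        hits = {cid for cid, mol in mols.items() if mol is not None and mol.HasSubstructMatch(patt)}
        out[spec.name] = ChemotypeSubset(
            name=spec.name, site_of_action=spec.site_of_action,
            members=hits, below_threshold=len(hits) < spec.min_count,
        )
    return out


# -- set comparison ------------------------------------------------------------

def compare_sets(
    property_tables: Mapping[str, pd.DataFrame],
    properties: Sequence[str] = ("mw", "logd74", "logp", "hba", "hbd", "rot_bonds", "rings", "tpsa"),
    ranges: Mapping[str, Sequence[PropertyRange]] | None = None,
    charge_counts: Mapping[str, Mapping[str, int]] | None = None,
) -> pd.DataFrame:
    """Side-by-side per-set summary table (median-table shape).

    ``property_tables`` maps set label -> per-compound property frame.
    One row per set: n, the median of each requested property, any
    configured range percentages, and (optionally) the four
    charge-class counts.
    """
    ranges = DEFAULT_RANGES if ranges is None else ranges
    rows = []
    for label, frame in property_tables.items():
        row: dict[str, object] = {"set": label, "n": len(frame)}
        for prop in properties:
            values = frame[prop].tolist() if prop in frame else []
            summary = summarize(values, prop, tuple(ranges.get(prop, ())))
            row[f"median_{prop}"] = summary.median
            row[f"mean_{prop}"] = summary.mean
            for rname, pct in summary.percent_in_range.items():
                row[f"pct_{rname}"] = pct
        if charge_counts and label in charge_counts:
            for cls in CHARGE_CLASSES:
                row[f"n_{cls}"] = charge_counts[label].get(cls, 0)
        rows.append(row)
    return pd.DataFrame(rows).set_index("set")


def plot_distributions(
    property_tables: Mapping[str, pd.DataFrame],
    properties: Sequence[str],
    path: str | Path,
    bin_widths: Mapping[str, float] | None = None,
) -> Path:
    """Overlaid per-property density histograms, one panel per property."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    widths = dict(DEFAULT_BIN_WIDTHS)
    widths.update(bin_widths or {})
    n_props = len(properties)
    ncols = min(2, n_props)
    nrows = math.ceil(n_props / ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(6 * ncols, 4 * nrows), squeeze=False)
    for k, prop in enumerate(properties):
        ax = axes[k // ncols][k % ncols]
        for label, frame in property_tables.items():
            vals = frame[prop].dropna() if prop in frame else pd.Series(dtype=float)
            if vals.empty:
                continue
            width = widths.get(prop, None)
            if width:
                lo = math.floor(vals.min() / width) * width
                bins = np.arange(lo, vals.max() + 2 * width, width)
            else:
                bins = "auto"
            ax.hist(vals, bins=bins, density=True, histtype="step", label=f"{label} (n={len(vals)})")
        ax.set_xlabel(prop)
        ax.set_ylabel("density")
        ax.legend(fontsize=8)
    for k in range(n_props, nrows * ncols):
        axes[k // ncols][k % ncols].axis("off")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
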