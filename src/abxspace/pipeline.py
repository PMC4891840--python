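"""End-to-end pipeline orchestration.

Stages: read the three exports, standardize every structure, label the
two activity matrices, derive the eight analysis sets, diversity-reduce
each set by sphere exclusion, compute the nine-property vectors and
fingerprints, then emit the report bundle: a set-size table, a
median/charge-class comparison table, pairwise-similarity
distributions, Gram-positive/negative and temporal profiles,
chemotype subsets, distribution plots, and a run log with every
exclusion counter. Deterministic given the config (one root seed
drives the only stochastic stage, the subset selection).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import activity, chembl_io, descriptors, diversity, profiles
from .chembl_io import FilterSpec
from .standardize import StandardizationError, standardize

logger = logging.getLogger(__name__)

PROFILED_PROPERTIES = ("mw", "logd74", "logp", "hba", "hbd", "rot_bonds", "rings", "tpsa")
PLOTTED_PROPERTIES = ("mw", "logd74", "tpsa", "rot_bonds")


@dataclass
class PipelineConfig:
    compounds_path: str
    activities_path: str
    annotations_path: str | None = None
    output_dir: str = "abxspace_out"
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    salt_list_path: str | None = None
    ionization_rules_path: str | None = None
    gram_lookup_path: str | None = None
    chemotype_spec_path: str | None = None
    diversity_threshold: float = 0.65
    seed: int = 0
    apply_diversity_reduction: bool = True
    temporal_min_n: int = 10
    make_plots: bool = True

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        payload = dataclasses.asdict(self)
        payload["filter_spec"]["accepted_activity_types"] = {
            k: sorted(v) for k, v in self.filter_spec.accepted_activity_types.items()
        }
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        fs = payload.pop("filter_spec", None)
        config = cls(**payload)
        if fs:
            fs["accepted_activity_types"] = {
                k: frozenset(v) for k, v in fs.get("accepted_activity_types", {}).items()
            }
            config.filter_spec = FilterSpec(**fs)
        return config


@dataclass
class ReportBundle:
    """All artifacts of one pipeline run."""

    sets: dict[str, set[str]]                      # full memberships
    reduced_sets: dict[str, set[str]]              # after sphere exclusion
    standardized: dict[str, object]                # compound_id -> StandardizedMolecule
    property_table: pd.DataFrame                   # all compounds
    set_sizes: pd.DataFrame
    comparison: pd.DataFrame
    similarity: dict[str, diversity.SimilarityDistribution]
    gram_sets: dict[str, set[str]]
    gram_comparison: pd.DataFrame
    temporal: dict[int, profiles.DistributionSummary]
    chemotypes: dict[str, profiles.ChemotypeSubset]
    counters: dict
    output_dir: Path


class StageError(RuntimeError):
    def __init__(self, stage: str, counters: dict, cause: Exception):
        self.stage = stage
        self.counters = counters
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    counters: dict = {}
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    # -- read ----------------------------------------------------------------
    try:
        compounds, n_skipped = chembl_io.read_compounds(
            config.compounds_path, config.annotations_path)
        activity_result = chembl_io.read_activities(config.activities_path, config.filter_spec)
        counters["structures_skipped"] = n_skipped
        counters["activity_rows"] = activity_result.n_input_rows
        counters["activity_rejected"] = activity_result.n_rejected
        counters["activity_excluded_type"] = activity_result.n_excluded_type
        counters["activity_excluded_units"] = activity_result.n_excluded_units
    except Exception as exc:
        raise StageError("read", counters, exc)

    compounds = chembl_io.assign_first_years(compounds, activity_result.records)
    first_year = {c.compound_id: c.first_year for c in compounds}

    # -- standardize ---------------------------------------------------------
    salt_list = None
    rules = None
    try:
        if config.salt_list_path:
            from .standardize import load_salts
            salt_list = load_salts(config.salt_list_path)
        if config.ionization_rules_path:
            from .standardize import load_rules
            rules = load_rules(config.ionization_rules_path)
        standardized = {}
        n_failed = 0
        for comp in compounds:
            try:
                standardized[comp.compound_id] = standardize(
                    comp.structure, comp.compound_id, salt_list, rules)
            except StandardizationError:
                n_failed += 1
                logger.warning("standardization failed for %s", comp.compound_id)
        counters["standardization_failed"] = n_failed
    except Exception as exc:
        raise StageError("standardize", counters, exc)

    # -- label + matrices ----------------------------------------------------
    try:
        from rdkit.Chem import Descriptors as _D
        mol_weights = {cid: _D.MolWt(sm.mol()) for cid, sm in standardized.items()}
        ab_records = [r for r in activity_result.records if r.assay_class == "antibacterial"]
        bio_records = [r for r in activity_result.records if r.assay_class == "biochemical"]
        ab_matrix, ab_counters = activity.build_matrix(ab_records, config.filter_spec, mol_weights)
        ab_matrix.assay_class = "antibacterial"
        bio_matrix, bio_counters = activity.build_matrix(bio_records, config.filter_spec, mol_weights)
        bio_matrix.assay_class = "biochemical"
        counters["ab_unlabelled"] = ab_counters.n_unlabelled
        counters["ab_unknown_compound"] = ab_counters.n_unknown_compound
        counters["bio_unlabelled"] = bio_counters.n_unlabelled
        counters["bio_unknown_compound"] = bio_counters.n_unknown_compound
    except Exception as exc:
        raise StageError("label", counters, exc)

    # -- sets ----------------------------------------------------------------
    try:
        sets = activity.build_sets(ab_matrix, bio_matrix, compounds)
        activity.check_set_invariants(sets)
    except Exception as exc:
        raise StageError("sets", counters, exc)

    # -- diversity reduction + similarity ------------------------------------
    try:
        fingerprints = {cid: descriptors.compute_fingerprint(sm)
                        for cid, sm in standardized.items()}
        reduced_sets: dict[str, set[str]] = {}
        similarity: dict[str, diversity.SimilarityDistribution] = {}
        for label, members in sets.items():
            ids = sorted(m for m in members if m in fingerprints)
            fps = [fingerprints[cid] for cid in ids]
            if len(fps) >= 2:
                similarity[label] = diversity.pairwise_distribution(fps)
            if config.apply_diversity_reduction and fps:
                kept = diversity.diverse_subset(fps, config.diversity_threshold, config.seed)
                reduced_sets[label] = {ids[i] for i in kept}
            else:
                reduced_sets[label] = set(ids)
    except Exception as exc:
        raise StageError("diversity", counters, exc)

    # -- properties ----------------------------------------------------------
    try:
        vectors = [descriptors.compute_properties(sm) for sm in standardized.values()]
        property_table = descriptors.properties_table(vectors)
    except Exception as exc:
        raise StageError("properties", counters, exc)

    # -- profiles ------------------------------------------------------------
    try:
        per_set_tables = {
            label: property_table.loc[sorted(members & set(property_table.index))]
            for label, members in reduced_sets.items()
        }
        charge_counts = {
            label: profiles.charge_class_counts(
                standardized[cid] for cid in members if cid in standardized)
            for label, members in reduced_sets.items()
        }
        comparison = profiles.compare_sets(per_set_tables, PROFILED_PROPERTIES,
                                           charge_counts=charge_counts)
        set_sizes = pd.DataFrame({
            "set": list(sets),
            "n_full": [len(sets[l]) for l in sets],
            "n_reduced": [len(reduced_sets[l]) for l in sets],
        }).set_index("set")

        gram_annotation = (profiles.GramAnnotation.from_path(config.gram_lookup_path)
                           if config.gram_lookup_path else profiles.GramAnnotation.default())
        gram_pos, gram_neg = profiles.gram_split(ab_matrix, gram_annotation)
        gram_sets = {"gram_positive": gram_pos, "gram_negative": gram_neg}
        gram_tables = {
            label: property_table.loc[sorted(members & set(property_table.index))]
            for label, members in gram_sets.items()
        }
        gram_comparison = profiles.compare_sets(gram_tables, PROFILED_PROPERTIES)

        aa_members = sets.get("AA", set())
        temporal, n_no_year = profiles.temporal_profile(
            aa_members, property_table["mw"].to_dict(), first_year,
            "mw", config.temporal_min_n)
        counters["temporal_missing_year"] = n_no_year

        chemotype_specs = None
        if config.chemotype_spec_path:
            import csv as _csv
            with open(config.chemotype_spec_path, newline="") as fh:
                chemotype_specs = [
                    profiles.ChemotypeSpec(r["name"], r["smarts"], r["site_of_action"],
                                           int(r.get("min_count", 40)))
                    for r in _csv.DictReader(fh, delimiter="\t")
                ]
        smiles_map = {cid: sm.smiles for cid, sm in standardized.items()}
        chemotypes = profiles.chemotype_subsets(sets["AA"], smiles_map, chemotype_specs)
    except Exception as exc:
        raise StageError("profiles", counters, exc)

    # -- write bundle --------------------------------------------------------
    try:
        set_sizes.to_csv(outdir / "set_sizes.csv")
        comparison.to_csv(outdir / "set_comparison.csv")
        gram_comparison.to_csv(outdir / "gram_comparison.csv")
        for label, dist in similarity.items():
            dist.to_frame().to_csv(outdir / f"similarity_{label}.csv", index=False)
        for label, members in reduced_sets.items():
            chembl_io.write_set(
                {cid: standardized[cid].smiles for cid in sorted(members) if cid in standardized},
                outdir / f"set_{label}")
        temporal_frame = pd.DataFrame([
            {"year": year, "n": s.n, "median_mw": s.median, "mean_mw": s.mean}
            for year, s in temporal.items()
        ])
        temporal_frame.to_csv(outdir / "temporal_mw.csv", index=False)
        chemotype_frame = pd.DataFrame([
            {"chemotype": ct.name, "site_of_action": ct.site_of_action,
             "n": len(ct.members), "below_threshold": ct.below_threshold}
            for ct in chemotypes.values()
        ])
        chemotype_frame.to_csv(outdir / "chemotypes.csv", index=False)
        ab_matrix.to_csv(outdir / "matrix_antibacterial.csv")
        bio_matrix.to_csv(outdir / "matrix_biochemical.csv")
        config.to_yaml(outdir / "run_config.yaml")
        (outdir / "run_counters.json").write_text(json.dumps(counters, indent=2, sort_keys=True))
        if config.make_plots:
            profiles.plot_distributions(
                {k: v for k, v in per_set_tables.items() if len(v)},
                PLOTTED_PROPERTIES, outdir / "set_distributions.png")
            if any(len(v) for v in gram_tables.values()):
                profiles.plot_distributions(
                    {k: v for k, v in gram_tables.items() if len(v)},
                    PLOTTED_PROPERTIES, outdir / "gram_distributions.png")
    except Exception as exc:
        raise StageError("write", counters, exc)

    return ReportBundle(
        sets=sets, reduced_sets=reduced_sets, standardized=standardized,
        property_table=property_table, set_sizes=set_sizes, comparison=comparison,
        similarity=similarity, gram_sets=gram_sets, gram_comparison=gram_comparison,
        temporal=temporal, chemotypes=chemotypes, counters=counters, output_dir=outdir,
    )
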