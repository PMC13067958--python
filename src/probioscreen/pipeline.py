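"""Pipeline orchestration and cohort-level descriptive comparisons.

Stages run in dependency order (qc, screen, confirm, safety, bacteriocin,
cazyme, pangenome, summaries); any stage can be skipped.  All tables are
UTF-8 TSV with one header row, written under a single output directory next
to a run manifest (seed, parameters, package versions, input checksums)
sufficient to reproduce the bundle bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from . import __version__
from . import assembly_qc, bacteriocin_profile, cazyme_aggregate, marker_screen
from . import pangenome as pangenome_mod
from . import safety_screen, sequence_confirmation, synthetic_genomes
from .genome_io import GenomeRecord, load_cohort

log = logging.getLogger(__name__)

STAGES = ("qc", "screen", "confirm", "safety", "bacteriocin", "cazyme", "pangenome", "summaries")

#: single-locus markers confirmed by alignment in the screening protocol
VALIDATION_MARKERS = ("bsh", "gadB", "atpA", "dnaK", "srtA", "clpP", "dltA")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    output_dir: str
    input_dir: str | None = None
    simulate: dict | None = None  # CohortConfig field overrides
    seed: int = 0
    skip: set[str] = field(default_factory=set)
    n_permutations: int = 100
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.simulate is None):
            raise PipelineConfigError("exactly one of input_dir / simulate must be given")
        unknown = set(self.skip) - set(STAGES)
        if unknown:
            raise PipelineConfigError(f"unknown stages in skip: {sorted(unknown)}")

    @classmethod
    def from_mapping(cls, data: dict) -> "PipelineConfig":
        known = {"output_dir", "input_dir", "simulate", "seed", "skip", "n_permutations", "log_level"}
        unknown = set(data) - known
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        if "output_dir" not in data:
            raise PipelineConfigError("config needs output_dir")
        data = dict(data)
        data["skip"] = set(data.get("skip", ()))
        return cls(**data)


def derive_stage_seeds(seed: int) -> dict[str, int]:
    """One top-level seed deterministically derives per-stage seeds."""
    state = np.random.SeedSequence(seed).generate_state(len(STAGES)) % (2**31)
    return dict(zip(STAGES, (int(s) for s in state)))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(frame: pd.DataFrame, path: Path, **kwargs) -> None:
    frame.to_csv(path, sep="\t", index=kwargs.pop("index", False), **kwargs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all unskipped stages; returns the run manifest mapping."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    tables = outdir / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    seeds = derive_stage_seeds(config.seed)
    ran: list[str] = []

    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", seeds["qc"])
        if "pangenome_plan" in sim_kwargs and isinstance(sim_kwargs["pangenome_plan"], dict):
            sim_kwargs["pangenome_plan"] = synthetic_genomes.PangenomePlan(**sim_kwargs["pangenome_plan"])
        cohort_config = synthetic_genomes.CohortConfig(**sim_kwargs)
        cohort = synthetic_genomes.simulate_cohort(cohort_config)
        synthetic_genomes.write_cohort(cohort, outdir / "cohort")
        records, metadata = cohort.records, cohort.metadata
        hit_tables = {
            "bacteriocin": cohort.bacteriocin_hits,
            "safety": cohort.safety_hits,
            "cazyme": cohort.cazyme_hits,
        }
        input_checksums = {}
    else:
        indir = Path(config.input_dir)
        records, metadata = load_cohort(indir)
        hit_tables = {}
        for name in ("bacteriocin", "safety", "cazyme"):
            path = indir / "hits" / f"{name}_hits.tsv"
            hit_tables[name] = pd.read_csv(path, sep="\t") if path.exists() else pd.DataFrame()
        input_checksums = {
            str(p.relative_to(indir)): _sha256(p) for p in sorted(indir.rglob("*")) if p.is_file()
        }

    by_id = {r.genome_id: r for r in records}

    # ---- qc
    retained_ids = sorted(by_id)
    if "qc" not in config.skip:
        try:
            meta_rows = metadata.set_index("genome_id")
            metrics, decisions = [], []
            for gid in sorted(by_id):
                log.info("qc: %s", gid)
                m = assembly_qc.compute_metrics(
                    by_id[gid],
                    assembly_level=str(meta_rows.loc[gid].get("assembly_level", "contig")),
                    excluded_origin=bool(meta_rows.loc[gid].get("excluded_origin", False)),
                )
                metrics.append(m)
                decisions.append(assembly_qc.apply_gate(m))
            _write(assembly_qc.qc_report(metrics, decisions), tables / "qc_report.tsv")
            retained_species = assembly_qc.filter_species_representation(decisions, metadata)
            passing = {d.genome_id for d in decisions if d.passed}
            retained_ids = sorted(
                gid for gid in passing
                if meta_rows.loc[gid, "species"] in retained_species
            )
            ran.append("qc")
        except assembly_qc.EmptyCohortError as exc:
            raise StageError("qc", str(exc)) from exc

    retained = [by_id[g] for g in retained_ids]
    metadata_retained = metadata[metadata["genome_id"].isin(retained_ids)]

    # ---- marker screen
    panel = marker_screen.load_panel()
    hits: list[marker_screen.MarkerHit] = []
    if "screen" not in config.skip:
        hits = marker_screen.screen_cohort(retained, panel)
        _write(marker_screen.hits_frame(hits), tables / "marker_hits.tsv")
        for level in ("marker", "subcategory", "category"):
            for mode in ("count", "proportion"):
                matrix = marker_screen.build_matrix(
                    hits, panel, metadata_retained, grouping="species", level=level, mode=mode
                )
                _write(matrix.values, tables / f"marker_{level}_{mode}.tsv", index=True)
        ran.append("screen")

    # ---- confirmation
    if "confirm" not in config.skip and "screen" not in config.skip:
        ref_db = synthetic_genomes.reference_db(list(VALIDATION_MARKERS))
        ref_fasta = Path(config.input_dir or "") / "reference_proteins.faa" if config.input_dir else None
        if ref_fasta and ref_fasta.exists():
            ref_db = sequence_confirmation.load_reference_panel(ref_fasta)
        candidates = [h for h in hits if h.marker_id in ref_db]
        outcomes = sequence_confirmation.confirm_hits(candidates, retained, ref_db)
        _write(sequence_confirmation.outcomes_frame(outcomes), tables / "confirmation.tsv")
        _write(sequence_confirmation.concordance(outcomes), tables / "concordance.tsv")
        ran.append("confirm")

    # ---- safety
    if "safety" not in config.skip:
        frames = []
        raw = hit_tables.get("safety", pd.DataFrame())
        for panel_id in ("AMR", "VF"):
            sub = raw[raw["panel_id"] == panel_id] if "panel_id" in raw.columns else pd.DataFrame()
            if len(sub):
                frames.append(
                    safety_screen.filter_alignment_hits(sub, safety_screen.DEFAULT_PANELS[panel_id])
                )
        for record in retained:
            frames.append(safety_screen.screen_terms(record, safety_screen.BA_PANEL))
            frames.append(safety_screen.screen_terms(record, safety_screen.HEMOLYSIN_PANEL))
        all_hits = (
            pd.concat([f for f in frames if len(f)], ignore_index=True)
            if any(len(f) for f in frames)
            else pd.DataFrame(columns=safety_screen.HIT_COLUMNS)
        )
        _write(all_hits, tables / "safety_hits.tsv")
        _write(safety_screen.safety_profile(all_hits, metadata_retained), tables / "safety_prevalence.tsv")
        ran.append("safety")

    # ---- bacteriocin
    if "bacteriocin" not in config.skip:
        raw = hit_tables.get("bacteriocin", pd.DataFrame())
        raw = raw[raw["genome_id"].isin(retained_ids)] if "genome_id" in raw.columns else raw
        loci = bacteriocin_profile.consolidate(raw) if len(raw) else []
        loci = bacteriocin_profile.assign_subclasses(loci, bacteriocin_profile.load_subclass_table())
        _write(bacteriocin_profile.loci_frame(loci), tables / "bacteriocin_loci.tsv")
        _write(bacteriocin_profile.species_summary(loci, metadata_retained), tables / "bacteriocin_summary.tsv")
        _write(bacteriocin_profile.subclass_composition(loci, metadata_retained), tables / "bacteriocin_composition.tsv")
        ran.append("bacteriocin")

    # ---- cazyme
    if "cazyme" not in config.skip:
        raw = hit_tables.get("cazyme", pd.DataFrame())
        raw = raw[raw["genome_id"].isin(retained_ids)] if "genome_id" in raw.columns else raw
        assignments = cazyme_aggregate.filter_and_assign(raw) if len(raw) else []
        _write(cazyme_aggregate.assignments_frame(assignments), tables / "cazyme_assignments.tsv")
        _write(cazyme_aggregate.class_counts(assignments, metadata_retained), tables / "cazyme_class_counts.tsv")
        _write(cazyme_aggregate.family_prevalence(assignments, metadata_retained), tables / "cazyme_prevalence.tsv")
        ran.append("cazyme")

    # ---- pangenome
    if "pangenome" not in config.skip:
        proteins = [
            (r.genome_id, f.locus_tag, f.translation)
            for r in retained
            for f in r.features
        ]
        families = pangenome_mod.cluster_families(proteins)
        census = pangenome_mod.partition(families, n_genomes=len(retained))
        _write(pd.DataFrame([census]), tables / "pangenome_census.tsv")
        curve = pangenome_mod.accumulation_curve(
            families, n_permutations=config.n_permutations, seed=seeds["pangenome"],
            genomes=retained_ids,
        )
        _write(curve, tables / "accumulation_curve.tsv")
        pangenome_mod.presence_absence_frame(families, retained_ids).to_csv(
            tables / "gene_presence_absence.csv"
        )
        _write(
            pangenome_mod.unique_genes(families, retained_ids).reset_index(name="unique_families"),
            tables / "unique_genes.tsv",
        )
        ran.append("pangenome")

    # ---- summaries
    if "summaries" not in config.skip:
        qc_path = tables / "qc_report.tsv"
        if qc_path.exists():
            qc = pd.read_csv(qc_path, sep="\t")
            characteristics = qc.merge(
                metadata[["genome_id", "species", "source_category"]], on="genome_id"
            )
            _write(characteristics, tables / "genome_characteristics.tsv")
            try:
                test = compare_sizes_by_source(characteristics[characteristics["passed"]])
                _write(test.as_frame(), tables / "size_by_source.tsv")
            except ValueError as exc:
                log.warning("size-by-source comparison skipped: %s", exc)
        ran.append("summaries")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages_run": ran,
        "stages_skipped": sorted(config.skip),
        "parameters": {
            "input_dir": config.input_dir,
            "simulate": config.simulate,
            "n_permutations": config.n_permutations,
        },
        "input_checksums": input_checksums,
        "n_genomes_input": len(records),
        "n_genomes_retained": len(retained_ids),
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


@dataclass
class SizeBySource:
    h_statistic: float
    p_value: float
    medians: dict[str, float]
    n_per_category: dict[str, int]

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source_category": cat,
                "n": self.n_per_category[cat],
                "median_total_length": self.medians[cat],
                "kruskal_h": self.h_statistic,
                "p_value": self.p_value,
            }
            for cat in sorted(self.medians)
        ]
        return pd.DataFrame(rows)


def compare_sizes_by_source(
    characteristics: pd.DataFrame, include_missing: bool = False
) -> SizeBySource:
    """Kruskal–Wallis comparison of genome size across isolation-source
    categories (tie-corrected H, chi-square approximation with k-1 df).
    The 'missing' category is excluded unless requested."""
    frame = characteristics
    if not include_missing:
        frame = frame[frame["source_category"] != "missing"]
    groups = {
        cat: sub["total_length"].to_numpy()
        for cat, sub in frame.groupby("source_category")
        if len(sub)
    }
    if len(groups) < 2:
        raise ValueError("NOT_COMPARABLE: need >= 2 non-empty source categories")
    values = [groups[c] for c in sorted(groups)]
    if all(np.array_equal(v, values[0]) for v in values[1:]):
        h, p = 0.0, 1.0  # identical groups: H is exactly 0
    else:
        h, p = scipy.stats.kruskal(*values)
    return SizeBySource(
        h_statistic=float(h),
        p_value=float(p),
        medians={c: float(np.median(g)) for c, g in groups.items()},
        n_per_category={c: int(len(g)) for c, g in groups.items()},
    )
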