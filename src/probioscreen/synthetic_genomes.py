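"""Synthetic annotated cohorts with planted, labelled ground truth.

Every downstream stage of the pipeline is exercised against toy genomes
generated here: multiple species with uneven genome counts, genome sizes and
GC content spanning configurable ranges (scaled down from the 1.2-4.0 Mb /
32-53% GC spread of real lactobacilli assemblies), six isolation-source
categories, and planted features recorded in a ground-truth manifest:

* probiotic marker genes in three modes — ``exact`` reference copies,
  ``diverged:<pct>`` substitution-mutated copies at a controlled identity,
  and ``decoy`` marker-like product strings attached to unrelated sequences;
* bacteriocin structural loci with known names and subclasses, plus
  BAGEL4-style raw hit tables containing redundant overlapping hits and
  non-structural rows for the consolidation stage;
* safety genes with controlled identity/coverage (AMR/VF) or annotated
  gene symbols (BA decarboxylases, hemolysins), plus screening-style
  tabular hits;
* gene-family structure (core/accessory/unique) producing an open
  pan-genome, plus DIAMOND-style CAZy hit tables with known best hits.

Background sequence is i.i.d. nucleotides at the configured GC with
intergenic spacers of at least 50 bp; divergence is introduced by
substitutions only, so identity and coverage are controlled independently.
All randomness flows from a single seed; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from .genome_io import CdsFeature, GenomeRecord, SOURCE_CATEGORIES, write_genome, write_metadata

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: gene symbol + product string per marker, matching exactly one panel regex each
MARKER_LEXICON: dict[str, tuple[str | None, str]] = {
    "bsh": ("bsh", "Choloylglycine hydrolase"),
    "gadA": ("gadA", "Glutamate decarboxylase alpha"),
    "gadB": ("gadB", "Glutamate decarboxylase beta"),
    "gadC": ("gadC", "Glutamate/gamma-aminobutyrate antiporter"),
    "srtA": ("srtA", "Sortase SrtA"),
    "spa_pili": ("spaA", "Pilin protein SpaA"),
    "eps": ("epsD", "Exopolysaccharide biosynthesis protein EpsD"),
    "wzx_wzy": ("wzx", "Polysaccharide flippase Wzx"),
    "wzb_wzc": ("wzb", "Protein-tyrosine phosphatase Wzb"),
    "gtf": ("gtfB", "Glucosyltransferase GtfB"),
    "rfb": ("rfbB", "dTDP-glucose 4,6-dehydratase"),
    "ugd": ("ugd", "UDP-glucose 6-dehydrogenase"),
    "gnd": ("gnd", "6-phosphogluconate dehydrogenase"),
    "groEL": ("groEL", "Chaperonin GroEL"),
    "dnaK": ("dnaK", "Chaperone protein DnaK"),
    "clpC": ("clpC", "ATP-dependent Clp protease ATP-binding subunit ClpC"),
    "clpP": ("clpP", "ATP-dependent Clp protease proteolytic subunit"),
    "csp": ("cspA", "Cold shock protein CspA"),
    "sodA": ("sodA", "Superoxide dismutase"),
    "kat": ("katA", "Catalase"),
    "ahpC": ("ahpC", "Alkyl hydroperoxide reductase subunit C"),
    "fol": ("folA", "Dihydrofolate reductase"),
    "rib": ("ribD", "Riboflavin biosynthesis protein RibD"),
    "thi": ("thiE", "Thiamine-phosphate synthase"),
    "atpA": ("atpA", "ATP synthase subunit alpha"),
    "atp_operon": ("atpD", "ATP synthase subunit beta"),
    "arc": ("arcA", "Arginine deiminase"),
    "mub": ("mub", "Mucus-binding protein"),
    "cna": ("cna", "Collagen-binding adhesin"),
    "fbpA": ("fbpA", "Fibronectin-binding protein A"),
    "slp": ("slpA", "S-layer protein"),
    "bacteriocin_general": (None, "Bacteriocin biosynthesis protein"),
    "pln": ("plnE", "Plantaricin E biosynthesis protein"),
    "pdu": ("pduC", "Propanediol dehydratase large subunit"),
    "cob_cbi": ("cobD", "Cobalamin biosynthesis protein CobD"),
    "pts": ("ptsG", "PTS system glucose-specific transporter subunit IIA"),
    "lac": ("lacZ", "Beta-galactosidase"),
    "gal": ("galK", "Galactokinase"),
    "man": ("manA", "Mannose-6-phosphate isomerase"),
    "rbs": ("rbsA", "Ribose import ATP-binding protein RbsA"),
    "cas": ("cas9", "CRISPR-associated endonuclease Cas9"),
    "dltA": ("dltA", "D-alanine--poly(phosphoribitol) ligase subunit 1"),
}

#: (panel, gene) -> (gene symbol, product) for planted safety genes
SAFETY_LEXICON: dict[tuple[str, str], tuple[str, str]] = {
    ("AMR", "tet(M)"): ("tet(M)", "Tetracycline resistance ribosomal protection protein Tet(M)"),
    ("AMR", "erm(B)"): ("erm(B)", "rRNA adenine N-6-methyltransferase Erm(B)"),
    ("AMR", "msr(D)"): ("msr(D)", "ABC-F type ribosomal protection protein Msr(D)"),
    ("AMR", "aadD"): ("aadD", "Aminoglycoside nucleotidyltransferase AadD"),
    ("VF", "gelE"): ("gelE", "Gelatinase GelE"),
    ("VF", "esp"): ("esp", "Enterococcal surface protein Esp"),
    ("BA", "hdcA"): ("hdcA", "Histidine decarboxylase"),
    ("BA", "tyrDC"): ("tyrDC", "Tyrosine decarboxylase"),
    ("HEMOLYSIN", "hlyA"): ("hlyA", "Hemolysin A"),
    ("HEMOLYSIN", "cylB"): ("cylB", "Cytolysin transporter CylB"),
}


class ConfigError(ValueError):
    """Infeasible or invalid cohort configuration."""


@dataclass
class PangenomePlan:
    n_core_families: int = 90
    accessory_rate: float = 0.35
    unique_gene_rate: int = 5
    n_accessory_pool: int = 40


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort; ``seed`` fixes all randomness."""

    n_species: int = 3
    genomes_per_species: tuple[int, ...] = (12, 12, 12)
    genome_length_range: tuple[int, int] = (60_000, 90_000)
    gc_range: tuple[float, float] = (0.32, 0.53)
    source_mix: dict[str, float] = field(
        default_factory=lambda: {
            "fermentation": 0.18,
            "environment": 0.10,
            "human": 0.22,
            "animal": 0.14,
            "other": 0.10,
            "missing": 0.26,
        }
    )
    marker_plan: list[tuple[str, str, float]] = field(
        default_factory=lambda: [
            ("bsh", "exact", 0.85),
            ("gadB", "exact", 0.75),
            ("atpA", "exact", 1.0),
            ("dnaK", "exact", 0.9),
            ("srtA", "exact", 0.6),
            ("clpP", "exact", 0.8),
            ("dltA", "exact", 0.5),
            ("groEL", "exact", 1.0),
            ("pts", "exact", 0.9),
            ("lac", "exact", 0.7),
            ("eps", "exact", 0.5),
            ("fol", "exact", 0.6),
            ("rib", "exact", 0.5),
            ("arc", "exact", 0.5),
            ("sodA", "exact", 0.6),
            ("cas", "exact", 0.3),
            ("mub", "exact", 0.3),
            ("dnaK", "diverged:60", 0.25),
            ("bsh", "decoy", 0.15),
            ("srtA", "decoy", 0.10),
        ]
    )
    bacteriocin_plan: list[tuple[str, str, float]] = field(
        default_factory=lambda: [
            ("Plantaricin E", "IIb", 0.45),
            ("Plantaricin F", "IIb", 0.45),
            ("Enterolysin A", "III", 0.60),
            ("Helveticin J", "III", 0.35),
            ("Pediocin", "IIa", 0.30),
            ("Sakacin P", "IIa", 0.20),
            ("Nisin A", "I", 0.10),
            ("Garvicin KS", "other", 0.10),
        ]
    )
    safety_plan: list[tuple[str, str, float, float, float]] = field(
        default_factory=lambda: [
            # (panel, gene, identity %, coverage fraction, per-genome probability)
            ("AMR", "tet(M)", 95.0, 0.80, 0.30),
            ("AMR", "erm(B)", 92.0, 0.55, 0.20),
            ("AMR", "aadD", 85.0, 0.90, 0.15),   # below identity threshold
            ("AMR", "msr(D)", 96.0, 0.45, 0.15), # below coverage threshold
            ("VF", "gelE", 94.0, 0.80, 0.10),
            ("VF", "esp", 93.0, 0.60, 0.10),     # below VF coverage threshold
            ("BA", "hdcA", 100.0, 1.0, 0.15),
            ("BA", "tyrDC", 100.0, 1.0, 0.10),
            ("HEMOLYSIN", "hlyA", 100.0, 1.0, 0.12),
            ("HEMOLYSIN", "cylB", 100.0, 1.0, 0.08),
        ]
    )
    pangenome_plan: PangenomePlan = field(default_factory=PangenomePlan)
    within_family_substitution_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.n_species != len(self.genomes_per_species):
            raise ConfigError("genomes_per_species length must equal n_species")
        if self.genome_length_range[0] <= 0 or self.genome_length_range[1] < self.genome_length_range[0]:
            raise ConfigError("genome_length_range must be positive and ordered")
        if not 0 < self.gc_range[0] <= self.gc_range[1] < 1:
            raise ConfigError("gc_range must lie in (0, 1)")
        unknown = set(self.source_mix) - set(SOURCE_CATEGORIES)
        if unknown:
            raise ConfigError(f"unknown source categories {sorted(unknown)}")
        for plan_name, plan in (
            ("marker_plan", [p[2] for p in self.marker_plan]),
            ("bacteriocin_plan", [p[2] for p in self.bacteriocin_plan]),
            ("safety_plan", [p[4] for p in self.safety_plan]),
        ):
            if any(not 0 <= prob <= 1 for prob in plan):
                raise ConfigError(f"{plan_name} probabilities must lie in [0, 1]")
        for marker_id, mode, _ in self.marker_plan:
            if marker_id not in MARKER_LEXICON:
                raise ConfigError(f"marker {marker_id!r} has no lexicon entry")
            parse_plant_mode(mode)
        # feasibility: worst case every plan entry plants one ~250 aa gene
        n_plants = len(self.marker_plan) + len(self.bacteriocin_plan) + len(self.safety_plan)
        if n_plants * 900 > self.genome_length_range[1]:
            raise ConfigError(
                f"plan places up to {n_plants} genes (~{n_plants * 900} bp) but genomes "
                f"are at most {self.genome_length_range[1]} bp"
            )


def parse_plant_mode(mode: str) -> tuple[str, float | None]:
    if mode in ("exact", "decoy"):
        return mode, None
    if mode.startswith("diverged:"):
        target = float(mode.split(":", 1)[1])
        if target < 5.0:
            raise ConfigError(f"diverged target identity {target}% cannot be controlled")
        return "diverged", target
    raise ConfigError(f"unknown plant mode {mode!r}")


@dataclass
class GroundTruthManifest:
    markers: list[dict] = field(default_factory=list)
    bacteriocins: list[dict] = field(default_factory=list)
    safety: list[dict] = field(default_factory=list)
    families: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        data = json.loads(Path(path).read_text())
        return cls(**data)


@dataclass
class SyntheticCohort:
    config: CohortConfig
    records: list[GenomeRecord]
    manifest: GroundTruthManifest
    metadata: pd.DataFrame
    bacteriocin_hits: pd.DataFrame
    safety_hits: pd.DataFrame
    cazyme_hits: pd.DataFrame
    cazyme_expected: pd.DataFrame


# ---------------------------------------------------------------- sequences

_CODONS_BY_AA: dict[str, list[tuple[str, int]]] = {}
for _codon, _aa in unambiguous_dna_by_id[11].forward_table.items():
    if set(_codon) <= set("ACGT"):
        _CODONS_BY_AA.setdefault(_aa, []).append((_codon, _codon.count("G") + _codon.count("C")))
for _aa in _CODONS_BY_AA:
    _CODONS_BY_AA[_aa].sort(key=lambda cg: (cg[1], cg[0]))


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def mutate_protein(rng: np.random.Generator, protein: str, n_substitutions: int) -> str:
    """Substitute exactly ``n_substitutions`` positions with different residues."""
    seq = list(protein)
    positions = rng.choice(len(seq), size=n_substitutions, replace=False)
    for pos in positions:
        alternatives = [a for a in AMINO_ACIDS if a != seq[pos]]
        seq[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(seq)


def reference_protein(marker_id: str) -> str:
    """Deterministic curated-reference stand-in for a marker (synthetic:
    derived from the marker id, stable across runs and processes)."""
    crc = zlib.crc32(marker_id.encode())
    rng = np.random.default_rng(crc % (2**31))
    return random_protein(rng, 160 + crc % 100)


def reference_db(marker_ids: list[str]):
    """Reference panel for :mod:`sequence_confirmation`, one sequence per marker."""
    from .sequence_confirmation import ReferenceProtein

    return {
        m: [ReferenceProtein(m, f"SYN_{m.upper()}", reference_protein(m))]
        for m in sorted(set(marker_ids))
    }


def back_translate(rng: np.random.Generator, protein: str, gc: float) -> str:
    """Codon choice steered so the coding sequence lands near the target GC."""
    options = [_CODONS_BY_AA[aa] for aa in protein]
    min_gc = sum(opts[0][1] for opts in options)
    max_gc = sum(opts[-1][1] for opts in options)
    needed = int(np.clip(round(gc * 3 * len(protein)), min_gc, max_gc))
    deficit = needed - min_gc
    codons = [""] * len(protein)
    for idx in rng.permutation(len(protein)):
        opts = options[idx]
        base = opts[0][1]
        extra = min(deficit, opts[-1][1] - base)
        attainable = [cg for cg in opts if cg[1] - base <= extra]
        target = max(cg[1] for cg in attainable)
        pick = [cg for cg in attainable if cg[1] == target]
        codons[idx] = pick[rng.integers(len(pick))][0]
        deficit -= target - base
    return "".join(codons)


def spacer(rng: np.random.Generator, gc: float, length: int | None = None) -> str:
    """Intergenic spacer (>= 50 bp) with an exact-proportion GC fill."""
    if length is None:
        length = int(rng.integers(50, 151))
    n_gc = int(np.clip(round(gc * length), 0, length))
    bases = np.concatenate(
        [rng.choice(list("GC"), size=n_gc), rng.choice(list("AT"), size=length - n_gc)]
    )
    rng.shuffle(bases)
    return "".join(bases)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def append_gene(
    genome: GenomeRecord,
    protein: str,
    rng: np.random.Generator,
    gc: float,
    gene: str | None = None,
    product: str | None = "hypothetical protein",
    note: str | None = None,
    contig_id: str | None = None,
) -> CdsFeature:
    """Append one CDS (preceded by a spacer) to a contig; returns the feature."""
    if contig_id is None:
        contig_id = list(genome.contigs)[rng.integers(len(genome.contigs))]
    gap = spacer(rng, gc)
    cds = back_translate(rng, protein, gc) + "TAA"
    strand = "+" if rng.integers(2) else "-"
    nt = cds if strand == "+" else _revcomp(cds)
    current = genome.contigs[contig_id]
    start = len(current) + len(gap) + 1
    genome.contigs[contig_id] = current + gap + nt
    feature = CdsFeature(
        locus_tag=f"{genome.genome_id}_{len(genome.features) + 1:05d}",
        contig_id=contig_id,
        start=start,
        end=start + len(nt) - 1,
        strand=strand,
        translation=protein,
        gene_name=gene,
        product=product,
        note=note,
    )
    genome.features.append(feature)
    return feature


# ---------------------------------------------------------------- planting

def plant_marker(
    genome: GenomeRecord,
    reference: str,
    mode: str,
    rng: np.random.Generator,
    marker_id: str,
    gc: float = 0.40,
) -> tuple[GenomeRecord, dict]:
    """Plant one marker gene; returns the genome and its manifest entry.

    ``exact`` copies the reference with a marker-consistent annotation;
    ``diverged:<pct>`` introduces substitutions so realized identity equals
    the target to within rounding; ``decoy`` attaches the marker-consistent
    annotation to an unrelated random sequence.
    """
    kind, target = parse_plant_mode(mode)
    gene_symbol, product = MARKER_LEXICON[marker_id]
    if kind == "exact":
        protein, realized = reference, 100.0
    elif kind == "diverged":
        n_sub = round(len(reference) * (1 - target / 100.0))
        protein = mutate_protein(rng, reference, n_sub)
        realized = 100.0 * (len(reference) - n_sub) / len(reference)
    else:  # decoy
        length = int(len(reference) * rng.uniform(0.8, 1.2))
        protein, realized = random_protein(rng, length), None
    feature = append_gene(genome, protein, rng, gc, gene=gene_symbol, product=product)
    entry = {
        "genome_id": genome.genome_id,
        "marker_id": marker_id,
        "locus_tag": feature.locus_tag,
        "mode": mode,
        "target_identity": target if kind == "diverged" else (100.0 if kind == "exact" else None),
        "realized_identity": realized,
    }
    return genome, entry


def plant_bacteriocin(
    genome: GenomeRecord, name: str, subclass: str, rng: np.random.Generator, gc: float
) -> dict:
    protein = random_protein(rng, int(rng.integers(40, 90)))
    feature = append_gene(genome, protein, rng, gc, gene=None, product=f"{name} precursor peptide")
    return {
        "genome_id": genome.genome_id,
        "name": name,
        "subclass": subclass,
        "locus_tag": feature.locus_tag,
        "contig_id": feature.contig_id,
        "start": feature.start,
        "end": feature.end,
    }


def plant_safety_gene(
    genome: GenomeRecord,
    panel: str,
    gene: str,
    identity: float,
    coverage: float,
    rng: np.random.Generator,
    gc: float,
) -> dict:
    symbol, product = SAFETY_LEXICON[(panel, gene)]
    ref = reference_protein(f"safety:{gene}")
    truncated = ref[: max(10, round(coverage * len(ref)))]
    n_sub = round(len(truncated) * (1 - identity / 100.0))
    protein = mutate_protein(rng, truncated, n_sub)
    feature = append_gene(genome, protein, rng, gc, gene=symbol, product=product)
    return {
        "genome_id": genome.genome_id,
        "panel": panel,
        "gene": gene,
        "locus_tag": feature.locus_tag,
        "identity": identity,
        "coverage": coverage,
    }


# ---------------------------------------------------------------- cohort

def simulate_protein_families(
    n_genomes: int,
    n_core_families: int,
    unique_per_genome: int,
    seed: int = 0,
) -> tuple[list[tuple[str, str, str]], dict[tuple[str, str], str]]:
    """Protein-level family fixture: exact-copy core families shared by every
    genome plus private random genes; returns (proteins, true family map)."""
    rng = np.random.default_rng(seed)
    cores = [random_protein(rng, int(rng.integers(120, 250))) for _ in range(n_core_families)]
    proteins: list[tuple[str, str, str]] = []
    truth: dict[tuple[str, str], str] = {}
    for g in range(n_genomes):
        gid = f"g{g + 1:03d}"
        for i, core in enumerate(cores):
            pid = f"{gid}_core{i:03d}"
            proteins.append((gid, pid, core))
            truth[(gid, pid)] = f"core{i:03d}"
        for u in range(unique_per_genome):
            pid = f"{gid}_uniq{u:03d}"
            proteins.append((gid, pid, random_protein(rng, int(rng.integers(120, 250)))))
            truth[(gid, pid)] = f"uniq_{gid}_{u:03d}"
    return proteins, truth


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full cohort: genomes, metadata, manifest and raw hit tables."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    plan = config.pangenome_plan

    core_refs = [random_protein(rng, int(rng.integers(120, 260))) for _ in range(plan.n_core_families)]
    accessory_refs = [random_protein(rng, int(rng.integers(120, 260))) for _ in range(plan.n_accessory_pool)]

    manifest = GroundTruthManifest()
    records: list[GenomeRecord] = []
    sources = list(config.source_mix)
    weights = np.array([config.source_mix[s] for s in sources], dtype=float)
    weights /= weights.sum()

    for s in range(config.n_species):
        species = f"Species sp{s + 1:02d}"
        genus = f"Genus g{s % 3 + 1}"
        species_gc = rng.uniform(*config.gc_range)
        species_len = rng.uniform(*config.genome_length_range)
        for g in range(config.genomes_per_species[s]):
            gid = f"sp{s + 1:02d}g{g + 1:03d}"
            gc = float(np.clip(species_gc + rng.normal(0, 0.004), *config.gc_range))
            target_len = species_len * rng.uniform(0.95, 1.05)
            n_contigs = int(rng.integers(1, 5))
            genome = GenomeRecord(
                genome_id=gid,
                contigs={f"{gid}_c{c + 1}": "" for c in range(n_contigs)},
                species_label=species,
                genus_label=genus,
                source_category=str(rng.choice(sources, p=weights)),
                completeness=round(float(rng.uniform(96, 100)), 2),
                contamination=round(float(rng.uniform(0, 3)), 2),
            )
            mut = config.within_family_substitution_rate
            for i, ref in enumerate(core_refs):
                protein = mutate_protein(rng, ref, round(mut * len(ref)))
                feat = append_gene(genome, protein, rng, gc)
                manifest.families.append(
                    {"genome_id": gid, "locus_tag": feat.locus_tag, "family_id": f"core{i:03d}"}
                )
            for i, ref in enumerate(accessory_refs):
                if rng.random() < plan.accessory_rate:
                    protein = mutate_protein(rng, ref, round(mut * len(ref)))
                    feat = append_gene(genome, protein, rng, gc)
                    manifest.families.append(
                        {"genome_id": gid, "locus_tag": feat.locus_tag, "family_id": f"acc{i:03d}"}
                    )
            for u in range(plan.unique_gene_rate):
                feat = append_gene(genome, random_protein(rng, int(rng.integers(120, 260))), rng, gc)
                manifest.families.append(
                    {"genome_id": gid, "locus_tag": feat.locus_tag, "family_id": f"uniq_{gid}_{u:03d}"}
                )
            # filler singleton genes up to the target genome length
            f = 0
            while sum(len(c) for c in genome.contigs.values()) < target_len:
                feat = append_gene(genome, random_protein(rng, int(rng.integers(120, 260))), rng, gc)
                manifest.families.append(
                    {"genome_id": gid, "locus_tag": feat.locus_tag, "family_id": f"fill_{gid}_{f:03d}"}
                )
                f += 1
            for marker_id, mode, prob in config.marker_plan:
                if rng.random() < prob:
                    _, entry = plant_marker(
                        genome, reference_protein(marker_id), mode, rng, marker_id, gc
                    )
                    manifest.markers.append(entry)
            for name, subclass, prob in config.bacteriocin_plan:
                if rng.random() < prob:
                    manifest.bacteriocins.append(plant_bacteriocin(genome, name, subclass, rng, gc))
            for panel, gene, identity, coverage, prob in config.safety_plan:
                if rng.random() < prob:
                    manifest.safety.append(
                        plant_safety_gene(genome, panel, gene, identity, coverage, rng, gc)
                    )
            for cid in list(genome.contigs):
                genome.contigs[cid] += spacer(rng, gc)
            genome.validate()
            records.append(genome)

    metadata = write_metadata_frame(records)
    bacteriocin_hits = _bacteriocin_hit_table(manifest, rng)
    safety_hits = _safety_hit_table(manifest)
    cazyme_hits, cazyme_expected = _cazyme_hit_table(records, rng)
    return SyntheticCohort(
        config, records, manifest, metadata, bacteriocin_hits, safety_hits,
        cazyme_hits, cazyme_expected,
    )


def write_metadata_frame(records: list[GenomeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome_id": r.genome_id,
                "species": r.species_label,
                "genus": r.genus_label,
                "source_category": r.source_category,
                "completeness": r.completeness,
                "contamination": r.contamination,
                "assembly_level": "contig",
                "excluded_origin": False,
            }
            for r in records
        ]
    )


def _bacteriocin_hit_table(manifest: GroundTruthManifest, rng: np.random.Generator) -> pd.DataFrame:
    """BAGEL4-style raw hits: one structural row per planted locus, plus
    redundant overlapping structural duplicates and non-structural rows."""
    rows = []
    for entry in manifest.bacteriocins:
        score = round(float(rng.uniform(80, 250)), 1)
        base = {
            "genome_id": entry["genome_id"],
            "contig_id": entry["contig_id"],
            "bacteriocin_name": entry["name"],
        }
        rows.append({**base, "start": entry["start"], "end": entry["end"],
                     "role": "structural", "score": score})
        span = entry["end"] - entry["start"] + 1
        if rng.random() < 0.4:  # redundant overlapping duplicate
            shift = int(rng.integers(1, max(2, span // 5)))
            rows.append({**base, "start": entry["start"] + shift, "end": entry["end"] + shift,
                         "role": "structural", "score": round(score - 10.0, 1)})
        if rng.random() < 0.6:  # accompanying transport/immunity gene
            rows.append({**base, "start": entry["end"] + 200, "end": entry["end"] + 1100,
                         "role": ("immunity", "transport")[int(rng.integers(2))],
                         "score": round(float(rng.uniform(40, 90)), 1)})
    return pd.DataFrame(
        rows, columns=["genome_id", "contig_id", "start", "end", "bacteriocin_name", "role", "score"]
    )


def _safety_hit_table(manifest: GroundTruthManifest) -> pd.DataFrame:
    """Screening-style tabular hits for the alignment panels (AMR/VF)."""
    rows = [
        {
            "genome_id": e["genome_id"],
            "panel_id": e["panel"],
            "gene": e["gene"],
            "locus": e["locus_tag"],
            "coverage": e["coverage"],
            "identity": e["identity"],
        }
        for e in manifest.safety
        if e["panel"] in ("AMR", "VF")
    ]
    return pd.DataFrame(
        rows, columns=["genome_id", "panel_id", "gene", "locus", "coverage", "identity"]
    )


_CAZY_POOL = (
    ("GH13", 0.14), ("GH1", 0.10), ("GH23", 0.08), ("GH25", 0.08), ("GH73", 0.06),
    ("GT2", 0.14), ("GT4", 0.12), ("GT8", 0.06), ("GT28", 0.04),
    ("CBM50", 0.08), ("CBM48", 0.03), ("CE4", 0.03), ("AA3", 0.02), ("PL8", 0.02),
)


def _cazy_label(family: str, rng: np.random.Generator) -> str:
    dialect = rng.integers(3)
    if dialect == 0:
        return family
    if dialect == 1:
        return f"{family}_{int(rng.integers(1, 40))}"
    return f"ACC{int(rng.integers(1000, 9999))}|{family}({int(rng.integers(1, 50))}-{int(rng.integers(100, 400))})"


def _cazyme_hit_table(
    records: list[GenomeRecord], rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DIAMOND-style hits with a known best hit per query; the expected table
    lists the assignments surviving the top-1 + E < 1e-102 rule."""
    families = [f for f, _ in _CAZY_POOL]
    probs = np.array([w for _, w in _CAZY_POOL])
    probs /= probs.sum()
    raw, expected = [], []
    for record in records:
        gid = record.genome_id
        for q in range(int(rng.integers(20, 41))):
            qseqid = f"{gid}_caz{q:03d}"
            family = str(rng.choice(families, p=probs))
            strong = rng.random() >= 0.15
            exponent = rng.uniform(103, 180) if strong else rng.uniform(60, 101)
            best_bits = round(float(rng.uniform(320, 480)), 1)
            raw.append(
                {
                    "genome_id": gid,
                    "qseqid": qseqid,
                    "sseqid": _cazy_label(family, rng),
                    "evalue": 10.0 ** -exponent,
                    "bitscore": best_bits,
                }
            )
            if rng.random() < 0.5:  # weaker secondary hit to another family
                other = str(rng.choice([f for f in families if f != family]))
                raw.append(
                    {
                        "genome_id": gid,
                        "qseqid": qseqid,
                        "sseqid": _cazy_label(other, rng),
                        "evalue": 10.0 ** -rng.uniform(103, 150),
                        "bitscore": round(best_bits - float(rng.uniform(20, 80)), 1),
                    }
                )
            if strong:
                expected.append({"genome_id": gid, "qseqid": qseqid, "family": family})
    return (
        pd.DataFrame(raw, columns=["genome_id", "qseqid", "sseqid", "evalue", "bitscore"]),
        pd.DataFrame(expected, columns=["genome_id", "qseqid", "family"]),
    )


# ---------------------------------------------------------------- output

def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write the cohort as per-genome GFF3/FASTA plus metadata, manifest and
    raw hit tables; returns the cohort directory."""
    outdir = Path(outdir)
    (outdir / "genomes").mkdir(parents=True, exist_ok=True)
    (outdir / "hits").mkdir(exist_ok=True)
    for record in cohort.records:
        write_genome(record, outdir / "genomes")
    write_metadata(cohort.records, outdir / "metadata.tsv")
    cohort.manifest.to_json(outdir / "manifest.json")
    cohort.bacteriocin_hits.to_csv(outdir / "hits" / "bacteriocin_hits.tsv", sep="\t", index=False)
    cohort.safety_hits.to_csv(outdir / "hits" / "safety_hits.tsv", sep="\t", index=False)
    cohort.cazyme_hits.to_csv(outdir / "hits" / "cazyme_hits.tsv", sep="\t", index=False)
    cohort.cazyme_expected.to_csv(outdir / "hits" / "cazyme_expected.tsv", sep="\t", index=False)
    return outdir
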