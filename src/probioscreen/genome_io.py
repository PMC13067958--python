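"""Uniform in-memory genome model plus GFF3/FASTA readers and writers.

Every downstream stage consumes :class:`GenomeRecord` objects: a set of
nucleotide contigs, the CDS features annotated on them (with the free-text
``gene``/``product``/``note`` attributes that the marker screen mines), and
the per-genome metadata (species, isolation source, CheckM-style completeness
and contamination estimates).

Coordinates are 1-based inclusive throughout the package; conversion to the
half-open convention used by in-memory slicing is confined to this module.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

SOURCE_CATEGORIES = ("fermentation", "environment", "human", "animal", "other", "missing")

#: GFF3 attribute keys mined by the marker screen (matched case-insensitively).
ANNOTATION_FIELDS = ("gene", "product", "note")


class GenomeIOError(ValueError):
    """Malformed or inconsistent genome input."""


@dataclass
class CdsFeature:
    """One CDS line of a GFF3 annotation.

    ``start``/``end`` are 1-based inclusive base-pair coordinates on
    ``contig_id``; ``translation`` is the amino-acid sequence (trailing stop
    removed).  ``translation_source`` records whether the protein came from a
    supplied protein FASTA or was self-translated from the nucleotide span.
    """

    locus_tag: str
    contig_id: str
    start: int
    end: int
    strand: str
    translation: str
    gene_name: str | None = None
    product: str | None = None
    note: str | None = None
    translation_source: str = "protein_fasta"

    def annotation_field(self, name: str) -> str | None:
        if name not in ANNOTATION_FIELDS:
            raise ValueError(f"unknown annotation field {name!r}")
        return {"gene": self.gene_name, "product": self.product, "note": self.note}[name]


@dataclass
class GenomeRecord:
    """One annotated assembly plus its cohort metadata."""

    genome_id: str
    contigs: dict[str, str]
    features: list[CdsFeature] = field(default_factory=list)
    species_label: str = ""
    genus_label: str = ""
    source_category: str = "missing"
    completeness: float = 100.0
    contamination: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.source_category not in SOURCE_CATEGORIES:
            raise GenomeIOError(
                f"{self.genome_id}: source_category {self.source_category!r} "
                f"not one of {SOURCE_CATEGORIES}"
            )
        for value, name in ((self.completeness, "completeness"), (self.contamination, "contamination")):
            if not 0.0 <= value <= 100.0:
                raise GenomeIOError(f"{self.genome_id}: {name} {value} outside [0, 100]")
        seen: set[str] = set()
        for feat in self.features:
            if feat.locus_tag in seen:
                raise GenomeIOError(f"{self.genome_id}: duplicate locus_tag {feat.locus_tag}")
            seen.add(feat.locus_tag)
            if feat.contig_id not in self.contigs:
                raise GenomeIOError(
                    f"{self.genome_id}: feature {feat.locus_tag} references missing "
                    f"contig {feat.contig_id}"
                )
            clen = len(self.contigs[feat.contig_id])
            if not 1 <= feat.start <= feat.end <= clen:
                raise GenomeIOError(
                    f"{self.genome_id}: feature {feat.locus_tag} span "
                    f"{feat.start}..{feat.end} outside contig of length {clen}"
                )
            if not feat.translation:
                raise GenomeIOError(f"{self.genome_id}: feature {feat.locus_tag} has empty translation")

    def feature(self, locus_tag: str) -> CdsFeature:
        for feat in self.features:
            if feat.locus_tag == locus_tag:
                return feat
        raise KeyError(f"{self.genome_id}: unknown locus_tag {locus_tag!r}")


def translate_cds(nucleotides: str, strand: str = "+") -> str:
    """Translate a CDS span with bacterial translation table 11.

    The minus strand is reverse-complemented first; the trailing stop is
    trimmed; ambiguous codons become X; the start codon is translated as the
    annotated residue (no forced Met), matching Prokka protein FASTA output.
    """
    seq = Seq(nucleotides)
    if strand == "-":
        seq = seq.reverse_complement()
    if len(seq) % 3 != 0:
        raise GenomeIOError(f"CDS length {len(seq)} not divisible by 3")
    protein = str(seq.translate(table=11))
    if protein.endswith("*"):
        protein = protein[:-1]
    return protein


def _attribute(attrs: dict, key: str) -> str | None:
    """Case-insensitive attribute lookup; multi-valued entries joined with '; '."""
    for k, values in attrs.items():
        if k.lower() == key:
            joined = "; ".join(str(v) for v in values)
            return joined if joined else None
    return None


def read_annotated_genome(
    gff3_path: str | Path,
    nucleotide_fasta_path: str | Path,
    protein_fasta_path: str | Path | None = None,
    *,
    genome_id: str | None = None,
    species_label: str = "",
    genus_label: str = "",
    source_category: str = "missing",
    completeness: float = 100.0,
    contamination: float = 0.0,
) -> GenomeRecord:
    """Parse a GFF3 + nucleotide FASTA (+ optional protein FASTA) into a GenomeRecord.

    One :class:`CdsFeature` is produced per CDS line.  Translations are taken
    from the protein FASTA when supplied (keyed by locus tag); features absent
    from it fall back to self-translation and are flagged via
    ``translation_source='self'``.  A CDS referencing a missing contig is a
    hard error; a CDS whose length is not divisible by 3 when self-translating
    is skipped with a warning.
    """
    gff3_path = Path(gff3_path)
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(nucleotide_fasta_path), "fasta")}
    proteins: dict[str, str] = {}
    if protein_fasta_path is not None:
        proteins = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(protein_fasta_path), "fasta")}

    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", sort_attribute_values=True,
    )
    features: list[CdsFeature] = []
    for f in db.features_of_type("CDS", order_by=("seqid", "start")):
        attrs = dict(f.attributes)
        locus_tag = _attribute(attrs, "locus_tag") or f.id
        if f.seqid not in contigs:
            raise GenomeIOError(
                f"feature {locus_tag} references contig {f.seqid!r} absent from the FASTA"
            )
        translation = proteins.get(locus_tag)
        source = "protein_fasta"
        if translation is None:
            span = contigs[f.seqid][f.start - 1 : f.end]
            try:
                translation = translate_cds(span, f.strand)
            except GenomeIOError as exc:
                log.warning("skipping CDS %s: %s", locus_tag, exc)
                continue
            source = "self"
        features.append(
            CdsFeature(
                locus_tag=locus_tag,
                contig_id=f.seqid,
                start=f.start,
                end=f.end,
                strand=f.strand,
                translation=translation,
                gene_name=_attribute(attrs, "gene"),
                product=_attribute(attrs, "product"),
                note=_attribute(attrs, "note"),
                translation_source=source,
            )
        )
    return GenomeRecord(
        genome_id=genome_id or gff3_path.stem,
        contigs=contigs,
        features=features,
        species_label=species_label,
        genus_label=genus_label,
        source_category=source_category,
        completeness=completeness,
        contamination=contamination,
    )


def extract_protein(genome: GenomeRecord, locus_tag: str) -> str:
    """Return the stored translation for ``locus_tag`` (never recomputed)."""
    return genome.feature(locus_tag).translation


_ESCAPES = (("%", "%25"), (";", "%3B"), ("=", "%3D"), ("&", "%26"), (",", "%2C"))


def _escape(value: str) -> str:
    for char, code in _ESCAPES:
        value = value.replace(char, code)
    return value


def write_genome(genome: GenomeRecord, outdir: str | Path) -> dict[str, Path]:
    """Write ``<genome_id>.gff3/.fna/.faa`` under ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gid = genome.genome_id
    paths = {
        "gff3": outdir / f"{gid}.gff3",
        "fna": outdir / f"{gid}.fna",
        "faa": outdir / f"{gid}.faa",
    }
    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for contig_id, seq in genome.contigs.items():
            fh.write(f"##sequence-region {contig_id} 1 {len(seq)}\n")
        for feat in genome.features:
            attrs = [f"ID={feat.locus_tag}", f"locus_tag={feat.locus_tag}"]
            for key in ("gene", "product", "note"):
                value = feat.annotation_field(key)
                if value is not None:
                    attrs.append(f"{key}={_escape(value)}")
            fh.write(
                "\t".join(
                    (
                        feat.contig_id,
                        "probioscreen",
                        "CDS",
                        str(feat.start),
                        str(feat.end),
                        ".",
                        feat.strand,
                        "0",
                        ";".join(attrs),
                    )
                )
                + "\n"
            )
    SeqIO.write(
        [SeqRecord(Seq(seq), id=cid, description="") for cid, seq in genome.contigs.items()],
        str(paths["fna"]),
        "fasta",
    )
    SeqIO.write(
        [SeqRecord(Seq(f.translation), id=f.locus_tag, description="") for f in genome.features],
        str(paths["faa"]),
        "fasta",
    )
    return paths


METADATA_COLUMNS = [
    "genome_id", "species", "genus", "source_category",
    "completeness", "contamination", "assembly_level", "excluded_origin",
]


def write_metadata(records: list[GenomeRecord], path: str | Path,
                   assembly_levels: dict[str, str] | None = None,
                   excluded_origins: dict[str, bool] | None = None) -> pd.DataFrame:
    """Write the per-cohort metadata TSV for ``records``."""
    rows = []
    for rec in records:
        rows.append(
            {
                "genome_id": rec.genome_id,
                "species": rec.species_label,
                "genus": rec.genus_label,
                "source_category": rec.source_category,
                "completeness": rec.completeness,
                "contamination": rec.contamination,
                "assembly_level": (assembly_levels or {}).get(rec.genome_id, "contig"),
                "excluded_origin": (excluded_origins or {}).get(rec.genome_id, False),
            }
        )
    frame = pd.DataFrame(rows, columns=METADATA_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)
    return frame


def read_metadata(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = set(("genome_id", "species", "source_category")) - set(frame.columns)
    if missing:
        raise GenomeIOError(f"metadata {path} lacks required columns {sorted(missing)}")
    return frame


def load_cohort(cohort_dir: str | Path) -> tuple[list[GenomeRecord], pd.DataFrame]:
    """Load a cohort directory (``metadata.tsv`` + ``genomes/<id>.{gff3,fna,faa}``)."""
    cohort_dir = Path(cohort_dir)
    metadata = read_metadata(cohort_dir / "metadata.tsv")
    records = []
    for _, row in metadata.iterrows():
        gid = row["genome_id"]
        gdir = cohort_dir / "genomes"
        faa = gdir / f"{gid}.faa"
        records.append(
            read_annotated_genome(
                gdir / f"{gid}.gff3",
                gdir / f"{gid}.fna",
                faa if faa.exists() else None,
                genome_id=gid,
                species_label=row.get("species", ""),
                genus_label=row.get("genus", ""),
                source_category=row.get("source_category", "missing"),
                completeness=float(row.get("completeness", 100.0)),
                contamination=float(row.get("contamination", 0.0)),
            )
        )
    return records, metadata
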