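"""Assembly metrics and the cohort inclusion gate.

The gate mirrors the retrieval-time inclusion criteria of the survey this
package supports: assemblies must come from a whitelisted assembly level and
not be MAG/single-cell derived (both metadata flags), must not exceed 200
contigs unless contig N50 is at least 50 kb, and must have CheckM-style
completeness >= 95% with contamination <= 5%.  All thresholds are inclusive
on the stated side.  Species represented by fewer than 10 passing genomes are
dropped from downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome_io import GenomeRecord

ASSEMBLY_LEVELS = ("complete", "chromosome", "scaffold", "contig")

# failed-criterion codes
EXCLUDED_ORIGIN = "EXCLUDED_ORIGIN"
ASSEMBLY_LEVEL = "ASSEMBLY_LEVEL"
CONTIG_COUNT = "CONTIG_COUNT"
COMPLETENESS = "COMPLETENESS"
CONTAMINATION = "CONTAMINATION"


class EmptyCohortError(RuntimeError):
    """No species survived the representation filter."""


@dataclass
class AssemblyMetrics:
    genome_id: str
    total_length: int
    gc_percent: float
    contig_count: int
    n50: int
    completeness: float
    contamination: float
    assembly_level: str = "contig"
    excluded_origin: bool = False


@dataclass
class GateDecision:
    genome_id: str
    passed: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.passed == (not self.reasons)


def n50(contig_lengths: list[int]) -> int:
    """Smallest contig length L such that contigs >= L sum to >= half the assembly."""
    if not contig_lengths:
        raise ValueError("n50 of an empty assembly")
    total = sum(contig_lengths)
    running = 0
    for length in sorted(contig_lengths, reverse=True):
        running += length
        if 2 * running >= total:
            return length
    raise AssertionError("unreachable")


def gc_percent(sequences: list[str]) -> float:
    """GC% over unambiguous bases only (ambiguity codes excluded from both
    numerator and denominator); 0.0 for a sequence with no A/C/G/T."""
    gc = acgt = 0
    for seq in sequences:
        up = seq.upper()
        gc += up.count("G") + up.count("C")
        acgt += gc_denominator(up)
    return 100.0 * gc / acgt if acgt else 0.0


def gc_denominator(seq: str) -> int:
    return sum(seq.count(b) for b in "ACGT")


def compute_metrics(
    genome: GenomeRecord,
    assembly_level: str = "contig",
    excluded_origin: bool = False,
) -> AssemblyMetrics:
    if not genome.contigs:
        raise ValueError(f"{genome.genome_id}: empty genome")
    lengths = [len(s) for s in genome.contigs.values()]
    return AssemblyMetrics(
        genome_id=genome.genome_id,
        total_length=sum(lengths),
        gc_percent=gc_percent(list(genome.contigs.values())),
        contig_count=len(lengths),
        n50=n50(lengths),
        completeness=genome.completeness,
        contamination=genome.contamination,
        assembly_level=assembly_level,
        excluded_origin=excluded_origin,
    )


def apply_gate(
    metrics: AssemblyMetrics,
    *,
    max_contigs: int = 200,
    rescue_n50: int = 50_000,
    min_completeness: float = 95.0,
    max_contamination: float = 5.0,
) -> GateDecision:
    """Apply inclusion criteria (a)-(d); boundary values pass."""
    reasons = []
    if metrics.assembly_level not in ASSEMBLY_LEVELS:
        reasons.append(ASSEMBLY_LEVEL)
    if metrics.excluded_origin:
        reasons.append(EXCLUDED_ORIGIN)
    if metrics.contig_count > max_contigs and metrics.n50 < rescue_n50:
        reasons.append(CONTIG_COUNT)
    if metrics.completeness < min_completeness:
        reasons.append(COMPLETENESS)
    if metrics.contamination > max_contamination:
        reasons.append(CONTAMINATION)
    return GateDecision(metrics.genome_id, passed=not reasons, reasons=reasons)


def filter_species_representation(
    decisions: list[GateDecision],
    metadata: pd.DataFrame,
    min_genomes: int = 10,
) -> set[str]:
    """Species retained iff they have >= ``min_genomes`` passing genomes.

    Raises :class:`EmptyCohortError` when nothing survives, halting the
    pipeline rather than silently producing empty tables.
    """
    passing = {d.genome_id for d in decisions if d.passed}
    counts = (
        metadata[metadata["genome_id"].isin(passing)]
        .groupby("species")["genome_id"]
        .nunique()
    )
    retained = {species for species, n in counts.items() if n >= min_genomes}
    if not retained:
        raise EmptyCohortError(
            f"no species has >= {min_genomes} genomes passing the assembly gate"
        )
    return retained


def qc_report(metrics: list[AssemblyMetrics], decisions: list[GateDecision]) -> pd.DataFrame:
    by_id = {d.genome_id: d for d in decisions}
    rows = []
    for m in metrics:
        d = by_id[m.genome_id]
        rows.append(
            {
                "genome_id": m.genome_id,
                "total_length": m.total_length,
                "gc_percent": round(m.gc_percent, 4),
                "contig_count": m.contig_count,
                "n50": m.n50,
                "completeness": m.completeness,
                "contamination": m.contamination,
                "assembly_level": m.assembly_level,
                "excluded_origin": m.excluded_origin,
                "passed": d.passed,
                "reasons": ";".join(d.reasons),
            }
        )
    return pd.DataFrame(rows)
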