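"""Alignment-based confirmation of regex-derived marker candidates.

Candidate proteins are aligned against a curated reference panel with exact
Smith–Waterman local alignment (BLOSUM62, affine gaps: a gap of length k
costs 11 + k, the BLASTp default costs).  A candidate is confirmed when its
best reference alignment reaches >= 40% amino-acid identity, >= 70% query
coverage and E <= 1e-5 — the conservative thresholds of the screening
protocol; boundary values confirm.

Conventions (stated explicitly because they differ between tools):

* percent identity = 100 * identical aligned pairs / alignment columns,
  gap columns included (conservative);
* query coverage = aligned query span / query length;
* E = K * m * n * exp(-lambda * S) with the standard gapped BLOSUM62
  constants lambda = 0.267, K = 0.041; n is the total residue count of the
  marker's reference set, m the query length.

Reference panels are small, so no heuristic seeding is used; an adapter for
external 12-column tabular alignments is provided instead of reproducing
BLAST's own statistics.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

GAP_OPEN = 11
GAP_EXTEND = 1
KA_LAMBDA = 0.267
KA_K = 0.041

MIN_IDENTITY = 40.0
MIN_COVERAGE = 0.70
MAX_EVALUE = 1e-5

NO_REFERENCE = "NO_REFERENCE"

_RESIDUES = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX]+$")


@dataclass(frozen=True)
class ReferenceProtein:
    marker_id: str
    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence or not _RESIDUES.match(self.sequence):
            raise ValueError(f"reference {self.accession}: invalid residues")


@dataclass(frozen=True)
class AlignmentResult:
    query_id: str
    subject_id: str
    percent_identity: float
    query_coverage: float
    raw_score: float
    e_value: float


@dataclass
class ConfirmationOutcome:
    genome_id: str
    locus_tag: str
    marker_id: str
    best: AlignmentResult | None
    confirmed: bool
    reason: str = ""


def _aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # first gap residue costs open+extend so a length-k gap costs 11 + k
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


_ALIGNER = _aligner()


def _check_sequence(seq: str, what: str) -> None:
    if not seq:
        raise ValueError(f"{what} sequence is empty")
    if not _RESIDUES.match(seq):
        raise ValueError(f"{what} sequence contains non-residue characters")


def local_align(
    query: str,
    subject: str,
    query_id: str = "query",
    subject_id: str = "subject",
    search_space: int | None = None,
) -> AlignmentResult:
    """Optimal Smith–Waterman alignment of ``query`` against ``subject``.

    ``search_space`` overrides the subject-length term n in the E-value (used
    to account for the whole reference set of a marker).
    """
    _check_sequence(query, "query")
    _check_sequence(subject, "subject")
    alignment = _ALIGNER.align(query, subject)[0]
    score = float(alignment.score)
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = 100.0 * counts.identities / columns if columns else 0.0
    qblocks = alignment.aligned[0]
    span = int(qblocks[-1][1] - qblocks[0][0]) if len(qblocks) else 0
    coverage = span / len(query)
    n = search_space if search_space is not None else len(subject)
    e_value = KA_K * len(query) * n * math.exp(-KA_LAMBDA * score)
    return AlignmentResult(query_id, subject_id, identity, coverage, score, e_value)


def passes_thresholds(
    result: AlignmentResult,
    min_identity: float = MIN_IDENTITY,
    min_coverage: float = MIN_COVERAGE,
    max_evalue: float = MAX_EVALUE,
) -> bool:
    return (
        result.percent_identity >= min_identity
        and result.query_coverage >= min_coverage
        and result.e_value <= max_evalue
    )


def load_reference_panel(fasta_path: str | Path) -> dict[str, list[ReferenceProtein]]:
    """Read a reference FASTA with ``accession|marker_id`` headers."""
    db: dict[str, list[ReferenceProtein]] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        try:
            accession, marker_id = rec.id.split("|", 1)
        except ValueError as exc:
            raise ValueError(f"reference header {rec.id!r} is not 'accession|marker_id'") from exc
        db.setdefault(marker_id, []).append(
            ReferenceProtein(marker_id, accession, str(rec.seq))
        )
    return db


def confirm_hit(
    marker_hit,
    genome,
    reference_db: dict[str, list[ReferenceProtein]],
    min_identity: float = MIN_IDENTITY,
    min_coverage: float = MIN_COVERAGE,
    max_evalue: float = MAX_EVALUE,
) -> ConfirmationOutcome:
    """Align one candidate against every reference for its marker.

    Best hit = highest raw score, ties broken by lowest E-value then
    lexicographic accession.  Markers with no reference yield an unconfirmed
    outcome with reason ``NO_REFERENCE`` rather than an error.
    """
    query = genome.feature(marker_hit.locus_tag).translation
    references = reference_db.get(marker_hit.marker_id, [])
    if not references:
        return ConfirmationOutcome(
            marker_hit.genome_id, marker_hit.locus_tag, marker_hit.marker_id,
            best=None, confirmed=False, reason=NO_REFERENCE,
        )
    total_residues = sum(len(r.sequence) for r in references)
    results = [
        local_align(query, ref.sequence, marker_hit.locus_tag, ref.accession,
                    search_space=total_residues)
        for ref in sorted(references, key=lambda r: r.accession)
    ]
    best = min(results, key=lambda r: (-r.raw_score, r.e_value, r.subject_id))
    confirmed = passes_thresholds(best, min_identity, min_coverage, max_evalue)
    return ConfirmationOutcome(
        marker_hit.genome_id, marker_hit.locus_tag, marker_hit.marker_id,
        best=best, confirmed=confirmed,
    )


def confirm_hits(hits, genomes, reference_db, **thresholds) -> list[ConfirmationOutcome]:
    by_id = {g.genome_id: g for g in genomes}
    return [confirm_hit(h, by_id[h.genome_id], reference_db, **thresholds) for h in hits]


def concordance(outcomes: list[ConfirmationOutcome]) -> pd.DataFrame:
    """Per-marker candidate/confirmed counts and concordance percentage.

    Markers with zero candidates never appear (callers wanting an explicit
    row may reindex); a marker present with zero candidates after filtering
    would get concordance NA, never 0.
    """
    rows = []
    by_marker: dict[str, list[ConfirmationOutcome]] = {}
    for o in outcomes:
        by_marker.setdefault(o.marker_id, []).append(o)
    for marker_id in sorted(by_marker):
        group = by_marker[marker_id]
        n = len(group)
        confirmed = sum(o.confirmed for o in group)
        rows.append(
            {
                "marker_id": marker_id,
                "n_candidates": n,
                "n_confirmed": confirmed,
                "concordance_pct": 100.0 * confirmed / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["marker_id", "n_candidates", "n_confirmed", "concordance_pct"])


def outcomes_frame(outcomes: list[ConfirmationOutcome]) -> pd.DataFrame:
    rows = []
    for o in outcomes:
        rows.append(
            {
                "genome_id": o.genome_id,
                "locus_tag": o.locus_tag,
                "marker_id": o.marker_id,
                "best_accession": o.best.subject_id if o.best else "",
                "percent_identity": round(o.best.percent_identity, 4) if o.best else float("nan"),
                "query_coverage": round(o.best.query_coverage, 4) if o.best else float("nan"),
                "e_value": o.best.e_value if o.best else float("nan"),
                "confirmed": o.confirmed,
                "reason": o.reason,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id", "locus_tag", "marker_id", "best_accession",
            "percent_identity", "query_coverage", "e_value", "confirmed", "reason",
        ],
    )


OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_tabular_alignments(path: str | Path, query_lengths: dict[str, int]) -> list[AlignmentResult]:
    """Adapter for external outfmt-6-style alignments (12 columns, no header)."""
    frame = pd.read_csv(path, sep="\t", names=OUTFMT6_COLUMNS)
    results = []
    for _, row in frame.iterrows():
        qlen = query_lengths[row["qseqid"]]
        span = abs(int(row["qend"]) - int(row["qstart"])) + 1
        results.append(
            AlignmentResult(
                query_id=row["qseqid"],
                subject_id=row["sseqid"],
                percent_identity=float(row["pident"]),
                query_coverage=span / qlen,
                raw_score=float(row["bitscore"]),
                e_value=float(row["evalue"]),
            )
        )
    return results


def identity_vs_query(query: str, reference: str) -> float:
    """Identical aligned pairs as a percentage of the full query length.

    A near-global identity measure used for planted-gene bookkeeping: 100 for
    an exact copy, ~target for a substitution-diverged copy, small for an
    unrelated sequence even when a short local alignment is itself
    high-identity.
    """
    _check_sequence(query, "query")
    _check_sequence(reference, "reference")
    alignment = _ALIGNER.align(query, reference)[0]
    return 100.0 * alignment.counts().identities / len(query)
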