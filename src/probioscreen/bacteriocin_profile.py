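"""Bacteriocin hit consolidation, subclass assignment and species summaries.

Raw motif-based detections (BAGEL4-style rows: genome, contig, span, name,
role, score) are consolidated into loci: structural-role hits that share a
name and overlap by more than half of the shorter span collapse into one
locus keeping the best score; immunity/transport/biosynthetic rows never
create loci.  Named loci are mapped onto the classical subclass scheme —
class I lantibiotics, IIa pediocin-like, IIb two-peptide, IIc circular,
IId linear unmodified, III large heat-labile proteins — via a packaged,
editable name table; unmapped names become "other".

The species roll-up reproduces the abundance/diversity summary schema:
% of genomes with >= 1 locus, total locus count, distinct named types, the
top-3 dominant names, and a producer tier (strong >= 500 loci,
50 < moderate < 500, low/none otherwise — thresholds inferred from, and
checked against, the published species table shipped as reference data).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

SUBCLASSES = ("I", "IIa", "IIb", "IIc", "IId", "III", "other")
ROLES = ("structural", "immunity", "transport", "biosynthetic")

STRONG_MIN_ABUNDANCE = 500
MODERATE_MIN_ABUNDANCE = 50  # exclusive lower bound

NO_LOCI = "NO_LOCI"

HIT_COLUMNS = ["genome_id", "contig_id", "start", "end", "bacteriocin_name", "role", "score"]


@dataclass(frozen=True)
class BacteriocinLocus:
    genome_id: str
    contig_id: str
    start: int
    end: int
    bacteriocin_name: str
    score: float
    subclass: str = ""


def _overlap_majority(a: tuple[int, int], b: tuple[int, int], min_fraction: float) -> bool:
    overlap = min(a[1], b[1]) - max(a[0], b[0]) + 1
    shorter = min(a[1] - a[0] + 1, b[1] - b[0] + 1)
    return overlap > min_fraction * shorter


def consolidate(raw_hits: pd.DataFrame, overlap_fraction: float = 0.5) -> list[BacteriocinLocus]:
    """Merge overlapping/redundant structural hits into loci.

    Identical duplicates are removed; hits merge when they share
    (genome, contig, name) and overlap by > ``overlap_fraction`` of the
    shorter span (transitively); the merged locus spans their union and
    keeps the highest score.  Idempotent.
    """
    structural = raw_hits[raw_hits["role"] == "structural"].drop_duplicates(
        subset=["genome_id", "contig_id", "start", "end", "bacteriocin_name"]
    )
    loci: list[BacteriocinLocus] = []
    keys = ["genome_id", "contig_id", "bacteriocin_name"]
    for (genome_id, contig_id, name), group in sorted(
        structural.groupby(keys), key=lambda kv: kv[0]
    ):
        spans = group.sort_values(["start", "end"])[["start", "end", "score"]].to_numpy()
        # union-find over the transitive overlap relation
        parent = list(range(len(spans)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(spans)):
            for j in range(i + 1, len(spans)):
                a = (int(spans[i][0]), int(spans[i][1]))
                b = (int(spans[j][0]), int(spans[j][1]))
                if _overlap_majority(a, b, overlap_fraction):
                    parent[find(i)] = find(j)
        clusters: dict[int, list[int]] = {}
        for i in range(len(spans)):
            clusters.setdefault(find(i), []).append(i)
        for members in sorted(clusters.values(), key=lambda m: int(spans[m[0]][0])):
            loci.append(
                BacteriocinLocus(
                    genome_id=genome_id,
                    contig_id=contig_id,
                    start=int(min(spans[i][0] for i in members)),
                    end=int(max(spans[i][1] for i in members)),
                    bacteriocin_name=name,
                    score=float(max(spans[i][2] for i in members)),
                )
            )
    return loci


def _normalize_name(name: str) -> str:
    return re.sub(r"\s+", " ", name.strip()).lower()


def load_subclass_table(path: str | Path | None = None) -> dict[str, str]:
    if path is None:
        path = Path(str(resources.files("probioscreen").joinpath("data/bacteriocin_subclasses.tsv")))
    frame = pd.read_csv(path, sep="\t")
    table = {}
    for _, row in frame.iterrows():
        subclass = row["subclass"]
        if subclass not in SUBCLASSES:
            raise ValueError(f"{row['bacteriocin_name']!r}: unknown subclass {subclass!r}")
        table[_normalize_name(row["bacteriocin_name"])] = subclass
    return table


def assign_subclass(bacteriocin_name: str, mapping_table: dict[str, str]) -> str:
    """Exact-name lookup after whitespace/case normalization; unmapped -> other."""
    return mapping_table.get(_normalize_name(bacteriocin_name), "other")


def assign_subclasses(loci: list[BacteriocinLocus], mapping_table: dict[str, str]) -> list[BacteriocinLocus]:
    return [
        BacteriocinLocus(
            l.genome_id, l.contig_id, l.start, l.end, l.bacteriocin_name, l.score,
            subclass=assign_subclass(l.bacteriocin_name, mapping_table),
        )
        for l in loci
    ]


def tier(total_abundance: int) -> str:
    if total_abundance >= STRONG_MIN_ABUNDANCE:
        return "Strong producer"
    if total_abundance > MODERATE_MIN_ABUNDANCE:
        return "Moderate"
    return "Low/none"


def species_summary(loci: list[BacteriocinLocus], metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-species abundance/diversity roll-up (one row per species)."""
    species_of = dict(zip(metadata["genome_id"], metadata["species"]))
    genomes_per_species = metadata.groupby("species")["genome_id"].nunique()
    frame = loci_frame(loci)
    frame["species"] = frame["genome_id"].map(species_of)
    rows = []
    for species in sorted(genomes_per_species.index):
        n = int(genomes_per_species[species])
        if n == 0:
            continue
        sub = frame[frame["species"] == species]
        with_any = sub["genome_id"].nunique()
        name_counts = sub["bacteriocin_name"].value_counts()
        dominant = (
            "; ".join(
                name
                for name, _ in sorted(name_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:3]
            )
            if len(name_counts)
            else "None"
        )
        total = int(len(sub))
        rows.append(
            {
                "species": species,
                "n_genomes": n,
                "pct_with_any": round(100.0 * with_any / n, 1),
                "total_abundance": total,
                "unique_types": int(name_counts.size),
                "dominant": dominant,
                "notes": tier(total),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["species", "n_genomes", "pct_with_any", "total_abundance",
                 "unique_types", "dominant", "notes"],
    )


def subclass_composition(loci: list[BacteriocinLocus], metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-species proportions over the subclass scheme; rows sum to 1.
    Species without loci emit an all-zero row flagged NO_LOCI."""
    species_of = dict(zip(metadata["genome_id"], metadata["species"]))
    frame = loci_frame(loci)
    frame["species"] = frame["genome_id"].map(species_of)
    rows = []
    for species in sorted(metadata["species"].unique()):
        sub = frame[frame["species"] == species]
        counts = {sc: int((sub["subclass"] == sc).sum()) for sc in SUBCLASSES}
        total = sum(counts.values())
        row = {"species": species, "n_loci": total,
               "flag": "" if total else NO_LOCI}
        for sc in SUBCLASSES:
            row[sc] = counts[sc] / total if total else 0.0
        rows.append(row)
    return pd.DataFrame(rows, columns=["species", "n_loci", "flag", *SUBCLASSES])


def loci_frame(loci: list[BacteriocinLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome_id": l.genome_id,
                "contig_id": l.contig_id,
                "start": l.start,
                "end": l.end,
                "bacteriocin_name": l.bacteriocin_name,
                "score": l.score,
                "subclass": l.subclass,
            }
            for l in loci
        ],
        columns=["genome_id", "contig_id", "start", "end", "bacteriocin_name", "score", "subclass"],
    )


def reference_species_summary() -> pd.DataFrame:
    """The published species-level bacteriocin summary shipped as data (used
    by the tier-rule consistency check)."""
    path = resources.files("probioscreen").joinpath("data/bacteriocin_species_summary_reference.tsv")
    return pd.read_csv(str(path), sep="\t")
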