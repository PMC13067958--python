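"""CAZy search-output filtering and family/class aggregation.

Consumes DIAMOND-style 12-column tabular hits of predicted proteins against
the CAZy database and applies the dbCAN DIAMOND-workflow rule: keep only the
single best hit per query (highest bit score; ties broken by lowest E-value
then lexicographic subject) and only when E < 1e-102 (strict).  Families are
parsed from heterogeneous subject-label dialects ("GH13", "GH13_31",
"ACC|GH13(...)"); the class is the alphabetic prefix (GH, GT, PL, CE, AA,
CBM) and subfamilies are retained in a separate column.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd

log = logging.getLogger(__name__)

CAZY_CLASSES = ("GH", "GT", "PL", "CE", "AA", "CBM")
EVALUE_CUTOFF = 1e-102

_FAMILY = re.compile(r"\b(GH|GT|PL|CE|AA|CBM)(\d+)(?:_(\d+))?\b")


@dataclass(frozen=True)
class CazymeAssignment:
    protein_id: str
    genome_id: str
    family: str
    subfamily: str
    cazy_class: str
    e_value: float


def parse_family(subject_label: str) -> tuple[str, str, str] | None:
    """Extract (family, subfamily, class) from a CAZy subject label, or None."""
    m = _FAMILY.search(subject_label)
    if not m:
        return None
    cls, number, sub = m.group(1), m.group(2), m.group(3)
    family = f"{cls}{number}"
    subfamily = f"{family}_{sub}" if sub else ""
    return family, subfamily, cls


def filter_and_assign(
    raw_hits: pd.DataFrame, evalue_cutoff: float = EVALUE_CUTOFF
) -> list[CazymeAssignment]:
    """Top-1-per-query selection followed by the strict E-value filter.

    ``raw_hits`` needs columns genome_id, qseqid, sseqid, evalue, bitscore.
    Unparsable subject labels are dropped with a logged warning before
    best-hit selection.
    """
    rows = raw_hits.copy()
    parsed = rows["sseqid"].map(parse_family)
    bad = parsed.isna()
    if bad.any():
        for label in rows.loc[bad, "sseqid"].unique():
            log.warning("dropping hits with unparsable CAZy label %r", label)
        rows = rows[~bad]
        parsed = parsed[~bad]
    rows = rows.assign(
        family=[p[0] for p in parsed],
        subfamily=[p[1] for p in parsed],
        cazy_class=[p[2] for p in parsed],
    )
    rows = rows.sort_values(
        ["genome_id", "qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, True, False, True, True],
    )
    best = rows.drop_duplicates(subset=["genome_id", "qseqid"], keep="first")
    best = best[best["evalue"] < evalue_cutoff]
    return [
        CazymeAssignment(
            protein_id=row["qseqid"],
            genome_id=row["genome_id"],
            family=row["family"],
            subfamily=row["subfamily"],
            cazy_class=row["cazy_class"],
            e_value=float(row["evalue"]),
        )
        for _, row in best.iterrows()
    ]


def assignments_frame(assignments: list[CazymeAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome_id": a.genome_id,
                "protein_id": a.protein_id,
                "family": a.family,
                "subfamily": a.subfamily,
                "cazy_class": a.cazy_class,
                "e_value": a.e_value,
            }
            for a in assignments
        ],
        columns=["genome_id", "protein_id", "family", "subfamily", "cazy_class", "e_value"],
    )


def class_counts(
    assignments: list[CazymeAssignment], metadata: pd.DataFrame, grouping: str = "species"
) -> pd.DataFrame:
    """Long-format class totals per genome or species, with per-genome means."""
    if grouping not in ("genome", "species"):
        raise ValueError(f"unknown grouping {grouping!r}")
    frame = assignments_frame(assignments)
    species_of = dict(zip(metadata["genome_id"], metadata["species"]))
    frame["species"] = frame["genome_id"].map(species_of)
    genomes_per_species = metadata.groupby("species")["genome_id"].nunique()
    rows = []
    if grouping == "genome":
        for gid in sorted(metadata["genome_id"]):
            sub = frame[frame["genome_id"] == gid]
            for cls in CAZY_CLASSES:
                n = int((sub["cazy_class"] == cls).sum())
                rows.append({"genome_id": gid, "cazy_class": cls, "count": n,
                             "mean_per_genome": float(n)})
    else:
        for species in sorted(genomes_per_species.index):
            n_genomes = int(genomes_per_species[species])
            sub = frame[frame["species"] == species]
            for cls in CAZY_CLASSES:
                n = int((sub["cazy_class"] == cls).sum())
                rows.append(
                    {
                        "species": species,
                        "cazy_class": cls,
                        "count": n,
                        "mean_per_genome": n / n_genomes if n_genomes else float("nan"),
                    }
                )
    return pd.DataFrame(rows)


def family_prevalence(assignments: list[CazymeAssignment], metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-species % of genomes carrying >= 1 assignment of each family
    (dense over families seen anywhere; absent families get a 0% row)."""
    frame = assignments_frame(assignments)
    species_of = dict(zip(metadata["genome_id"], metadata["species"]))
    frame["species"] = frame["genome_id"].map(species_of)
    genomes_per_species = metadata.groupby("species")["genome_id"].nunique()
    families = sorted(frame["family"].unique())
    rows = []
    for species in sorted(genomes_per_species.index):
        n = int(genomes_per_species[species])
        sub = frame[frame["species"] == species]
        for family in families:
            carriers = sub[sub["family"] == family]["genome_id"].nunique()
            rows.append(
                {
                    "species": species,
                    "family": family,
                    "n_genomes": n,
                    "prevalence_pct": 100.0 * carriers / n if n else float("nan"),
                }
            )
    return pd.DataFrame(rows, columns=["species", "family", "n_genomes", "prevalence_pct"])
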