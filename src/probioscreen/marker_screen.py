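"""Regex screening of CDS annotation text against the probiotic-marker panel.

Each curated marker is a case-insensitive regular expression applied to a
subset of the ``gene``/``product``/``note`` attributes of every CDS.  Word
boundaries are encoded in the patterns themselves; the engine performs plain
substring search, so the panel TSV is the single source of matching
semantics.  A CDS may hit several markers (all hits kept), but one CDS never
yields two hits for the same marker.

The panel groups markers into the major functional categories used for the
collapsed heatmaps (stress tolerance, defense/CRISPR-Cas, carbohydrate
utilization, cell envelope/EPS, acid tolerance/energy, amino-acid metabolism,
vitamin/cofactor biosynthesis, bacteriocin production) and finer
subcategories; both levels are editable config, not code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .genome_io import ANNOTATION_FIELDS, GenomeRecord

CATEGORIES = (
    "Cold and heat stress tolerance",
    "Defense systems and CRISPR-Cas",
    "Carbohydrate utilization and transport",
    "Cell envelope and EPS biosynthesis",
    "Acid tolerance and energy metabolism",
    "Amino acid and general metabolism",
    "Vitamin and cofactor biosynthesis",
    "Bacteriocin and antimicrobial peptide production",
)

LEVELS = ("marker", "subcategory", "category")
MODES = ("presence", "count", "proportion")


class PanelError(ValueError):
    """Malformed marker panel."""


@dataclass(frozen=True)
class MarkerPattern:
    marker_id: str
    pattern: re.Pattern
    target_fields: frozenset[str]
    category: str
    subcategory: str


@dataclass(frozen=True)
class MarkerHit:
    genome_id: str
    locus_tag: str
    marker_id: str
    matched_field: str
    matched_text: str


@dataclass
class PresenceAbsenceMatrix:
    """Wide matrix of markers/subcategories/categories by genome or species."""

    values: pd.DataFrame
    mode: str
    level: str
    grouping: str
    zero_rows: list[str]


def default_panel_path() -> Path:
    return Path(str(resources.files("probioscreen").joinpath("data/marker_panel.tsv")))


def load_panel(panel_tsv: str | Path | None = None) -> list[MarkerPattern]:
    """Load and compile a marker panel TSV (columns: marker_id, pattern,
    fields, category, subcategory)."""
    path = Path(panel_tsv) if panel_tsv is not None else default_panel_path()
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"marker_id", "pattern", "fields", "category", "subcategory"}
    if not required.issubset(frame.columns):
        raise PanelError(f"panel {path} lacks columns {sorted(required - set(frame.columns))}")
    if frame.empty:
        raise PanelError(f"panel {path} is empty")
    panel: list[MarkerPattern] = []
    seen: set[str] = set()
    for idx, row in frame.iterrows():
        marker_id = row["marker_id"]
        if marker_id in seen:
            raise PanelError(f"duplicate marker_id {marker_id!r} (row {idx})")
        seen.add(marker_id)
        fields = frozenset(f.strip() for f in row["fields"].split("|"))
        unknown = fields - set(ANNOTATION_FIELDS)
        if unknown:
            raise PanelError(f"marker {marker_id!r}: unknown fields {sorted(unknown)}")
        try:
            compiled = re.compile(row["pattern"], re.IGNORECASE)
        except re.error as exc:
            raise PanelError(f"marker {marker_id!r} (row {idx}): bad regex: {exc}") from exc
        panel.append(
            MarkerPattern(
                marker_id=marker_id,
                pattern=compiled,
                target_fields=fields,
                category=row["category"],
                subcategory=row["subcategory"],
            )
        )
    return panel


def screen_genome(genome: GenomeRecord, panel: list[MarkerPattern]) -> list[MarkerHit]:
    """Emit one hit per (CDS, marker) pair whose pattern matches any target field."""
    hits: list[MarkerHit] = []
    for feat in sorted(genome.features, key=lambda f: f.locus_tag):
        for marker in panel:
            for field_name in ANNOTATION_FIELDS:  # fixed order: gene, product, note
                if field_name not in marker.target_fields:
                    continue
                text = feat.annotation_field(field_name)
                if text and marker.pattern.search(text):
                    hits.append(
                        MarkerHit(genome.genome_id, feat.locus_tag, marker.marker_id,
                                  field_name, text)
                    )
                    break  # one hit per (CDS, marker)
    return hits


def screen_cohort(genomes: list[GenomeRecord], panel: list[MarkerPattern]) -> list[MarkerHit]:
    hits: list[MarkerHit] = []
    for genome in sorted(genomes, key=lambda g: g.genome_id):
        hits.extend(screen_genome(genome, panel))
    return hits


def hits_frame(hits: list[MarkerHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome_id": h.genome_id,
                "locus_tag": h.locus_tag,
                "marker_id": h.marker_id,
                "matched_field": h.matched_field,
                "matched_text": h.matched_text,
            }
            for h in hits
        ],
        columns=["genome_id", "locus_tag", "marker_id", "matched_field", "matched_text"],
    )


def build_matrix(
    hits: list[MarkerHit],
    panel: list[MarkerPattern],
    metadata: pd.DataFrame,
    grouping: str = "species",
    level: str = "marker",
    mode: str = "count",
) -> PresenceAbsenceMatrix:
    """Aggregate hits into a wide matrix.

    ``grouping`` is ``genome`` or ``species`` (rows); ``level`` collapses the
    marker axis to subcategories or categories; ``mode`` selects any-hit
    booleans, summed counts, or per-row proportions.  Rows with zero hits
    stay in the matrix (all-zero) and are flagged in ``zero_rows``.
    """
    if grouping not in ("genome", "species"):
        raise ValueError(f"unknown grouping {grouping!r}")
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}")
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")

    label = {
        "marker": {m.marker_id: m.marker_id for m in panel},
        "subcategory": {m.marker_id: m.subcategory for m in panel},
        "category": {m.marker_id: m.category for m in panel},
    }[level]
    columns = sorted(set(label.values()))
    genome_to_group = (
        dict(zip(metadata["genome_id"], metadata["species"]))
        if grouping == "species"
        else {g: g for g in metadata["genome_id"]}
    )
    rows = sorted(set(genome_to_group.values()))

    counts = pd.DataFrame(0, index=rows, columns=columns, dtype=float)
    for h in hits:
        group = genome_to_group.get(h.genome_id)
        if group is None:
            raise KeyError(f"hit genome {h.genome_id!r} absent from metadata")
        counts.loc[group, label[h.marker_id]] += 1

    zero_rows = [r for r in rows if counts.loc[r].sum() == 0]
    if mode == "presence":
        values = counts > 0
    elif mode == "count":
        values = counts
    else:
        totals = counts.sum(axis=1).replace(0, 1.0)  # zero-hit rows stay all-zero
        values = counts.div(totals, axis=0)
    values.index.name = grouping
    return PresenceAbsenceMatrix(values=values, mode=mode, level=level,
                                 grouping=grouping, zero_rows=zero_rows)
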