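"""Safety-gene screening: AMR/VF threshold filtering and BA/hemolysin term scans.

Two alignment-based panels mirror the retention rules used for acquired
resistance and virulence screening: AMR hits are kept at >= 50% coverage and
>= 90% identity, virulence-factor (VF) hits at the stricter >= 70% coverage
and >= 90% identity; boundary values are retained.  Coverage is
query-relative (flagged in output headers because the convention is
unstated in some tools).

Two annotation-term panels flag biogenic-amine (BA) decarboxylases and
transporters (hdcA, tdc/tyrDC, odc, cadA, tyrP) and hemolysin/cytolysin
genes (hly*/cyl* symbols plus product terms), with the same matching
semantics as the marker screen.

The module reports retained hits and per-species prevalence; it deliberately
draws no safety verdict from them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .genome_io import GenomeRecord

MALFORMED = "MALFORMED"
PANEL_IDS = ("AMR", "VF", "BA", "HEMOLYSIN")


@dataclass(frozen=True)
class TermPattern:
    symbol: str
    pattern: re.Pattern
    fields: tuple[str, ...]


@dataclass
class SafetyPanel:
    panel_id: str
    detection: str  # "alignment" | "annotation_terms"
    min_coverage: float = 0.0
    min_identity: float = 0.0
    term_patterns: list[TermPattern] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.panel_id not in PANEL_IDS:
            raise ValueError(f"unknown panel {self.panel_id!r}")
        if self.detection == "alignment" and not (self.min_coverage and self.min_identity):
            raise ValueError(f"{self.panel_id}: alignment panel needs both thresholds")
        if self.detection == "annotation_terms" and not self.term_patterns:
            raise ValueError(f"{self.panel_id}: term panel needs term_patterns")


def _terms(entries: list[tuple[str, str, tuple[str, ...]]]) -> list[TermPattern]:
    return [TermPattern(sym, re.compile(rx, re.IGNORECASE), fields) for sym, rx, fields in entries]


AMR_PANEL = SafetyPanel("AMR", "alignment", min_coverage=0.50, min_identity=90.0)
VF_PANEL = SafetyPanel("VF", "alignment", min_coverage=0.70, min_identity=90.0)

BA_PANEL = SafetyPanel(
    "BA",
    "annotation_terms",
    term_patterns=_terms(
        [
            ("hdcA", r"\bhdc[AB]?\b|histidine decarboxylase", ("gene", "product")),
            ("tdc", r"\b(tdc|tyrDC)\b|tyrosine decarboxylase", ("gene", "product")),
            ("odc", r"\bodc\w*\b|ornithine decarboxylase", ("gene", "product")),
            ("cadA", r"\bcadA\b|lysine decarboxylase", ("gene", "product")),
            ("tyrP", r"\btyrP\b|tyrosine permease", ("gene", "product")),
        ]
    ),
)

HEMOLYSIN_PANEL = SafetyPanel(
    "HEMOLYSIN",
    "annotation_terms",
    term_patterns=_terms(
        [
            ("hly", r"\bhly\w*", ("gene",)),
            ("cyl", r"\bcyl\w*", ("gene",)),
            ("hemolysin", r"\bhemolysin\b", ("product",)),
            ("cytolysin", r"\bcytolysin\b", ("product",)),
        ]
    ),
)

DEFAULT_PANELS = {p.panel_id: p for p in (AMR_PANEL, VF_PANEL, BA_PANEL, HEMOLYSIN_PANEL)}

HIT_COLUMNS = [
    "genome_id", "panel_id", "gene", "locus", "coverage", "identity", "retained", "reason"
]


def filter_alignment_hits(raw_hits: pd.DataFrame, panel: SafetyPanel) -> pd.DataFrame:
    """Apply the panel's retention thresholds to tabular alignment hits.

    ``raw_hits`` needs columns genome_id, gene, coverage (query-relative
    fraction), identity (percent); a ``locus`` column is carried through when
    present.  Rows missing coverage or identity are rejected with reason
    MALFORMED rather than dropped silently.
    """
    if panel.detection != "alignment":
        raise ValueError(f"{panel.panel_id} is not an alignment panel")
    rows = []
    for _, row in raw_hits.iterrows():
        coverage = row.get("coverage")
        identity = row.get("identity")
        malformed = pd.isna(coverage) or pd.isna(identity)
        retained = (
            not malformed
            and float(coverage) >= panel.min_coverage
            and float(identity) >= panel.min_identity
        )
        rows.append(
            {
                "genome_id": row["genome_id"],
                "panel_id": panel.panel_id,
                "gene": row["gene"],
                "locus": row.get("locus", ""),
                "coverage": coverage,
                "identity": identity,
                "retained": retained,
                "reason": MALFORMED if malformed else "",
            }
        )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def screen_terms(genome: GenomeRecord, panel: SafetyPanel) -> pd.DataFrame:
    """Scan annotation text for the panel's term patterns (one hit per
    CDS × symbol)."""
    if panel.detection != "annotation_terms":
        raise ValueError(f"{panel.panel_id} is not a term panel")
    rows = []
    for feat in sorted(genome.features, key=lambda f: f.locus_tag):
        for term in panel.term_patterns:
            for field_name in term.fields:
                text = feat.annotation_field(field_name)
                if text and term.pattern.search(text):
                    rows.append(
                        {
                            "genome_id": genome.genome_id,
                            "panel_id": panel.panel_id,
                            "gene": term.symbol,
                            "locus": feat.locus_tag,
                            "coverage": float("nan"),
                            "identity": float("nan"),
                            "retained": True,
                            "reason": "",
                        }
                    )
                    break
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def safety_profile(hits: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-species prevalence of each retained gene: % of the species' genomes
    carrying >= 1 retained hit (copy number ignored).  Long format; genes with
    zero retained hits in a species keep their 0% row when the gene was
    retained anywhere."""
    species_of = dict(zip(metadata["genome_id"], metadata["species"]))
    genomes_per_species = metadata.groupby("species")["genome_id"].nunique()
    retained = hits[hits["retained"]].copy()
    if retained.empty:
        return pd.DataFrame(columns=["species", "panel_id", "gene", "n_genomes", "prevalence_pct"])
    retained["species"] = retained["genome_id"].map(species_of)
    rows = []
    genes = retained[["panel_id", "gene"]].drop_duplicates()
    for species in sorted(genomes_per_species.index):
        n = int(genomes_per_species[species])
        sub = retained[retained["species"] == species]
        for _, g in genes.sort_values(["panel_id", "gene"]).iterrows():
            carriers = sub[(sub["panel_id"] == g["panel_id"]) & (sub["gene"] == g["gene"])][
                "genome_id"
            ].nunique()
            rows.append(
                {
                    "species": species,
                    "panel_id": g["panel_id"],
                    "gene": g["gene"],
                    "n_genomes": n,
                    "prevalence_pct": 100.0 * carriers / n,
                }
            )
    return pd.DataFrame(rows)
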