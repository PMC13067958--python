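import numpy as np
import pandas as pd
import pytest

from probioscreen.bacteriocin_profile import (
    SUBCLASSES,
    assign_subclass,
    assign_subclasses,
    consolidate,
    load_subclass_table,
    loci_frame,
    reference_species_summary,
    species_summary,
    subclass_composition,
    tier,
)

from oracles import overlap_components


def _hits(rows):
    return pd.DataFrame(
        rows, columns=["genome_id", "contig_id", "start", "end", "bacteriocin_name", "role", "score"]
    )


class TestConsolidate:
    def test_near_duplicate_structural_hits_merge(self):
        hits = _hits(
            [
                ("g1", "c1", 100, 400, "Plantaricin E", "structural", 90.0),
                ("g1", "c1", 150, 420, "Plantaricin E", "structural", 80.0),
            ]
        )
        loci = consolidate(hits)
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end, loci[0].score) == (100, 420, 90.0)

    def test_adjacent_different_names_stay_separate(self):
        hits = _hits(
            [
                ("g1", "c1", 100, 400, "Plantaricin E", "structural", 90.0),
                ("g1", "c1", 401, 700, "Plantaricin F", "structural", 85.0),
            ]
        )
        assert len(consolidate(hits)) == 2

    def test_non_structural_roles_never_create_loci(self):
        hits = _hits(
            [
                ("g1", "c1", 100, 400, "Plantaricin E", "immunity", 50.0),
                ("g1", "c1", 500, 900, "Plantaricin E", "transport", 50.0),
            ]
        )
        assert consolidate(hits) == []

    def test_matches_all_pairs_overlap_oracle(self, rng):
        """10 raw hits with duplicated spans reduce to the component count of
        a brute-force pairwise overlap graph."""
        spans = []
        base = 100
        for _ in range(6):
            length = int(rng.integers(120, 400))
            spans.append((base, base + length))
            base += length + int(rng.integers(300, 600))
        duplicated = spans + [
            (s + 10, e + 10) for s, e in spans[:4]  # 4 near-duplicates
        ]
        hits = _hits(
            [("g1", "c1", s, e, "Pediocin", "structural", 50.0) for s, e in duplicated]
        )
        expected = len(overlap_components(duplicated))
        loci = consolidate(hits)
        assert len(loci) == expected == 6

    def test_idempotent(self, rng):
        spans = [(100, 400), (350, 600), (900, 1200), (905, 1190), (2000, 2100)]
        hits = _hits(
            [("g1", "c1", s, e, "Pediocin", "structural", float(i)) for i, (s, e) in enumerate(spans)]
        )
        once = consolidate(hits)
        again = consolidate(
            pd.DataFrame(
                [
                    {
                        "genome_id": l.genome_id, "contig_id": l.contig_id,
                        "start": l.start, "end": l.end,
                        "bacteriocin_name": l.bacteriocin_name,
                        "role": "structural", "score": l.score,
                    }
                    for l in once
                ]
            )
        )
        assert [(l.start, l.end, l.score) for l in again] == [
            (l.start, l.end, l.score) for l in once
        ]


class TestSubclasses:
    def test_curated_assignments(self):
        table = load_subclass_table()
        assert assign_subclass("Nisin A", table) == "I"
        assert assign_subclass("Pediocin", table) == "IIa"
        assert assign_subclass("Enterolysin A", table) == "III"

    def test_normalization_and_unmapped_fallback(self):
        table = load_subclass_table()
        assert assign_subclass("  enterolysin   a ", table) == "III"
        assert assign_subclass("Unheard-of peptide", table) == "other"


class TestSpeciesSummary:
    def _metadata(self, n, species="A"):
        return pd.DataFrame(
            {"genome_id": [f"g{i}" for i in range(n)], "species": species}
        )

    def _locus(self, genome_id, name, subclass="IIb", start=100):
        hits = _hits([(genome_id, "c1", start, start + 200, name, "structural", 50.0)])
        return assign_subclasses(consolidate(hits), load_subclass_table())[0]

    def test_pct_with_any(self):
        loci = [self._locus("g0", "Plantaricin E"), self._locus("g1", "Plantaricin E")]
        summary = species_summary(loci, self._metadata(4))
        assert summary["pct_with_any"].iloc[0] == 50.0

    def test_empty_species_row(self):
        summary = species_summary([], self._metadata(23, species="L. aviarius"))
        row = summary.iloc[0]
        assert (row["total_abundance"], row["unique_types"], row["dominant"]) == (0, 0, "None")
        assert row["notes"] == "Low/none"

    def test_dominant_top3_with_lexicographic_ties(self):
        loci = (
            [self._locus("g0", "Plantaricin F", start=100 + 500 * i) for i in range(3)]
            + [self._locus("g1", "Plantaricin E", start=100 + 500 * i) for i in range(2)]
            + [self._locus("g2", "Pediocin"), self._locus("g2", "Nisin A", start=900)]
        )
        summary = species_summary(loci, self._metadata(3))
        assert summary["dominant"].iloc[0] == "Plantaricin F; Plantaricin E; Nisin A"

    def test_tier_rule_reproduces_reference_table(self):
        """The inferred strong/moderate/low thresholds reproduce the printed
        producer label for every row of the published species summary."""
        reference = reference_species_summary()
        assert len(reference) == 35
        for _, row in reference.iterrows():
            assert tier(int(row["total_abundance"])) == row["notes"], row["species"]

    def test_abundance_conservation_on_cohort(self, cohort):
        loci = assign_subclasses(
            consolidate(cohort.bacteriocin_hits), load_subclass_table()
        )
        summary = species_summary(loci, cohort.metadata)
        assert summary["total_abundance"].sum() == len(loci)
        # consolidated loci equal the planted loci one-to-one
        assert len(loci) == len(cohort.manifest.bacteriocins)


class TestComposition:
    def test_proportions_and_integer_recovery(self):
        metadata = pd.DataFrame({"genome_id": ["g0"], "species": ["A"]})
        hits = _hits(
            [("g0", "c1", 100 + 500 * i, 300 + 500 * i, name, "structural", 50.0)
             for i, name in enumerate(
                 ["Plantaricin E", "Plantaricin F", "Plantaricin J", "Enterolysin A"]
             )]
        )
        loci = assign_subclasses(consolidate(hits), load_subclass_table())
        composition = subclass_composition(loci, metadata).set_index("species")
        assert composition.loc["A", "IIb"] == pytest.approx(0.75)
        assert composition.loc["A", "III"] == pytest.approx(0.25)
        row = composition.loc["A", list(SUBCLASSES)]
        assert row.sum() == pytest.approx(1.0, abs=1e-9)
        counts = row * composition.loc["A", "n_loci"]
        assert all(abs(c - round(c)) < 1e-9 for c in counts)

    def test_species_without_loci_flagged(self):
        metadata = pd.DataFrame({"genome_id": ["g0"], "species": ["A"]})
        composition = subclass_composition([], metadata)
        assert composition["flag"].iloc[0] == "NO_LOCI"
        assert composition[list(SUBCLASSES)].iloc[0].sum() == 0.0

    def test_cohort_composition_matches_planted_frequencies(self, cohort):
        loci = assign_subclasses(
            consolidate(cohort.bacteriocin_hits), load_subclass_table()
        )
        composition = subclass_composition(loci, cohort.metadata).set_index("species")
        manifest = pd.DataFrame(cohort.manifest.bacteriocins)
        species_of = dict(zip(cohort.metadata["genome_id"], cohort.metadata["species"]))
        manifest["species"] = manifest["genome_id"].map(species_of)
        for species, sub in manifest.groupby("species"):
            planted = sub["subclass"].value_counts(normalize=True)
            for subclass in SUBCLASSES:
                assert composition.loc[species, subclass] == pytest.approx(
                    planted.get(subclass, 0.0), abs=1e-9
                )
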