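import numpy as np
import pandas as pd
import pytest

from probioscreen import marker_screen as ms
from probioscreen import synthetic_genomes as sg
from probioscreen.genome_io import CdsFeature, GenomeRecord
from probioscreen.marker_screen import PanelError, build_matrix, load_panel, screen_genome


def _genome(features):
    contig = "A" * 2000
    feats = [
        CdsFeature(f"t{i}", "c1", 1 + 10 * i, 9 + 10 * i, "+", "M",
                   gene_name=g, product=p, note=n)
        for i, (g, p, n) in enumerate(features)
    ]
    return GenomeRecord(genome_id="g1", contigs={"c1": contig}, features=feats)


class TestLoadPanel:
    def test_default_panel_compiles_with_known_taxonomy(self, panel):
        assert {m.category for m in panel} <= set(ms.CATEGORIES)
        assert len({m.marker_id for m in panel}) == len(panel)

    def test_duplicate_marker_rejected(self, tmp_path):
        path = tmp_path / "panel.tsv"
        path.write_text(
            "marker_id\tpattern\tfields\tcategory\tsubcategory\n"
            "a\tx\tgene\tC\tS\na\ty\tgene\tC\tS\n"
        )
        with pytest.raises(PanelError, match="duplicate"):
            load_panel(path)

    def test_malformed_regex_names_the_row(self, tmp_path):
        path = tmp_path / "panel.tsv"
        path.write_text(
            "marker_id\tpattern\tfields\tcategory\tsubcategory\nbad\t(\tgene\tC\tS\n"
        )
        with pytest.raises(PanelError, match="bad"):
            load_panel(path)

    def test_empty_panel_rejected(self, tmp_path):
        path = tmp_path / "panel.tsv"
        path.write_text("marker_id\tpattern\tfields\tcategory\tsubcategory\n")
        with pytest.raises(PanelError, match="empty"):
            load_panel(path)


class TestScreenGenome:
    def test_product_match_is_case_insensitive_with_taxonomy(self, panel):
        genome = _genome([(None, "Glutamate decarboxylase beta", None)])
        hits = screen_genome(genome, panel)
        assert [h.marker_id for h in hits] == ["gadB"]
        (pattern,) = [m for m in panel if m.marker_id == "gadB"]
        assert pattern.subcategory == "GABA production"
        assert hits[0].matched_field == "product"

    def test_hypothetical_protein_yields_no_hits(self, panel):
        genome = _genome([(None, "hypothetical protein", None)])
        assert screen_genome(genome, panel) == []

    def test_planted_markers_and_decoys_all_hit(self, panel, rng):
        """5 exact plants + 3 decoys -> exactly 8 hits, one per planted CDS."""
        genome = GenomeRecord(genome_id="g1", contigs={"c1": ""})
        planted = []
        for marker_id in ("bsh", "gadB", "srtA", "dnaK", "clpP"):
            _, e = sg.plant_marker(genome, sg.reference_protein(marker_id), "exact",
                                   rng, marker_id, 0.4)
            planted.append((e["locus_tag"], marker_id))
        for marker_id in ("bsh", "gadB", "srtA"):
            _, e = sg.plant_marker(genome, sg.reference_protein(marker_id), "decoy",
                                   rng, marker_id, 0.4)
            planted.append((e["locus_tag"], marker_id))
        hits = screen_genome(genome, panel)
        assert {(h.locus_tag, h.marker_id) for h in hits} == set(planted)
        assert len(hits) == 8

    def test_output_independent_of_feature_order(self, panel, rng):
        genome = GenomeRecord(genome_id="g1", contigs={"c1": ""})
        for marker_id in ("bsh", "pts", "lac", "cas"):
            sg.plant_marker(genome, sg.reference_protein(marker_id), "exact",
                            rng, marker_id, 0.4)
        hits_fwd = screen_genome(genome, panel)
        genome.features.reverse()
        hits_rev = screen_genome(genome, panel)
        assert hits_fwd == hits_rev

    def test_lexicon_products_match_exactly_their_own_marker(self, panel):
        """The planting lexicon and the panel are one-to-one: each planted
        gene symbol + product triggers its own marker and no other."""
        for marker_id, (gene, product) in sg.MARKER_LEXICON.items():
            genome = _genome([(gene, product, None)])
            hits = screen_genome(genome, panel)
            assert {h.marker_id for h in hits} == {marker_id}, (marker_id, hits)

    def test_exact_plants_in_cohort_all_recovered(self, cohort, cohort_hits):
        planted = {
            (m["genome_id"], m["locus_tag"], m["marker_id"])
            for m in cohort.manifest.markers
        }
        found = {(h.genome_id, h.locus_tag, h.marker_id) for h in cohort_hits}
        assert planted <= found


class TestBuildMatrix:
    def _simple_hits(self, panel):
        genome_a = _genome([("bsh", None, None)])
        genome_a.genome_id = "A"
        hits = screen_genome(genome_a, panel)
        metadata = pd.DataFrame(
            {"genome_id": ["A", "B"], "species": ["spA", "spB"]}
        )
        return hits, metadata

    def test_presence_mode_flags_zero_rows(self, panel):
        hits, metadata = self._simple_hits(panel)
        matrix = build_matrix(hits, panel, metadata, grouping="genome",
                              level="marker", mode="presence")
        assert bool(matrix.values.loc["A", "bsh"]) is True
        assert not matrix.values.loc["B"].any()
        assert matrix.zero_rows == ["B"]

    def test_proportion_rows_normalised(self, panel):
        hits, metadata = self._simple_hits(panel)
        # stress 30% / carbohydrate 70% style check with synthetic counts
        matrix = build_matrix(hits, panel, metadata, grouping="genome",
                              level="marker", mode="proportion")
        assert matrix.values.loc["A"].sum() == pytest.approx(1.0, abs=1e-9)
        assert matrix.values.loc["B"].sum() == 0.0

    def test_count_column_sums_match_raw_hits(self, cohort, cohort_hits, panel):
        matrix = build_matrix(cohort_hits, panel, cohort.metadata,
                              grouping="species", level="marker", mode="count")
        recount = pd.Series(
            [h.marker_id for h in cohort_hits], dtype="object"
        ).value_counts()
        for marker_id in matrix.values.columns:
            assert matrix.values[marker_id].sum() == recount.get(marker_id, 0)

    def test_subcategory_matrix_collapses_to_category_matrix(self, cohort, cohort_hits, panel):
        sub = build_matrix(cohort_hits, panel, cohort.metadata, "species",
                           "subcategory", "count").values
        cat = build_matrix(cohort_hits, panel, cohort.metadata, "species",
                           "category", "count").values
        collapse = {}
        for m in panel:
            collapse.setdefault(m.category, set()).add(m.subcategory)
        for category, subcategories in collapse.items():
            collapsed = sub[[s for s in subcategories if s in sub.columns]].sum(axis=1)
            pd.testing.assert_series_equal(collapsed, cat[category], check_names=False)

    def test_unknown_level_rejected(self, panel):
        hits, metadata = self._simple_hits(panel)
        with pytest.raises(ValueError):
            build_matrix(hits, panel, metadata, level="operon")
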