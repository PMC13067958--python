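import math

import numpy as np
import pytest

from probioscreen import synthetic_genomes as sg
from probioscreen.genome_io import GenomeRecord
from probioscreen.marker_screen import MarkerHit
from probioscreen.sequence_confirmation import (
    _ALIGNER,
    AlignmentResult,
    KA_K,
    KA_LAMBDA,
    NO_REFERENCE,
    ReferenceProtein,
    concordance,
    confirm_hit,
    identity_vs_query,
    local_align,
    passes_thresholds,
)

from oracles import smith_waterman_score

AA = sg.AMINO_ACIDS


def _random_peptide(rng, low=5, high=30):
    return "".join(rng.choice(list(AA), size=int(rng.integers(low, high + 1))))


class TestLocalAlign:
    def test_identical_sequences_full_identity_and_coverage(self, rng):
        seq = _random_peptide(rng, 100, 100)
        result = local_align(seq, seq)
        assert result.percent_identity == 100.0
        assert result.query_coverage == 1.0

    def test_classic_pair_matches_dp_oracle(self):
        assert local_align("HEAGAWGHEE", "PAWHEAE").raw_score == smith_waterman_score(
            "HEAGAWGHEE", "PAWHEAE"
        )

    def test_score_matches_brute_force_oracle_on_random_pairs(self, rng):
        """>= 200 random peptide pairs (<= 30 aa) against an independent
        affine-gap dynamic program."""
        for _ in range(200):
            a, b = _random_peptide(rng), _random_peptide(rng)
            assert local_align(a, b).raw_score == smith_waterman_score(a, b), (a, b)

    def test_score_symmetry(self, rng):
        for _ in range(25):
            a, b = _random_peptide(rng), _random_peptide(rng)
            assert local_align(a, b).raw_score == local_align(b, a).raw_score

    def test_identity_and_coverage_recomputed_from_traceback(self, rng):
        """The reported identity/coverage agree with values re-derived from
        the raw aligned blocks of the optimal alignment."""
        for _ in range(50):
            a, b = _random_peptide(rng, 10, 30), _random_peptide(rng, 10, 30)
            result = local_align(a, b)
            alignment = _ALIGNER.align(a, b)[0]
            qblocks, sblocks = alignment.aligned
            identities = gap_columns = aligned_pairs = 0
            for (qs, qe), (ss, se) in zip(qblocks, sblocks):
                aligned_pairs += qe - qs
                identities += sum(a[qs + k] == b[ss + k] for k in range(qe - qs))
            for i in range(1, len(qblocks)):
                gap_columns += qblocks[i][0] - qblocks[i - 1][1]
                gap_columns += sblocks[i][0] - sblocks[i - 1][1]
            expected_identity = 100.0 * identities / (aligned_pairs + gap_columns)
            expected_coverage = (qblocks[-1][1] - qblocks[0][0]) / len(a)
            assert result.percent_identity == pytest.approx(expected_identity)
            assert result.query_coverage == pytest.approx(expected_coverage)

    def test_half_aligned_query_coverage(self):
        query = "".join("ACDEFGHIKL" for _ in range(10))  # 100 aa
        subject = query[:50]
        assert local_align(query, subject).query_coverage == pytest.approx(0.5)

    def test_evalue_follows_karlin_altschul_form(self):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 5
        result = local_align(seq, seq, search_space=1000)
        expected = KA_K * len(seq) * 1000 * math.exp(-KA_LAMBDA * result.raw_score)
        assert result.e_value == pytest.approx(expected)

    def test_invalid_residues_rejected(self):
        with pytest.raises(ValueError):
            local_align("MA*", "MA")
        with pytest.raises(ValueError):
            local_align("", "MA")


class TestThresholds:
    @pytest.mark.parametrize(
        "identity, coverage, evalue, expected",
        [
            (40.0, 0.70, 1e-5, True),    # all three at their boundaries
            (39.5, 0.95, 1e-30, False),  # identity just below
            (80.0, 0.69, 1e-30, False),  # coverage just below
            (80.0, 0.90, 2e-5, False),   # e-value just above
        ],
    )
    def test_boundary_semantics(self, identity, coverage, evalue, expected):
        result = AlignmentResult("q", "s", identity, coverage, 100.0, evalue)
        assert passes_thresholds(result) is expected


def _plant_and_hit(rng, mode, marker_id="dnaK"):
    genome = GenomeRecord(genome_id="g", contigs={"c1": ""})
    _, entry = sg.plant_marker(
        genome, sg.reference_protein(marker_id), mode, rng, marker_id, 0.4
    )
    hit = MarkerHit("g", entry["locus_tag"], marker_id, "product", "x")
    return genome, hit


class TestConfirmHit:
    def test_exact_plants_confirm(self, rng, validation_reference_db):
        for _ in range(5):
            genome, hit = _plant_and_hit(rng, "exact")
            assert confirm_hit(hit, genome, validation_reference_db).confirmed

    def test_divergence_bracket_60_confirms_20_does_not(self, rng, validation_reference_db):
        for _ in range(10):
            genome, hit = _plant_and_hit(rng, "diverged:60")
            assert confirm_hit(hit, genome, validation_reference_db).confirmed
            genome, hit = _plant_and_hit(rng, "diverged:20")
            assert not confirm_hit(hit, genome, validation_reference_db).confirmed

    def test_decoys_rejected_and_distant_from_reference(self, rng, validation_reference_db):
        for _ in range(10):
            genome, hit = _plant_and_hit(rng, "decoy")
            outcome = confirm_hit(hit, genome, validation_reference_db)
            assert not outcome.confirmed
            decoy = genome.feature(hit.locus_tag).translation
            assert identity_vs_query(decoy, sg.reference_protein("dnaK")) < 30.0

    def test_missing_reference_marks_outcome(self, rng):
        genome, hit = _plant_and_hit(rng, "exact")
        outcome = confirm_hit(hit, genome, {})
        assert not outcome.confirmed
        assert outcome.reason == NO_REFERENCE

    def test_best_reference_chosen_by_score_then_accession(self, rng):
        reference = sg.reference_protein("dnaK")
        genome, hit = _plant_and_hit(rng, "exact")
        db = {
            "dnaK": [
                ReferenceProtein("dnaK", "B_FAR", sg.random_protein(rng, 180)),
                ReferenceProtein("dnaK", "A_TRUE", reference),
            ]
        }
        outcome = confirm_hit(hit, genome, db)
        assert outcome.best.subject_id == "A_TRUE"


class TestConcordance:
    def test_simple_ratio(self, rng, validation_reference_db):
        outcomes = []
        for mode in ["exact"] * 3 + ["decoy"]:
            genome, hit = _plant_and_hit(rng, mode)
            outcomes.append(confirm_hit(hit, genome, validation_reference_db))
        table = concordance(outcomes)
        row = table[table["marker_id"] == "dnaK"].iloc[0]
        assert (row["n_candidates"], row["n_confirmed"]) == (4, 3)
        assert row["concordance_pct"] == pytest.approx(75.0)

    def test_cohort_concordance_matches_manifest_ratios(self, cohort, validation_outcomes):
        """Per validation marker the concordance equals the planted
        confirmed/total ratio from the ground-truth manifest."""
        table = concordance(validation_outcomes).set_index("marker_id")
        confirmed_modes = {"exact"}
        for marker_id in table.index:
            planted = [m for m in cohort.manifest.markers if m["marker_id"] == marker_id]
            expected_confirmed = sum(
                1 for m in planted
                if m["mode"] in confirmed_modes or m["mode"] == "diverged:60"
            )
            assert table.loc[marker_id, "n_candidates"] == len(planted)
            assert table.loc[marker_id, "n_confirmed"] == expected_confirmed
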