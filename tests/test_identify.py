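"""Identification tests: motif match scoring, permutation E-values and
the redundancy/completeness filters."""

from __future__ import annotations

import random

import numpy as np
import pytest

import famscan
from famscan.identify import (
    EVALUE_THRESHOLD,
    empirical_evalue,
    family_score,
    filter_candidates,
    match_fraction,
    null_score_distribution,
    scan_protein,
)
from famscan.models import AMINO_ACIDS, MotifDefinition, ProteinRecord
from famscan.reference import MOTIFS


class TestMatchFraction:
    def test_resolved_consensus_scores_one(self):
        motif = MotifDefinition(1, "ACDEFG")
        assert match_fraction("ACDEFG", motif) == 1.0

    @pytest.mark.parametrize("window", ["IAYAAA", "LAYAAA"])
    def test_ambiguity_letter_accepts_both_residues(self, window):
        motif = MotifDefinition(1, "JAYAAA")
        assert match_fraction(window, motif) == 1.0
        assert match_fraction("VAYAAA", motif) == pytest.approx(5 / 6)

    def test_j_matches_isoleucine_and_leucine_fully(self):
        motif = MotifDefinition(1, "JAYJAY")
        assert match_fraction("IAYLAY", motif) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="width"):
            match_fraction("ACD", MotifDefinition(1, "ACDEFG"))

    def test_random_window_expectation_matches_closed_form(self):
        motif = next(m for m in MOTIFS if m.index == 7)
        expected = np.mean(
            [
                1.0 if c == "X" else (2 / 20 if c in "BZJ" else 1 / 20)
                for c in motif.consensus
            ]
        )
        rng = random.Random(0)
        draws = [
            match_fraction(
                "".join(rng.choice(AMINO_ACIDS) for _ in range(motif.width)), motif
            )
            for _ in range(400)
        ]
        assert np.mean(draws) == pytest.approx(expected, abs=0.01)


class TestScanProtein:
    def test_scaffold_yields_ten_perfect_hits(self):
        scaffold = famscan.build_scaffold(MOTIFS, seed=1)
        hits = scan_protein(scaffold, MOTIFS)
        assert [h.motif_index for h in hits] == [m.index for m in MOTIFS]
        assert all(h.fraction == 1.0 for h in hits)

    def test_hit_start_is_one_based_and_in_bounds(self):
        scaffold = famscan.build_scaffold(MOTIFS, seed=1)
        for hit, motif in zip(scan_protein(scaffold, MOTIFS), MOTIFS):
            assert 1 <= hit.start
            assert hit.start + motif.width - 1 <= len(scaffold.sequence)
            window = scaffold.sequence[hit.start - 1 : hit.start - 1 + motif.width]
            assert match_fraction(window, motif) == hit.fraction

    def test_truncated_decoy_lacks_its_excised_core_motif(self, bundle, scan_reports):
        by_id = {r.protein_id: r for r in scan_reports}
        assert not by_id["StHsp70-17_frag"].hits[1].present
        assert not by_id["StHsp70-12_frag"].hits[3].present
        assert not by_id["StHsp70-9_frag"].hits[4].present

    def test_planted_motif7_loss_detected(self, scan_reports):
        by_id = {r.protein_id: r for r in scan_reports}
        assert not by_id["StHsp70-6"].hits[7].present
        assert not by_id["StHsp70-14"].hits[8].present

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            scan_protein(ProteinRecord("x", ""), MOTIFS)


class TestFamilyScore:
    def test_perfect_member_scores_one(self):
        scaffold = famscan.build_scaffold(MOTIFS, seed=2)
        assert family_score(scan_protein(scaffold, MOTIFS)) == 1.0

    def test_score_monotone_as_window_mutates_toward_consensus(self):
        motif = next(m for m in MOTIFS if m.index == 1)
        base = "A" * motif.width
        target = motif.consensus.replace("J", "I").replace("B", "D").replace(
            "Z", "E").replace("X", "A")
        prev = -1.0
        for k in (0, 10, 25, 50):
            window = target[:k] + base[k:]
            frac = match_fraction(window, motif)
            assert frac >= prev
            prev = frac


class TestEmpiricalEvalue:
    def test_score_above_all_nulls_hits_floor(self):
        proteome = [ProteinRecord(f"p{i}", "ACDEFGHIKLMNPQRSTVWY" * 5) for i in range(25)]
        null = np.linspace(0.0, 0.5, 999)
        ev = empirical_evalue(1.0, proteome, MOTIFS, null_scores=null)
        assert ev == pytest.approx(25 / 1000)

    def test_minimum_score_returns_database_size(self):
        proteome = [ProteinRecord(f"p{i}", "A" * 100) for i in range(25)]
        null = np.linspace(0.0, 0.5, 999)
        assert empirical_evalue(0.0, proteome, MOTIFS, null_scores=null) == 25.0

    def test_monotone_non_increasing_in_score(self):
        proteome = [ProteinRecord(f"p{i}", "A" * 100) for i in range(10)]
        null = np.linspace(0.0, 1.0, 99)
        evs = [
            empirical_evalue(s, proteome, MOTIFS, null_scores=null)
            for s in (0.0, 0.2, 0.4, 0.8, 1.0)
        ]
        assert all(a >= b for a, b in zip(evs, evs[1:]))

    def test_null_fraction_below_alpha_bounded(self):
        """Under the all-shuffled null, P(E < alpha) <= alpha / N_db."""
        rng = np.random.default_rng(0)
        proteome = [
            ProteinRecord(f"p{i}", "".join(rng.choice(list(AMINO_ACIDS), 300)))
            for i in range(12)
        ]
        null = null_score_distribution(proteome, MOTIFS, n_shuffles=199, seed=1)
        alpha = 2.0
        hits = 0
        draws = null_score_distribution(proteome, MOTIFS, n_shuffles=100, seed=2)
        for s in draws:
            if empirical_evalue(float(s), proteome, MOTIFS, null_scores=null) < alpha:
                hits += 1
        assert hits / len(draws) <= 1.5 * alpha / len(proteome)


class TestFilterCandidates:
    def test_default_proteome_gives_25_raw_and_20_accepted(self, bundle, scan_reports):
        raw = [r for r in scan_reports if r.evalue < EVALUE_THRESHOLD]
        assert len(raw) == 25
        accepted = filter_candidates(
            scan_reports, bundle.proteins, {g.id: g for g in bundle.genes}
        )
        assert len(accepted) == 20
        assert {r.protein_id for r in accepted} == bundle.truth.family_members

    def test_identical_sequences_keep_exactly_one(self):
        seq = famscan.build_scaffold(MOTIFS, seed=5).sequence
        proteome = [ProteinRecord("dup_b", seq), ProteinRecord("dup_a", seq)]
        reports = famscan.scan_proteome(proteome, MOTIFS, n_shuffles=49, seed=1)
        accepted = filter_candidates(reports, proteome, evalue_threshold=3.0)
        assert [r.protein_id for r in accepted] == ["dup_a"]  # smaller id wins

    def test_candidate_missing_core_motif_rejected_incomplete(self, bundle, scan_reports):
        by_id = {r.protein_id: r for r in scan_reports}
        filter_candidates(scan_reports, bundle.proteins)
        assert by_id["StHsp70-12_frag"].incomplete
        assert by_id["StHsp70-12_frag"].verdict == "reject"

    def test_decisions_invariant_under_input_order(self, bundle, scan_reports):
        forward = filter_candidates(list(scan_reports), bundle.proteins)
        backward = filter_candidates(list(scan_reports)[::-1], bundle.proteins)
        assert [r.protein_id for r in forward] == [r.protein_id for r in backward]

    def test_zero_decoys_recovers_planted_family_exactly(self):
        cfg = famscan.GeneratorConfig(seed=8, n_decoys=0, n_background=10)
        bundle = famscan.generate(cfg)
        # small proteome: keep the E-value floor N_db/(n_shuffles+1) below
        # the acceptance threshold
        reports = famscan.scan_proteome(bundle.proteins, MOTIFS, n_shuffles=499, seed=2)
        accepted = filter_candidates(
            reports, bundle.proteins, {g.id: g for g in bundle.genes}
        )
        assert {r.protein_id for r in accepted} == bundle.truth.family_members
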