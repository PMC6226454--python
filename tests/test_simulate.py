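"""Generator tests: scaffold assembly, family evolution, genome placement
and the planted expression/CT structure."""

from __future__ import annotations


import numpy as np
import pytest

import famscan
from famscan import io
from famscan.models import MotifDefinition
from famscan.reference import (
    FAMILY_TABLE,
    MOTIF_LOSSES,
    MOTIFS,
    NARRATIVE_INTRONLESS,
    TISSUES,
)
from famscan.simulate import (
    GeneratorConfig,
    _scaffold_segments,
    build_scaffold,
    evolve_family,
    simulate_ct,
    simulate_expression,
    translate,
)


class TestScaffold:
    def test_zero_linkers_length_is_sum_of_widths(self):
        scaffold = build_scaffold(MOTIFS, seed=0, linker_length_range=(0, 0))
        assert len(scaffold.sequence) == sum(m.width for m in MOTIFS)

    def test_deterministic_for_fixed_seed(self):
        a = build_scaffold(MOTIFS, seed=5)
        b = build_scaffold(MOTIFS, seed=5)
        assert a.sequence == b.sequence
        assert a.sequence != build_scaffold(MOTIFS, seed=6).sequence

    def test_all_motifs_present_at_full_match(self):
        scaffold = build_scaffold(MOTIFS, seed=3)
        hits = famscan.scan_protein(scaffold, MOTIFS)
        assert len(hits) == 10
        assert all(h.present and h.fraction == 1.0 for h in hits)

    def test_missing_motif_reported_by_index(self):
        with pytest.raises(ValueError, match=r"\[6\]"):
            build_scaffold(tuple(m for m in MOTIFS if m.index != 6), seed=0)

    def test_default_length_within_published_family_range(self):
        scaffold = build_scaffold(MOTIFS, seed=11)
        assert 486 <= len(scaffold.sequence) <= 890


class TestEvolveFamily:
    def test_zero_rates_leave_motifs_identical_to_scaffold(self):
        cfg = GeneratorConfig(
            seed=2, substitution_rate_within=0.0, substitution_rate_between=0.0
        )
        segments = _scaffold_segments(MOTIFS, cfg.seed, cfg.linker_length_range,
                                      cfg.motif_order)
        scaffold_motifs = {
            s.motif_index: "".join(s.residues) for s in segments if s.kind == "motif"
        }
        for member in evolve_family(segments, cfg):
            lost = MOTIF_LOSSES.get(member.name, ())
            for seg in member.segments:
                if seg.kind == "motif":
                    assert seg.motif_index not in lost
                    assert "".join(seg.residues) == scaffold_motifs[seg.motif_index]

    def test_member_lengths_match_curated_table(self, config):
        segments = _scaffold_segments(MOTIFS, config.seed, config.linker_length_range,
                                      config.motif_order)
        lengths = {m.name: len(m.sequence) for m in evolve_family(segments, config)}
        for row in FAMILY_TABLE:
            assert lengths[row.name] == row.length_aa
        assert max(lengths.values()) == 890
        assert min(lengths.values()) == 486

    def test_planted_motif_losses_removed(self, config):
        segments = _scaffold_segments(MOTIFS, config.seed, config.linker_length_range,
                                      config.motif_order)
        members = {m.name: m for m in evolve_family(segments, config)}
        for name, losses in MOTIF_LOSSES.items():
            kept = {s.motif_index for s in members[name].segments if s.kind == "motif"}
            assert kept.isdisjoint(losses)

    def test_within_subfamily_identity_exceeds_between(self, bundle):
        from famscan.duplication import smith_waterman

        seq = {p.id: p.sequence for p in bundle.proteins}
        within = smith_waterman(seq["StHsp70-7"], seq["StHsp70-13"]).identity
        between = smith_waterman(seq["StHsp70-7"], seq["StHsp70-2"]).identity
        assert within > between

    def test_rate_outside_range_rejected(self):
        with pytest.raises(ValueError, match="substitution rate"):
            GeneratorConfig(substitution_rate_within=0.95)


class TestPlaceGenes:
    def test_no_family_gene_on_chromosomes_2_and_5(self, bundle):
        chroms = {
            g.chromosome for g in bundle.genes if g.id in bundle.truth.family_members
        }
        assert "2" not in chroms and "5" not in chroms

    def test_chromosome_1_carries_four_family_genes(self, bundle):
        on_chr1 = [
            g for g in bundle.genes
            if g.chromosome == "1" and g.id in bundle.truth.family_members
        ]
        assert len(on_chr1) == 4

    def test_intronless_member_has_single_exon(self, bundle):
        assert len(bundle.gene("StHsp70-14").exons) == 1
        # narrative override: these two are intron-less as well
        for name in NARRATIVE_INTRONLESS:
            assert len(bundle.gene(name).exons) == 1

    def test_table_intron_counts_flag_restores_printed_column(self):
        cfg = GeneratorConfig(seed=7, table_intron_counts=True)
        bundle = famscan.generate(cfg)
        for name in NARRATIVE_INTRONLESS:
            assert len(bundle.gene(name).exons) == 2

    def test_translated_cds_equals_protein_for_every_gene(self, bundle):
        for gene in bundle.genes:
            assert translate(bundle.cds[gene.id]) == bundle.protein(gene.id).sequence

    def test_gene_ids_unique_and_within_chromosome_bounds(self, bundle):
        ids = [g.id for g in bundle.genes]
        assert len(ids) == len(set(ids))
        lengths = dict(bundle.chromosomes)
        for gene in bundle.genes:
            assert 1 <= gene.start <= gene.end <= lengths[gene.chromosome]

    def test_cds_length_matches_published_orf(self, bundle):
        table = {g.name: g for g in FAMILY_TABLE}
        for name, row in table.items():
            assert bundle.gene(name).cds_length == row.orf_bp

    def test_outputs_byte_identical_across_runs(self, tmp_path):
        cfg = GeneratorConfig(seed=9)
        payloads = []
        for sub in ("a", "b"):
            bundle = famscan.generate(cfg)
            fasta = tmp_path / sub / "p.fasta"
            gff = tmp_path / sub / "g.gff3"
            fasta.parent.mkdir()
            io.write_fasta(bundle.proteins, fasta)
            io.write_gff3(bundle.genes, gff)
            payloads.append((fasta.read_bytes(), gff.read_bytes()))
        assert payloads[0] == payloads[1]


class TestSimulateExpression:
    def test_zero_noise_returns_pattern_means_exactly(self, bundle):
        cfg = GeneratorConfig(seed=4, expression_noise_sd=0.0)
        matrix = simulate_expression(bundle, cfg)
        assert set(matrix.columns) == set(TISSUES)
        broad = matrix.loc["StHsp70-1"]
        assert (broad == cfg.fpkm_high).all()
        silent = matrix.loc["StHsp70-15"]
        assert (silent == cfg.fpkm_low).all()

    def test_root_tuber_pattern_gene_nonzero_only_there(self, fpkm):
        row = fpkm.loc["StHsp70-11"]
        on = row[row > 0].index
        assert set(on) == {"root", "tuber"}

    def test_all_entries_nonnegative(self, fpkm):
        assert (fpkm.values >= 0).all()

    def test_empty_tissue_list_rejected(self, bundle, config):
        with pytest.raises(ValueError):
            simulate_expression(bundle, config, tissues=())


class TestSimulateCt:
    def test_zero_effect_zero_noise_gives_unit_fold_changes(self, bundle):
        cfg = GeneratorConfig(seed=3, ct_effect=0.0, ct_noise_sd=0.0)
        calls = famscan.regulation_calls(simulate_ct(bundle, cfg), fold_min=1.0)
        assert all(c.fold_change == 1.0 for c in calls)

    def test_planted_twofold_up_shifts_treated_dct_by_one_cycle(self, bundle):
        cfg = GeneratorConfig(seed=3, ct_effect=1.0, ct_noise_sd=0.0)
        table = simulate_ct(bundle, cfg)
        from famscan.qpcr import _replicate_dcts

        dcts = _replicate_dcts(table)
        up = np.mean(dcts[("StHsp70-1", "salt")])  # planted up under salt
        control = np.mean(dcts[("StHsp70-1", "control")])
        assert up == pytest.approx(control - 1.0)

    def test_reference_ct_constant_in_expectation(self, ct_table):
        refs = np.array([r.ct_reference for r in ct_table.records])
        assert abs(refs.mean() - 20.0) < 0.05

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            GeneratorConfig(replicates=1)


def test_motif_definition_validates_width_and_alphabet():
    with pytest.raises(ValueError, match="width"):
        MotifDefinition(1, "ACD")
    with pytest.raises(ValueError, match="invalid"):
        MotifDefinition(1, "ACDEFU" * 2)
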