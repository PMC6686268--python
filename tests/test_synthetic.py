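"""The generators themselves: determinism, truth sufficiency, closures."""

import json

import pytest

from aquamip.npa import find_npa_boxes, npa_spacing
from aquamip.promoter import CisMotif, scan_promoter
from aquamip.seqio import count_introns, read_gff3
from aquamip.synthetic import (
    MIN_SPACING,
    TEMPLATES,
    build_scaffold,
    generate_fpkm,
    generate_gene_models,
    generate_mip_protein,
    generate_promoter,
    panel_alignment,
)


class TestDeterminism:
    def test_identical_seed_and_params_give_identical_outputs(self):
        a, _ = generate_mip_protein("PIP1", mutation_rate=0.1, seed=12)
        b, _ = generate_mip_protein("PIP1", mutation_rate=0.1, seed=12)
        assert a.sequence == b.sequence
        p1, _ = generate_promoter([("CGTCA", 2, "+")], seed=8, tag="x")
        p2, _ = generate_promoter([("CGTCA", 2, "+")], seed=8, tag="x")
        assert p1 == p2
        g1, _ = generate_gene_models({2: 3}, seed=4)
        g2, _ = generate_gene_models({2: 3}, seed=4)
        assert g1 == g2

    def test_different_seeds_differ(self):
        a, _ = generate_mip_protein("PIP1", mutation_rate=0.1, seed=1)
        b, _ = generate_mip_protein("PIP1", mutation_rate=0.1, seed=2)
        assert a.sequence != b.sequence


class TestProteinGenerator:
    def test_zero_mutation_reproduces_scaffold(self):
        scaffold, _ = build_scaffold("TIP1")
        rec, _ = generate_mip_protein("TIP1", mutation_rate=0.0, seed=99)
        assert rec.sequence == scaffold

    def test_spacing_closes_the_loop_with_npa_scan(self):
        rec, truth = generate_mip_protein("NIP2", spacing=108, npa_triplets=("NPA", "NPA"), seed=0)
        prof = find_npa_boxes(rec.sequence)
        assert npa_spacing(prof) == 108
        assert tuple(b.start for b in prof.boxes) == truth["box_starts"]

    def test_incompatible_spacing_errors(self):
        with pytest.raises(ValueError, match="spacing"):
            generate_mip_protein("PIP1", spacing=MIN_SPACING - 1)

    def test_mutation_rate_bounds(self):
        with pytest.raises(ValueError):
            generate_mip_protein("PIP1", mutation_rate=0.5)

    def test_planted_marker_residues_survive_mutation(self):
        rec, truth = generate_mip_protein("SIP2", mutation_rate=0.3, seed=5)
        for res, pos in zip(truth["arR"], truth["arR_positions"]):
            assert rec.sequence[pos] == res
        for res, pos in zip(truth["froger"], truth["froger_positions"]):
            assert rec.sequence[pos] == res

    def test_no_spurious_npa_boxes_after_repair(self):
        for s in range(30):
            rec, truth = generate_mip_protein("XIP1", mutation_rate=0.2, seed=s)
            prof = find_npa_boxes(rec.sequence)
            assert tuple(b.start for b in prof.boxes) == truth["box_starts"], s


def test_panel_alignment_is_consistent_with_shipped_fixture(panel):
    aligned, columns = panel_alignment()
    assert columns == panel.columns
    fixture = {m.id: (m.aligned_seq, m.subfamily, m.subgroup) for m in panel.members}
    assert {pid: (row, f, g) for pid, row, f, g in aligned} == fixture


class TestPromoterGenerator:
    def test_no_plants_yields_no_hits_against_screened_set(self):
        motifs = [CisMotif("CGTCA-motif", "CGTCA", "x"), CisMotif("MBS", "CAACTG", "y")]
        seq, _ = generate_promoter([], screen=[m.consensus for m in motifs], seed=3, tag="np")
        assert scan_promoter(seq, motifs) == []

    def test_planted_counts_and_offsets_exact(self):
        motif = CisMotif("CGTCA-motif", "CGTCA", "x")
        seq, truth = generate_promoter([(motif.consensus, 3, "+")], seed=6, tag="p")
        hits = scan_promoter(seq, [motif])
        assert sorted((h.strand, h.start) for h in hits) == sorted(
            (s, p) for _, s, p in truth["plants"]
        )

    def test_impossible_placement_errors(self):
        with pytest.raises(ValueError, match="overlap"):
            generate_promoter([("CGTCA", 300, "+")], length=100, seed=0)


class TestFpkmGenerator:
    def test_zero_noise_gives_perfect_correlation(self):
        import numpy as np

        m, truth = generate_fpkm(6, 8, planted_pairs=(0.7,), noise_sd=0.0, seed=1)
        a, b, _ = truth["pairs"][0]
        assert np.corrcoef(m.loc[a], m.loc[b])[0, 1] == pytest.approx(1.0)

    def test_invalid_target_r_rejected(self):
        with pytest.raises(ValueError):
            generate_fpkm(6, 8, planted_pairs=(1.5,), seed=0)
        with pytest.raises(ValueError):
            generate_fpkm(6, 3, seed=0)


class TestGeneModelGenerator:
    def test_intron_distribution_recovered_exactly(self, tmp_path):
        dist = {2: 17, 3: 10, 4: 3, 1: 3}
        text, truth = generate_gene_models(dist, seed=1)
        f = tmp_path / "syn.gff3"
        f.write_text(text)
        table = count_introns(read_gff3(f))
        assert table["intron_count"].value_counts().to_dict() == dist
        by_truth = {t["transcript_id"]: t["intron_count"] for t in truth["transcripts"]}
        assert dict(zip(table["transcript_id"], table["intron_count"])) == by_truth

    def test_no_utr_transcripts_flagged_false(self, tmp_path):
        text, truth = generate_gene_models({2: 4}, seed=2, no_utr_transcripts=2)
        f = tmp_path / "syn2.gff3"
        f.write_text(text)
        table = count_introns(read_gff3(f)).set_index("transcript_id")
        for t in truth["transcripts"]:
            assert bool(table.loc[t["transcript_id"], "has_utr5"]) is t["has_utr5"]
            assert bool(table.loc[t["transcript_id"], "has_utr3"]) is t["has_utr3"]

    def test_out_of_range_intron_counts_rejected(self):
        with pytest.raises(ValueError):
            generate_gene_models({5: 1}, seed=0)
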