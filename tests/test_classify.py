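"""p-distances, neighbor joining, and subfamily placement."""

import io

import numpy as np
import pytest

from aquamip.classify import (
    DistanceMatrix,
    assign_subfamily,
    build_distance_matrix,
    nj_tree,
    pip1_vs_pip2,
)
from aquamip.physchem import TMSegment, predict_tm_segments
from aquamip.residue_profile import ReferencePanel
from aquamip.seqio import ProteinRecord
from aquamip.synthetic import generate_mip_protein


class TestDistanceMatrix:
    def test_identical_rows_have_zero_distance(self):
        d = build_distance_matrix({"a": "MKTLL", "b": "MKTLL"})
        assert d.get("a", "b") == 0.0

    def test_half_mismatches(self):
        d = build_distance_matrix({"a": "AAAA", "b": "AATT"})
        assert d.get("a", "b") == pytest.approx(0.5)

    def test_matches_brute_force_on_random_alignment(self):
        rng = np.random.default_rng(5)
        letters = list("ACDE-")
        aln = {
            f"t{i}": "".join(rng.choice(letters, size=40)) for i in range(5)
        }
        d = build_distance_matrix(aln)
        ids = list(aln)
        for i in range(5):
            for j in range(i + 1, 5):
                a, b = aln[ids[i]], aln[ids[j]]
                cols = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
                expected = sum(x != y for x, y in cols) / len(cols)
                assert d.get(ids[i], ids[j]) == pytest.approx(expected)

    def test_zero_comparable_columns_names_the_pair(self):
        with pytest.raises(ValueError, match="a.*b|b.*a"):
            build_distance_matrix({"a": "AA--", "b": "--TT"})

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], float))


def _random_additive_tree(labels, rng):
    """Random binary tree newick with branch lengths in [0.5, 5]."""

    def build(subset):
        if len(subset) == 1:
            return f"{subset[0]}:{rng.uniform(0.5, 5.0):.6f}"
        k = int(rng.integers(1, len(subset)))
        left, right = subset[:k], subset[k:]
        bl = rng.uniform(0.5, 5.0)
        return f"({build(left)},{build(right)}):{bl:.6f}"

    shuffled = list(rng.permutation(labels))
    return f"({build(shuffled[:1])},{build(shuffled[1:])});"


def _tip_distances(newick, labels):
    from skbio import TreeNode

    t = TreeNode.read(io.StringIO(newick))
    dm = t.tip_tip_distances()
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = dm[labels[i], labels[j]]
    return out


class TestNeighborJoining:
    def test_three_taxa_star(self):
        d = DistanceMatrix(["a", "b", "c"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        got = _tip_distances(nj_tree(d).newick, ["a", "b", "c"])
        assert np.allclose(got, d.matrix, atol=1e-9)

    def test_hand_additive_four_taxon_matrix(self):
        # generating tree: ((A:2,B:3):1,C:4,D:5) with C,D joined through the root
        d = DistanceMatrix(
            ["A", "B", "C", "D"],
            np.array(
                [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], float
            ),
        )
        got = _tip_distances(nj_tree(d).newick, ["A", "B", "C", "D"])
        assert np.allclose(got, d.matrix, atol=1e-9)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_additive_matrices_recovered_exactly(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        labels = [f"t{i}" for i in range(n_taxa)]
        for _ in range(5):
            true = _random_additive_tree(labels, rng)
            dmat = _tip_distances(true, labels)
            tree = nj_tree(DistanceMatrix(labels, dmat))
            got = _tip_distances(tree.newick, labels)
            assert np.allclose(got, dmat, atol=1e-9)

    def test_agrees_with_independent_nj_implementation(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(17)
        labels = [f"t{i}" for i in range(6)]
        dmat = _tip_distances(_random_additive_tree(labels, rng), labels)
        ours = _tip_distances(nj_tree(DistanceMatrix(labels, dmat)).newick, labels)
        theirs_tree = skbio_nj(SkbioDM(dmat, labels))
        theirs = _tip_distances(str(theirs_tree), labels)
        assert np.allclose(ours, theirs, atol=1e-6)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


class TestAssignSubfamily:
    def test_identity_query_has_full_support(self, panel):
        member = panel.members[0]
        q = ProteinRecord("query_pip", member.sequence)
        call = assign_subfamily(q, panel, bootstrap_n=50, seed=1)
        assert call.subfamily == member.subfamily
        assert call.support == 1.0

    def test_mutated_tip_members_classified_as_tip(self, panel):
        for s in range(25):
            rec, truth = generate_mip_protein("TIP1", mutation_rate=0.10, seed=s)
            call = assign_subfamily(rec, panel)
            assert call.subfamily == "TIP", s

    def test_random_sequence_is_unclassified(self, panel):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=250))
        call = assign_subfamily(ProteinRecord("rand", seq), panel, bootstrap_n=20, seed=2)
        assert call.subfamily == "unclassified" or "low_support" in call.flags

    def test_invariant_to_panel_member_order(self, panel):
        rec, _ = generate_mip_protein("NIP1", mutation_rate=0.12, seed=9)
        call1 = assign_subfamily(rec, panel)
        reordered = ReferencePanel(panel.members[::-1], panel.columns)
        call2 = assign_subfamily(rec, reordered)
        assert (call1.subfamily, call1.subgroup) == (call2.subfamily, call2.subgroup)


class TestPip1VsPip2:
    def test_panel_pip_members_self_consistent(self, panel):
        for m in panel.members:
            if m.subfamily != "PIP":
                continue
            q = ProteinRecord(m.id + "_q", m.sequence)
            segs = predict_tm_segments(m.sequence)
            subgroup, flags = pip1_vs_pip2(q, segs, panel)
            assert subgroup == m.subgroup, m.id

    def test_stretched_tail_becomes_pip1(self, panel):
        rec, _ = generate_mip_protein("PIP2", seed=3)
        stretched = ProteinRecord("long_tail", "E" * 30 + rec.sequence)
        segs = predict_tm_segments(stretched.sequence)
        subgroup, _ = pip1_vs_pip2(stretched, segs, panel)
        assert subgroup == "PIP1"

    def test_tie_at_cutoff_is_pip2_flagged(self, panel):
        q = ProteinRecord("tie", "E" * 30 + "L" * 23 + "E" * 30)
        segs = [TMSegment(30, 53, 3.8)]
        subgroup, flags = pip1_vs_pip2(q, segs, panel, cutoff=30)
        assert subgroup == "PIP2" and "tail_at_cutoff" in flags

    def test_no_tm_segments_falls_back(self, panel):
        q = ProteinRecord("no_tm", "E" * 60)
        subgroup, flags = pip1_vs_pip2(q, [], panel)
        assert subgroup == "" and "no_tm_segments" in flags
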