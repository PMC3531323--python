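import numpy as np
import pytest

from esimap import (
    Alignment,
    Atom,
    Structure,
    assign_faces,
    columns_for_face,
    hcluster,
    make_conservation_groups,
    pairwise_charge_similarity,
    pairwise_identity,
)
from esimap.seqcharge import (
    FACE_HIGH_X,
    FACE_LOW_X,
    SimilarityMatrix,
    read_alignment,
    write_alignment,
)


def aln(*rows, labels=None):
    labels = labels or [f"s{i}" for i in range(len(rows))]
    return Alignment(list(labels), list(rows))


class TestIdentity:
    def test_identical_rows(self):
        m = pairwise_identity(aln("AKLD", "AKLD"))
        assert m.values[0, 1] == 1.0

    def test_shared_gap_column_not_scored(self):
        m = pairwise_identity(aln("AK-D", "AR-D"))
        assert m.values[0, 1] == pytest.approx(2 / 3)  # 3 scored, 2 match

    def test_disjoint_residues(self):
        m = pairwise_identity(aln("AAAA", "GGGG"))
        assert m.values[0, 1] == 0.0

    def test_column_subset(self):
        m = pairwise_identity(aln("AKLD", "ARLD"), columns=[0, 2, 3])
        assert m.values[0, 1] == 1.0

    def test_row_order_invariance(self):
        a1 = pairwise_identity(aln("AKLD", "ARLD", "GKLD"))
        a2 = pairwise_identity(aln("GKLD", "ARLD", "AKLD"))
        assert a1.values[0, 1] == a2.values[2, 1]


class TestChargeSimilarity:
    def test_like_charge_positions_counted(self):
        m = pairwise_charge_similarity(aln("KDEA", "RDEG"))
        assert m.values[0, 1] == 3  # K/R, D/D, E/E

    def test_opposite_charges_do_not_count(self):
        m = pairwise_charge_similarity(aln("KKKK", "DDDD"))
        assert m.values[0, 1] == 0

    def test_diagonal_is_own_charged_count(self):
        m = pairwise_charge_similarity(aln("KDEAX", "RDEGK"))
        assert m.values[0, 0] == 3
        assert m.values[1, 1] == 4

    def test_diagonal_dominates_rows(self):
        rows = ["KDEARK", "RDEGKA", "KKDDEE", "AAAAKD"]
        m = pairwise_charge_similarity(aln(*rows))
        for i in range(4):
            assert m.values[i, i] == m.values[i].max()

    def test_ambiguous_and_gap_never_match(self):
        m = pairwise_charge_similarity(aln("KB-Z", "KX-Z"))
        assert m.values[0, 1] == 1  # only the K/K column

    def test_restriction_never_increases_counts(self):
        rng = np.random.default_rng(0)
        alphabet = np.array(list("KRDEAGST-"))
        rows = ["".join(rng.choice(alphabet, 30)) for _ in range(5)]
        full = pairwise_charge_similarity(aln(*rows)).values
        sub = pairwise_charge_similarity(aln(*rows), columns=range(10)).values
        assert np.all(sub <= full)


def single_atom_residues(xs):
    atoms = [Atom(i + 1, "CA", "ALA", "A", i + 1, np.array([x, 0.0, 0.0]))
             for i, x in enumerate(xs)]
    return Structure(atoms, "faces")


class TestFaces:
    def test_rule_assigns_both_faces(self):
        # mean x = 0; -6 joins low-x face, +6 the high-x face
        s = single_atom_residues([-6.0, -1.0, 1.0, 6.0])
        fa = assign_faces(s)
        assert fa.labels == [FACE_LOW_X, "neither", "neither", FACE_HIGH_X]

    def test_boundary_is_strict_on_high_side(self):
        # mean 0: x = +5 is NOT > mean+5, but x = -5 IS <= mean-5
        s = single_atom_residues([-5.0, 5.0])
        fa = assign_faces(s)
        assert fa.labels == [FACE_LOW_X, "neither"]

    def test_spanning_residue_is_neither(self):
        atoms = [Atom(1, "CA", "ALA", "A", 1, np.array([-8.0, 0, 0])),
                 Atom(2, "CB", "ALA", "A", 1, np.array([8.0, 0, 0])),
                 Atom(3, "CA", "ALA", "A", 2, np.array([0.0, 0, 0]))]
        fa = assign_faces(Structure(atoms, "span"))
        assert fa.labels[0] == "neither"


class TestColumnsForFace:
    def test_maps_through_reference_gaps(self):
        s = single_atom_residues([-6.0, -6.5, -7.0, 1.0, 6.0, 0.0, 0.5, -1, 2, 1])
        fa = assign_faces(s)
        ref = "AB-CDEFGH--IJ"  # 10 non-gap positions for 10 residues
        a = Alignment(["ref", "x"], [ref, "NNNNNNNNNNNNN"], reference_label="ref")
        cols = columns_for_face(a, fa, FACE_LOW_X)
        assert cols == [0, 1, 3]  # residues 1-3, skipping the gap column

    def test_reference_length_mismatch_errors(self):
        s = single_atom_residues([-6.0, 6.0])
        fa = assign_faces(s)
        a = Alignment(["ref"], ["ABC"], reference_label="ref")
        with pytest.raises(ValueError, match="residues"):
            columns_for_face(a, fa, FACE_LOW_X)

    def test_no_labeled_residues_gives_empty_subset(self):
        s = single_atom_residues([-1.0, 1.0])
        fa = assign_faces(s)
        a = Alignment(["ref"], ["AB"], reference_label="ref")
        assert columns_for_face(a, fa, FACE_LOW_X) == []


def similarity_from_distance(d, labels):
    return SimilarityMatrix(labels, 1.0 - d, kind="identity_fraction")


class TestHcluster:
    def test_closest_pair_merges_first(self):
        d = np.array([[0.0, 0.1, 0.9],
                      [0.1, 0.0, 0.9],
                      [0.9, 0.9, 0.0]])
        dend = hcluster(similarity_from_distance(d, ["A", "B", "C"]))
        first = dend.linkage_matrix[0]
        assert {dend.labels[int(first[0])], dend.labels[int(first[1])]} == {"A", "B"}
        assert first[2] == pytest.approx(0.1)

    def test_identical_items_merge_at_zero_height(self):
        m = pairwise_identity(aln("AKLD", "AKLD", "GGGG"))
        dend = hcluster(m)
        assert dend.linkage_matrix[0, 2] == pytest.approx(0.0)

    def test_ultrametric_four_leaf_recovery(self):
        """Complete linkage must recover the generating tree of any
        ultrametric 4-leaf distance set; the oracle enumerates the three
        possible pairings by brute force."""
        labels = ["A", "B", "C", "D"]
        d = np.array([[0.0, 0.2, 1.0, 1.0],
                      [0.2, 0.0, 1.0, 1.0],
                      [1.0, 1.0, 0.0, 0.4],
                      [1.0, 1.0, 0.4, 0.0]])
        # brute-force oracle: pick the pairing minimizing the larger
        # intra-pair distance over the 3 distinct 2+2 splits
        best = min(
            ([(0, 1), (2, 3)], [(0, 2), (1, 3)], [(0, 3), (1, 2)]),
            key=lambda split: max(d[i, j] for i, j in split))
        oracle_groups = {frozenset(labels[i] for i in pair) for pair in best}

        dend = hcluster(similarity_from_distance(d, labels))
        cut = dend.cut(2)
        groups = {}
        for lab, c in cut.items():
            groups.setdefault(c, set()).add(lab)
        assert {frozenset(g) for g in groups.values()} == oracle_groups
        # cophenetic distances reproduce the ultrametric input exactly
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import squareform

        coph = squareform(cophenet(dend.linkage_matrix))
        reorder = [labels.index(l) for l in dend.labels]
        assert np.allclose(coph, d[np.ix_(reorder, reorder)])

    def test_newick_has_all_leaves(self):
        m = pairwise_identity(aln("AKLD", "ARLD", "GGGG", "GGGA"))
        nwk = hcluster(m).newick()
        for lab in m.labels:
            assert lab in nwk
        assert nwk.endswith(";")

    def test_non_symmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            SimilarityMatrix(["a", "b"], np.array([[1.0, 0.2], [0.4, 1.0]]),
                             kind="identity_fraction")


def test_conserved_group_separates_from_scrambled_at_top_split():
    """Charge-position clustering over face columns puts the lineage with a
    fully conserved charge pattern and the lineage with its own partially
    scrambled pattern on opposite sides of the top split."""
    face_cols = list(range(1, 13))
    a, groups = make_conservation_groups(6, 6, face_cols, seed=3, n_residues=24)
    m = pairwise_charge_similarity(a, columns=[c - 1 for c in face_cols])
    dend = hcluster(m)
    cut = dend.cut(2)
    by_cluster = {}
    for lab, c in cut.items():
        by_cluster.setdefault(c, set()).add(groups[lab])
    assert sorted(map(tuple, by_cluster.values())) == [(1,), (2,)]


def test_alignment_fasta_roundtrip(tmp_path):
    a = aln("AK-D", "AR-D", labels=["human", "mouse"])
    path = tmp_path / "aln.fasta"
    write_alignment(a, path)
    back = read_alignment(path)
    assert back.labels == a.labels
    assert back.rows == a.rows
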