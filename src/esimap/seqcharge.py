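"""Sequence-side conservation analysis: identity and charge-position matrices.

From a multiple sequence alignment this module builds two pairwise matrices
— fraction of identical positions, and the count of positions where both
sequences carry a like-charged residue (both K/R, or both D/E) — optionally
restricted to alignment columns belonging to a coordinate-defined functional
face of the reference structure, then clusters them hierarchically.

Faces come from the x-coordinate rule: with mean(x) taken over all atoms of
the structure, a residue belongs to one face when any of its atoms has
x <= mean(x) - margin and to the opposite face when any atom has
x > mean(x) + margin (margin 5 A); everything else is 'neither'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform

from .structure_io import Structure

logger = logging.getLogger(__name__)

__all__ = [
    "Alignment",
    "SimilarityMatrix",
    "FaceAssignment",
    "read_alignment",
    "write_alignment",
    "pairwise_identity",
    "pairwise_charge_similarity",
    "assign_faces",
    "columns_for_face",
    "hcluster",
    "Dendrogram",
]

_POSITIVE = {"K", "R"}
_NEGATIVE = {"D", "E"}
GAP = "-"


@dataclass
class Alignment:
    """Gapped, equal-length sequences with labels; one row is the reference."""

    labels: list[str]
    rows: list[str]
    reference_label: str | None = None

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows length mismatch")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"aligned rows differ in length: {sorted(lengths)}")
        if self.reference_label is None and self.labels:
            self.reference_label = self.labels[0]
        if self.reference_label not in self.labels:
            raise ValueError(f"reference {self.reference_label!r} not in labels")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, label: str) -> str:
        return self.rows[self.labels.index(label)]


def read_alignment(path, reference_label: str | None = None) -> Alignment:
    """Read an aligned FASTA file."""
    from biotite.sequence.io.fasta import FastaFile

    ff = FastaFile.read(str(path))
    labels = list(ff.keys())
    rows = [str(ff[k]).upper() for k in labels]
    if not rows:
        raise ValueError(f"no sequences in {path}")
    return Alignment(labels, rows, reference_label)


def write_alignment(a: Alignment, path) -> None:
    from biotite.sequence.io.fasta import FastaFile

    ff = FastaFile()
    for label, row in zip(a.labels, a.rows):
        ff[label] = row
    ff.write(str(path))


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise scores: identity fraction or like-charge counts."""

    labels: list[str]
    values: np.ndarray
    kind: str  # identity_fraction | charge_count

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("similarity matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _select_columns(rows: list[str], columns) -> list[str]:
    if columns is None:
        return rows
    columns = list(columns)
    if not columns:
        raise ValueError("empty column subset")
    return ["".join(r[c] for c in columns) for r in rows]


def pairwise_identity(a: Alignment, columns=None) -> SimilarityMatrix:
    """Fraction of identical positions per sequence pair.

    Scored columns are those where at least one of the two rows is non-gap;
    a match requires equal non-gap letters. Columns gapped in both rows do
    not count toward the denominator.
    """
    if len(a.rows) < 2:
        raise ValueError("need at least 2 sequences")
    rows = _select_columns(a.rows, columns)
    n = len(rows)
    mat = np.eye(n)
    arrs = [np.frombuffer(r.encode(), dtype="S1") for r in rows]
    gap = GAP.encode()
    for i in range(n):
        for j in range(i + 1, n):
            either = (arrs[i] != gap) | (arrs[j] != gap)
            scored = int(either.sum())
            if scored == 0:
                mat[i, j] = mat[j, i] = 0.0
                continue
            matches = int(((arrs[i] == arrs[j]) & (arrs[i] != gap) & either).sum())
            mat[i, j] = mat[j, i] = matches / scored
    return SimilarityMatrix(list(a.labels), mat, kind="identity_fraction")


def pairwise_charge_similarity(a: Alignment, columns=None) -> SimilarityMatrix:
    """Count of positions where both sequences carry a like charge.

    A position counts when both rows are in {K, R} or both are in {D, E}.
    Gaps and ambiguous residues (B, Z, X) never count. The diagonal is each
    sequence's own charged-position count over the selected columns.
    """
    if len(a.rows) < 2:
        raise ValueError("need at least 2 sequences")
    rows = _select_columns(a.rows, columns)
    n = len(rows)
    pos = [np.array([c in _POSITIVE for c in r]) for r in rows]
    neg = [np.array([c in _NEGATIVE for c in r]) for r in rows]
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            count = int((pos[i] & pos[j]).sum() + (neg[i] & neg[j]).sum())
            mat[i, j] = mat[j, i] = count
    return SimilarityMatrix(list(a.labels), mat, kind="charge_count")


@dataclass
class FaceAssignment:
    """Per-residue face labels from the x-coordinate rule."""

    residue_keys: list[tuple[str, int]]  # (chain_id, residue_number) in order
    labels: list[str]  # cr2_face | thioester_face | neither
    mean_x: float
    margin: float = 5.0

    def residues_with(self, label: str) -> list[tuple[str, int]]:
        return [k for k, lab in zip(self.residue_keys, self.labels) if lab == label]

    def to_frame(self, s: Structure | None = None) -> pd.DataFrame:
        rows = []
        for key, lab in zip(self.residue_keys, self.labels):
            rows.append({"chain": key[0], "resnum": key[1], "face": lab})
        return pd.DataFrame(rows)


FACE_LOW_X = "cr2_face"        # atoms at x <= mean(x) - margin
FACE_HIGH_X = "thioester_face"  # atoms at x >  mean(x) + margin


def assign_faces(s: Structure, margin: float = 5.0) -> FaceAssignment:
    """Split residues into two opposing faces by atomic x-coordinates.

    With x_mean the mean x over all atoms: a residue joins the low-x face
    when any atom has x <= x_mean - margin, and the high-x face when any
    atom has x > x_mean + margin (strict). A residue qualifying for both
    (possible only for very extended residues) is flagged and assigned
    'neither' so the faces stay disjoint.
    """
    mean_x = float(s.coords[:, 0].mean())
    keys, labels = [], []
    for key, res_atoms in s.residues():
        xs = np.array([a.position[0] for a in res_atoms])
        low = bool(np.any(xs <= mean_x - margin))
        high = bool(np.any(xs > mean_x + margin))
        if low and high:
            logger.warning("residue %s qualifies for both faces; set to neither", key)
            labels.append("neither")
        elif low:
            labels.append(FACE_LOW_X)
        elif high:
            labels.append(FACE_HIGH_X)
        else:
            labels.append("neither")
        keys.append(key)
    return FaceAssignment(keys, labels, mean_x=mean_x, margin=margin)


def columns_for_face(a: Alignment, fa: FaceAssignment, face: str) -> list[int]:
    """Alignment columns whose reference-row residue carries the face label.

    The reference row's non-gap positions must map 1:1, in order, onto the
    structure's residues (the FaceAssignment's residue list).
    """
    ref = a.row(a.reference_label)
    non_gap_cols = [c for c, ch in enumerate(ref) if ch != GAP]
    if len(non_gap_cols) != len(fa.residue_keys):
        raise ValueError(
            f"reference row has {len(non_gap_cols)} residues but the structure "
            f"has {len(fa.residue_keys)}")
    return [c for c, lab in zip(non_gap_cols, fa.labels) if lab == face]


@dataclass
class Dendrogram:
    """Agglomerative merge tree over labeled items."""

    labels: list[str]
    linkage_matrix: np.ndarray
    distance: np.ndarray

    def newick(self) -> str:
        tree = to_tree(self.linkage_matrix)

        def fmt(node, parent_dist):
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6f}"
            return (f"({fmt(node.left, node.dist)},{fmt(node.right, node.dist)})"
                    f":{length:.6f}")

        return f"({fmt(tree.left, tree.dist)},{fmt(tree.right, tree.dist)});"

    def cut(self, k: int) -> dict:
        """Flat clusters at the k-cluster level: label -> cluster id."""
        assign = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in assign)))

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.linkage_matrix,
                            columns=["left", "right", "height", "size"])


def similarity_to_distance(m: SimilarityMatrix) -> np.ndarray:
    """Convert a similarity matrix to a [0, 1] distance matrix.

    identity_fraction: d = 1 - s. charge_count: d = 1 - c_ij/max(c_ii, c_jj),
    which removes sequence-length / net-charge-magnitude effects.
    """
    v = m.values
    if m.kind == "identity_fraction":
        d = 1.0 - v
    elif m.kind == "charge_count":
        diag = np.diag(v)
        denom = np.maximum.outer(diag, diag)
        denom = np.where(denom == 0, 1.0, denom)
        d = 1.0 - v / denom
    else:
        raise ValueError(f"unknown similarity kind {m.kind!r}")
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    return d


def hcluster(m: SimilarityMatrix, method: str = "complete") -> Dendrogram:
    """Agglomerative clustering of a similarity matrix (complete linkage).

    Items are pre-sorted by label so equal-distance merges break ties
    deterministically by label order; the output keeps the caller's labels.
    """
    if len(m.labels) < 2:
        raise ValueError("need at least 2 items to cluster")
    order = sorted(range(len(m.labels)), key=lambda i: m.labels[i])
    labels = [m.labels[i] for i in order]
    d = similarity_to_distance(m)[np.ix_(order, order)]
    z = linkage(squareform(d, checks=False), method=method)
    return Dendrogram(labels, z, d)
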