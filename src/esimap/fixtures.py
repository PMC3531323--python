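"""Synthetic structures, families and alignments with controlled electrostatics.

Pseudo-protein fixtures carry exactly the features the perturbation-map
method consumes — monopole positions, van der Waals radii and residue
identities — without real rotamer geometry. Each residue is a five-atom
unit (N, CA, C, O, CB) on either a linear chain (3.8 A CA spacing) or a
sphere-surface scatter; formal charges land on CB through the standard
parameter-assignment fallback.

Three generators cover the method's study conditions: single toy structures
with a stated charge layout, a hot-spot structure (a tight patch of
like-charged residues plus isolated dispersed charges) for the perturbation
ESI contrast, and homologue families with controlled charge-position
conservation plus the matching gapless alignment.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqcharge import Alignment, write_alignment
from .structure_io import Atom, Structure, write_pdb

__all__ = [
    "ToySpec",
    "make_toy_structure",
    "make_hotspot_fixture",
    "make_synthetic_family",
    "make_conservation_groups",
    "write_synthetic_family",
]

_NAME_FOR_CHARGE = {-1: "ASP", +1: "LYS", 0: "ALA"}
_NEG_NAMES = ("ASP", "GLU")
_POS_NAMES = ("LYS", "ARG")
_ONE = {"ASP": "D", "GLU": "E", "LYS": "K", "ARG": "R", "ALA": "A"}


@dataclass
class ToySpec:
    """Layout of a synthetic structure; deterministic for a fixed seed."""

    n_residues: int
    charges: dict = field(default_factory=dict)  # 1-based residue index -> -1/0/+1
    geometry: str = "linear"  # linear | sphere
    radius: float = 16.0  # sphere radius, A
    seed: int = 0
    label: str = "toy"


def _tangent_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    t1 = np.cross(u, ref)
    t1 /= np.linalg.norm(t1)
    return t1, np.cross(u, t1)


def _residue_atoms(ca: np.ndarray, u: np.ndarray, res_name: str,
                   res_num: int, serial0: int, chain: str = "A") -> list[Atom]:
    """Five-atom pseudo residue around a CA with CB pointing along u."""
    t1, t2 = _tangent_frame(u)
    positions = {
        "N": ca + 1.46 * t1,
        "CA": ca,
        "C": ca - 1.46 * t1,
        "O": ca - 1.46 * t1 + 1.23 * t2,
        "CB": ca + 1.53 * u,
    }
    return [Atom(serial0 + i, name, res_name, chain, res_num, pos)
            for i, (name, pos) in enumerate(positions.items(), start=1)]


def _fibonacci_directions(n: int) -> np.ndarray:
    """n near-uniform unit vectors on the sphere (deterministic)."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = np.pi * (1 + 5**0.5) * i
    r = np.sqrt(1 - z * z)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def make_toy_structure(spec: ToySpec, residue_names: dict | None = None) -> Structure:
    """Build a pseudo-structure from a ToySpec.

    Charges are requested per 1-based residue index; charged residues are
    named ASP (-1) / LYS (+1) unless residue_names overrides a position,
    neutral ones ALA. Atom pairs closer than 1 A are rejected.
    """
    if spec.n_residues < 1:
        raise ValueError("need at least one residue")
    bad = [i for i in spec.charges if not 1 <= i <= spec.n_residues]
    if bad:
        raise ValueError(f"charge layout indices out of range: {bad}")

    atoms: list[Atom] = []
    if spec.geometry == "linear":
        # compact offsets keep inter-residue atom gaps > 1 A at 3.8 A CA spacing
        offsets = {"N": np.array([-1.0, 0.8, 0.0]), "CA": np.zeros(3),
                   "C": np.array([1.0, 0.8, 0.0]), "O": np.array([1.4, 1.9, 0.0]),
                   "CB": np.array([0.0, -1.53, 0.0])}
        for i in range(1, spec.n_residues + 1):
            ca = np.array([3.8 * (i - 1), 0.0, 0.0])
            name = _res_name(spec, i, residue_names)
            atoms += [Atom(len(atoms) + k, nm, name, "A", i, ca + off)
                      for k, (nm, off) in enumerate(offsets.items(), start=1)]
    elif spec.geometry == "sphere":
        dirs = _fibonacci_directions(spec.n_residues)
        for i in range(1, spec.n_residues + 1):
            u = dirs[i - 1]
            ca = spec.radius * u
            atoms += _residue_atoms(ca, u, _res_name(spec, i, residue_names), i,
                                    len(atoms))
    else:
        raise ValueError(f"unknown geometry {spec.geometry!r}")

    _check_overlaps(atoms)
    return Structure(atoms, label=spec.label)


def _res_name(spec: ToySpec, i: int, residue_names: dict | None) -> str:
    if residue_names and i in residue_names:
        return residue_names[i]
    return _NAME_FOR_CHARGE[spec.charges.get(i, 0)]


def _check_overlaps(atoms: list[Atom]) -> None:
    coords = np.array([a.position for a in atoms])
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    if d2.min() < 1.0:
        i, j = np.unravel_index(int(d2.argmin()), d2.shape)
        raise ValueError(f"overlapping atoms {atoms[i].serial} and {atoms[j].serial} "
                         f"({np.sqrt(d2.min()):.2f} A apart)")


def make_hotspot_fixture(cluster_size: int = 5, n_dispersed: int = 5,
                         seed: int = 0, radius: float = 44.0,
                         patch_diameter: float = 8.0) -> Structure:
    """Sphere-surface structure with one like-charge cluster plus isolated charges.

    cluster_size acidic residues sit in a surface patch of diameter
    <= patch_diameter (8 A) around the +z pole; n_dispersed acidic residues
    sit pairwise >= 15 A apart on the lower hemisphere (far from the
    cluster); a belt of neutral residues fills out the scaffold. The default
    44 A scaffold radius keeps the dispersed charges genuinely isolated
    (~45 A apart) on a box of the same ~116 A scale used for real single-
    domain grids, so the hot-spot mechanism is observable: removing one of
    several co-located charges perturbs the local potential fractionally
    less than removing an isolated charge. The seed applies only a rigid
    rotation about z (all pairwise distances are invariant).

    Residue numbering is fixed: cluster residues are 1..cluster_size,
    dispersed residues are cluster_size+1..cluster_size+n_dispersed (also
    exposed as the .cluster_residues / .dispersed_residues attributes of the
    returned Structure; note plain copies made downstream keep only the
    numbering convention).
    """
    if cluster_size < 3:
        raise ValueError("cluster needs at least 3 charges")
    # cluster: pole + ring at a pole-chord of patch_diameter/2, so the ring
    # diameter (largest pairwise chord) equals patch_diameter
    theta_c = 2 * np.arcsin((patch_diameter / 2.0) / (2.0 * radius))
    cluster_dirs = [np.array([0.0, 0.0, 1.0])]
    for k in range(cluster_size - 1):
        ang = 2 * np.pi * k / (cluster_size - 1)
        cluster_dirs.append(np.array([
            np.sin(theta_c) * np.cos(ang), np.sin(theta_c) * np.sin(ang),
            np.cos(theta_c)]))
    # dispersed: evenly spaced ring on the lower hemisphere
    theta_d = np.deg2rad(110.0)
    dispersed_dirs = []
    for k in range(n_dispersed):
        ang = 2 * np.pi * k / max(n_dispersed, 1) + 0.3
        dispersed_dirs.append(np.array([
            np.sin(theta_d) * np.cos(ang), np.sin(theta_d) * np.sin(ang),
            np.cos(theta_d)]))
    if n_dispersed > 1:
        ring = radius * np.array(dispersed_dirs)
        dmin = min(np.linalg.norm(ring[i] - ring[j])
                   for i in range(n_dispersed) for j in range(i + 1, n_dispersed))
        if dmin < 15.0:
            raise ValueError(
                f"geometry infeasible: {n_dispersed} dispersed charges on a "
                f"{radius} A sphere come within {dmin:.1f} A (< 15 A)")
    # neutral scaffold belt between the two charged zones
    neutral_dirs = []
    for theta in (np.deg2rad(55.0), np.deg2rad(80.0), np.deg2rad(150.0)):
        for k in range(4):
            ang = 2 * np.pi * k / 4 + 0.9
            neutral_dirs.append(np.array([
                np.sin(theta) * np.cos(ang), np.sin(theta) * np.sin(ang),
                np.cos(theta)]))

    atoms: list[Atom] = []
    res_num = 0
    for dirs, name in ((cluster_dirs, "ASP"), (dispersed_dirs, "ASP"),
                       (neutral_dirs, "ALA")):
        for u in dirs:
            res_num += 1
            u = np.asarray(u, float)
            atoms += _residue_atoms(radius * u, u, name, res_num, len(atoms))
    # seeded rigid rotation about z: distances (and hence physics) invariant
    rot = np.random.default_rng(seed).uniform(0.0, 2 * np.pi)
    cr, sr = np.cos(rot), np.sin(rot)
    rz = np.array([[cr, -sr, 0.0], [sr, cr, 0.0], [0.0, 0.0, 1.0]])
    for a in atoms:
        a.position = rz @ a.position
    _check_overlaps(atoms)
    s = Structure(atoms, label=f"hotspot_c{cluster_size}_d{n_dispersed}")
    s.cluster_residues = list(range(1, len(cluster_dirs) + 1))
    s.dispersed_residues = list(range(len(cluster_dirs) + 1,
                                      len(cluster_dirs) + len(dispersed_dirs) + 1))
    return s


def make_synthetic_family(
    n_members: int,
    conserved_columns: list[int],
    scrambled_columns: list[int],
    seed: int = 0,
    n_residues: int = 20,
    radius: float = 16.0,
) -> tuple[Structure, list[Structure], Alignment]:
    """Homologue family sharing one geometry with controlled charge conservation.

    Columns are 1-based residue indices. Conserved columns carry one charge
    pattern (sign and D/E vs K/R letter drawn once from the seed) identical
    across members; scrambled columns redraw sign and letter per member.
    Returns (parent, members, gapless alignment); the parent is member one's
    twin and the alignment's reference row.
    """
    if set(conserved_columns) & set(scrambled_columns):
        raise ValueError("conserved and scrambled column sets must be disjoint")
    for c in list(conserved_columns) + list(scrambled_columns):
        if not 1 <= c <= n_residues:
            raise ValueError(f"column {c} out of range 1..{n_residues}")
    rng = np.random.default_rng(seed)
    conserved_names = {c: _draw_charged_name(rng) for c in conserved_columns}

    def build(label: str, member_rng) -> tuple[Structure, str]:
        names = dict(conserved_names)
        for c in scrambled_columns:
            names[c] = _draw_charged_name(member_rng)
        charges = {c: (-1 if n in _NEG_NAMES else +1) for c, n in names.items()}
        spec = ToySpec(n_residues, charges, geometry="sphere", radius=radius,
                       seed=seed, label=label)
        s = make_toy_structure(spec, residue_names=names)
        seq = "".join(_ONE[names.get(i, "ALA")] for i in range(1, n_residues + 1))
        return s, seq

    parent, parent_seq = build("parent", np.random.default_rng(seed + 1))
    members, labels, rows = [], [], []
    for m in range(n_members):
        s, seq = build(f"hom_{m + 1:02d}", np.random.default_rng(seed + 1 + m))
        members.append(s)
        labels.append(s.label)
        rows.append(seq)
    aln = Alignment(["parent"] + labels, [parent_seq] + rows,
                    reference_label="parent")
    return parent, members, aln


def _draw_charged_name(rng) -> str:
    sign = rng.choice([-1, +1])
    return rng.choice(_NEG_NAMES) if sign < 0 else rng.choice(_POS_NAMES)


def make_conservation_groups(
    n_group1: int,
    n_group2: int,
    face_columns: list[int],
    seed: int = 0,
    n_residues: int = 20,
    background_fraction: float = 0.5,
) -> tuple[Alignment, dict]:
    """Two-lineage alignment for the charge-clustering separation test.

    Group 1 conserves one charge pattern at every face column. Group 2
    shares a second, sign-flipped pattern on a background subset of the
    face columns (emulating its own conserved lineage pattern) and
    scrambles the rest per member. Returns the alignment and a
    label -> group map; group 1's first row is the reference.
    """
    rng = np.random.default_rng(seed)
    face_columns = list(face_columns)
    pattern1 = {c: _draw_charged_name(rng) for c in face_columns}
    n_bg = int(round(background_fraction * len(face_columns)))
    bg_cols = face_columns[:n_bg]
    pattern2 = {c: _flip(pattern1[c], rng) for c in bg_cols}

    labels, rows, groups = [], [], {}
    for g, n, prefix in ((1, n_group1, "g1"), (2, n_group2, "g2")):
        for m in range(n):
            label = f"{prefix}_{m + 1:02d}"
            member_rng = np.random.default_rng(seed + 101 * g + m)
            names = {}
            for c in face_columns:
                if g == 1:
                    names[c] = pattern1[c]
                elif c in pattern2:
                    names[c] = pattern2[c]
                else:
                    names[c] = _draw_charged_name(member_rng)
            rows.append("".join(_ONE[names.get(i, "ALA")]
                                for i in range(1, n_residues + 1)))
            labels.append(label)
            groups[label] = g
    return Alignment(labels, rows, reference_label=labels[0]), groups


def _flip(name: str, rng) -> str:
    return rng.choice(_POS_NAMES) if name in _NEG_NAMES else rng.choice(_NEG_NAMES)


def write_synthetic_family(parent: Structure, members: list[Structure],
                           aln: Alignment, out_dir) -> Path:
    """Write the family as PDB files, an aligned FASTA and a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_pdb(parent, out_dir / "parent.pdb")
    for m in members:
        write_pdb(m, out_dir / f"{m.label}.pdb")
    write_alignment(aln, out_dir / "family.fasta")
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "role", "file"])
        writer.writerow([parent.label, "parent", "parent.pdb"])
        for m in members:
            writer.writerow([m.label, "member", f"{m.label}.pdb"])
    return manifest
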