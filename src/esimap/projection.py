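"""Project grid fields onto atoms and residues for surface coloring.

Each atom samples the field by trilinear interpolation at a point displaced
radially outward from the structure's geometric center, a stated offset
beyond the atom's van der Waals radius — i.e. the field value "just outside
the surface", which is what molecular-surface colorings display. Per-residue
values aggregate the residue's atoms and are written as UCSF Chimera
attribute files, as a PDB with the value in the B-factor column, and as CSV.

The conventional color thresholds for the output maps are exposed as
metadata: potential maps saturate at +/-5 kT/e, isopotential contours are
drawn at +/-1.5 kT/e, mutation/ensemble perturbation maps span ESI
0.5-0.7-0.9 and homologue-family ESI maps span -0.10-0.15-0.40.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .pb import ScalarField
from .structure_io import Structure

__all__ = ["AtomProjection", "project_to_atoms", "write_attribute_file",
           "read_attribute_file", "write_bfactor_pdb", "COLOR_SCALES"]

COLOR_SCALES = {
    "potential_surface": (-5.0, 0.0, 5.0),      # kT/e
    "isopotential": (-1.5, 1.5),                # kT/e contour levels
    "esi_perturbation": (0.5, 0.7, 0.9),        # alanine-scan / ensemble maps
    "esi_homologues": (-0.10, 0.15, 0.40),      # homologue-family maps
}


@dataclass
class AtomProjection:
    """Sampled field value per atom plus per-residue aggregates."""

    structure: Structure
    atom_values: np.ndarray
    residue_table: pd.DataFrame  # chain, resnum, resname, value
    offset: float
    unit: str

    def __post_init__(self) -> None:
        if len(self.atom_values) != len(self.structure.atoms):
            raise ValueError("one value per atom required")


def project_to_atoms(
    f: ScalarField,
    s: Structure,
    offset: float = 1.4,
    aggregate: str = "mean",
) -> AtomProjection:
    """Sample a field just outside each atom's vdW surface.

    The sampling point is atom_position + u * (r_vdw + offset) where u is
    the unit vector from the structure's geometric center through the atom
    (atoms exactly at the center sample in place). Per-residue value is the
    mean (or median) over the residue's atoms. Errors if a sampling point
    leaves the grid.
    """
    center = s.center
    coords = s.coords
    vec = coords - center
    norm = np.linalg.norm(vec, axis=1)
    unit_v = np.divide(vec, norm[:, None], out=np.zeros_like(vec),
                       where=norm[:, None] > 1e-12)
    samples = coords + unit_v * (s.radii + offset)[:, None]

    frac = f.spec.world_to_grid(samples)
    n = np.asarray(f.spec.points)
    if np.any(frac < 0) or np.any(frac > n - 1):
        bad = int(np.where((frac < 0) | (frac > n - 1))[0][0])
        raise ValueError(
            f"sampling point for atom {s.atoms[bad].serial} lies outside the grid")
    atom_values = map_coordinates(f.values, frac.T, order=1, mode="nearest")

    agg = np.median if aggregate == "median" else np.mean
    rows = []
    i = 0
    for (chain, resnum), res_atoms in s.residues():
        vals = atom_values[i:i + len(res_atoms)]
        rows.append({"chain": chain, "resnum": resnum,
                     "resname": res_atoms[0].residue_name,
                     "value": float(agg(vals))})
        i += len(res_atoms)
    table = pd.DataFrame(rows)
    return AtomProjection(s, atom_values, table, offset=offset, unit=f.unit)


def write_attribute_file(a: AtomProjection, path, attribute: str = "esi") -> None:
    """Write a Chimera-style per-residue attribute file (and companion CSV)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"attribute: {attribute}\n")
        fh.write("match mode: 1-to-1\n")
        fh.write("recipient: residues\n")
        for row in a.residue_table.itertuples():
            fh.write(f"\t:{row.resnum}.{row.chain}\t{row.value:.6f}\n")
    a.residue_table.to_csv(path.with_suffix(".csv"), index=False)


def read_attribute_file(path) -> pd.DataFrame:
    """Re-parse a Chimera attribute file into (chain, resnum, value) rows."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.startswith("\t:"):
                continue
            spec_part, value = line.strip().split("\t")
            resnum, chain = spec_part.lstrip(":").split(".")
            rows.append({"chain": chain, "resnum": int(resnum),
                         "value": float(value)})
    if not rows:
        raise ValueError(f"no attribute lines found in {path}")
    return pd.DataFrame(rows)


def write_bfactor_pdb(a: AtomProjection, path, warn_clamp: bool = True) -> None:
    """Write the structure with per-atom values in the B-factor column.

    PDB's fixed-width B-factor field caps values at +/-999.99; out-of-range
    values are clamped (with a warning).
    """
    import warnings

    vals = np.clip(a.atom_values, -999.99, 999.99)
    if warn_clamp and np.any(vals != a.atom_values):
        warnings.warn("projection values clamped to +/-999.99 for the B-factor "
                      "column", stacklevel=2)
    s = a.structure.copy()
    with open(path, "w") as fh:
        for i, (atom, v) in enumerate(zip(s.atoms, vals), start=1):
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            fh.write(
                f"ATOM  {i:5d} {name:<4s} {atom.residue_name:<3s} "
                f"{atom.chain_id[:1]:1s}{atom.residue_number:4d}    "
                f"{atom.position[0]:8.3f}{atom.position[1]:8.3f}"
                f"{atom.position[2]:8.3f}{1.00:6.2f}{v:6.2f}          "
                f"{atom.element.upper():>2s}\n")
        fh.write("END\n")
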