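"""Structure input/output and charge/radius parameterization.

Reads PDB files (via biotite), assigns formal charges from a model-pKa
titration scheme at a stated pH, places those charges on the canonical
charged-group atoms, assigns per-element van der Waals radii, and writes
PQR files (whitespace-separated PDB dialect with charge and radius in
place of occupancy/B-factor).

The charge model is deliberately a monopole bookkeeping model, not a force
field: each titratable residue carries an integer formal charge (the
majority protonation state at the given pH) distributed over its charged
group. Electrostatic similarity analysis depends on where the monopoles
sit, not on sub-unit partial-charge detail.
"""

from __future__ import annotations

import logging
import urllib.request
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Structure",
    "TitrationModel",
    "ParameterSet",
    "read_pdb",
    "write_pdb",
    "read_pqr",
    "write_pqr",
    "assign_parameters",
    "net_charge",
    "fetch_pdb",
]


@dataclass
class Atom:
    """One atom: identity, position (Angstrom), charge (e), radius (Angstrom)."""

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_number: int
    position: np.ndarray
    charge: float = 0.0
    radius: float = 0.0
    element: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        if self.radius < 0:
            raise ValueError(f"atom {self.serial}: negative radius")
        if not self.element:
            self.element = _guess_element(self.name)


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    if not stripped:
        return ""
    if stripped[0].isdigit():  # e.g. 1HB
        stripped = stripped.lstrip("0123456789")
    # two-letter elements that occur in standard residues / common hetero groups
    if stripped[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "NA", "MN", "CU"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


@dataclass
class Structure:
    """An ordered collection of atoms with a label.

    Residues are contiguous runs of (chain_id, residue_number).
    """

    atoms: list[Atom]
    label: str = ""
    parameters_assigned: bool = False

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("Structure must contain at least one atom")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms])

    @property
    def center(self) -> np.ndarray:
        """Geometric center (mean of atomic positions)."""
        return self.coords.mean(axis=0)

    def residues(self) -> list[tuple[tuple[str, int], list[Atom]]]:
        """Contiguous (chain_id, residue_number) runs, in atom order."""
        runs: list[tuple[tuple[str, int], list[Atom]]] = []
        for atom in self.atoms:
            key = (atom.chain_id, atom.residue_number)
            if runs and runs[-1][0] == key:
                runs[-1][1].append(atom)
            else:
                runs.append((key, [atom]))
        return runs

    def copy(self, label: str | None = None) -> "Structure":
        atoms = [replace(a, position=a.position.copy()) for a in self.atoms]
        return Structure(atoms, label if label is not None else self.label,
                         self.parameters_assigned)


# residue types treated as acids (deprotonation yields -1) / bases (+1)
_ACIDS = {"ASP", "GLU", "CYS", "TYR"}
_BASES = {"LYS", "ARG", "HIS"}

_DEFAULT_PKA = {
    "ASP": 3.65,
    "GLU": 4.25,
    "LYS": 10.53,
    "ARG": 12.48,
    "HIS": 6.30,
    "CYS": 8.3,
    "TYR": 10.1,
    "NTERM": 8.0,
    "CTERM": 3.1,
}

_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


@dataclass(frozen=True)
class TitrationModel:
    """Integer formal charges from model pKa values at a fixed pH.

    A titratable group carries its charged state when the pH is on the
    charged side of its model pKa (majority protonation; no fractional
    charges). Exactly at the pKa the group is left neutral. Chain termini
    are charged by default (+1 N-terminus, -1 C-terminus); for single
    chains they cancel in the net charge.
    """

    pH: float = 7.4
    pka: dict = field(default_factory=lambda: dict(_DEFAULT_PKA))
    termini_charged: bool = True
    cys_titratable: bool = False  # disulfide-agnostic default: neutral CYS

    def formal_charge(self, residue_name: str) -> int:
        """Side-chain formal charge of a residue type at this pH."""
        res = residue_name.upper()
        if res == "CYS" and not self.cys_titratable:
            return 0
        if res in _ACIDS:
            return -1 if self.pH > self.pka[res] else 0
        if res in _BASES:
            return +1 if self.pH < self.pka[res] else 0
        return 0

    def nterm_charge(self) -> int:
        if not self.termini_charged:
            return 0
        return +1 if self.pH < self.pka["NTERM"] else 0

    def cterm_charge(self) -> int:
        if not self.termini_charged:
            return 0
        return -1 if self.pH > self.pka["CTERM"] else 0


# canonical charged-group atoms; formal charge split evenly across those present
_CHARGE_SITES = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "LYS": ("NZ",),
    "ARG": ("NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
    "CYS": ("SG",),
    "TYR": ("OH",),
}

# Bondi van der Waals radii (Angstrom) by element
_BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "SE": 1.90,
}
_DEFAULT_RADIUS = 1.70


@dataclass(frozen=True)
class ParameterSet:
    """Charge-placement and radius rules.

    Charges: the residue formal charge is split evenly over the canonical
    charged-group atoms that exist in the residue (Asp OD1/OD2 at -0.5 each,
    Lys NZ at +1, ...). If a pared-down residue (e.g. a CB-only pseudo
    residue from the fixture generator) lacks those atoms, the whole formal
    charge is placed on CB, falling back to CA — monopole position is what
    matters downstream. Radii: per-element Bondi values.
    """

    charge_sites: dict = field(default_factory=lambda: dict(_CHARGE_SITES))
    radii: dict = field(default_factory=lambda: dict(_BONDI_RADII))
    default_radius: float = _DEFAULT_RADIUS

    def radius_for(self, element: str) -> float:
        return self.radii.get(element.upper(), self.default_radius)


def read_pdb(path, model_index: int | str = 1):
    """Read a PDB file into one Structure or, for model_index='all', a list.

    MODEL/ENDMDL blocks are honored; altloc conflicts resolve to the
    highest-occupancy conformer (first seen on ties). model_index is
    1-based as in the PDB format.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    try:
        pdb_file = PDBFile.read(str(path))
    except Exception as exc:  # noqa: BLE001 - surface as a uniform error
        raise IOError(f"unreadable PDB file {path}: {exc}") from exc

    n_models = pdb_file.get_model_count()
    if n_models == 0:
        raise ValueError(f"zero atoms parsed from {path}")

    def _convert(model: int) -> Structure:
        arr = pdb_file.get_structure(model=model, altloc="occupancy")
        if arr.array_length() == 0:
            raise ValueError(f"zero atoms parsed from {path}")
        atoms = []
        for i in range(arr.array_length()):
            atoms.append(Atom(
                serial=i + 1,
                name=str(arr.atom_name[i]),
                residue_name=str(arr.res_name[i]),
                chain_id=str(arr.chain_id[i]),
                residue_number=int(arr.res_id[i]),
                position=np.asarray(arr.coord[i], dtype=float),
                element=str(arr.element[i]).capitalize(),
            ))
        label = path.stem if model == 1 and n_models == 1 else f"{path.stem}_m{model}"
        return Structure(atoms, label=label)

    if model_index == "all":
        return [_convert(m) for m in range(1, n_models + 1)]
    return _convert(int(model_index))


def write_pdb(s: Structure, path) -> None:
    """Write fixed-column PDB ATOM records (coordinates to 0.001 A)."""
    with open(path, "w") as fh:
        for i, a in enumerate(s.atoms, start=1):
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            fh.write(
                f"ATOM  {i:5d} {name:<4s} {a.residue_name:<3s} {a.chain_id[:1]:1s}"
                f"{a.residue_number:4d}    "
                f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {a.element.upper():>2s}\n"
            )
        fh.write("END\n")


def write_pqr(s: Structure, path) -> None:
    """Write a whitespace-separated PQR file (x y z charge radius)."""
    if not s.parameters_assigned:
        raise ValueError("cannot write PQR: parameters not assigned")
    with open(path, "w") as fh:
        for i, a in enumerate(s.atoms, start=1):
            fh.write(
                f"ATOM {i:6d} {a.name:<4s} {a.residue_name:<4s} {a.chain_id:1s} "
                f"{a.residue_number:5d} {a.position[0]:10.4f} {a.position[1]:10.4f} "
                f"{a.position[2]:10.4f} {a.charge:8.4f} {a.radius:7.4f}\n"
            )
        fh.write("END\n")


def read_pqr(path) -> Structure:
    """Read a whitespace-separated PQR file written by :func:`write_pqr`."""
    atoms = []
    path = Path(path)
    with open(path) as fh:
        for line in fh:
            if not line.startswith(("ATOM", "HETATM")):
                continue
            parts = line.split()
            if len(parts) < 10:
                raise ValueError(f"malformed PQR line: {line!r}")
            atoms.append(Atom(
                serial=int(parts[1]),
                name=parts[2],
                residue_name=parts[3],
                chain_id=parts[4],
                residue_number=int(parts[5]),
                position=np.array([float(parts[6]), float(parts[7]), float(parts[8])]),
                charge=float(parts[9]),
                radius=float(parts[10]) if len(parts) > 10 else 0.0,
            ))
    if not atoms:
        raise ValueError(f"zero atoms parsed from {path}")
    out = Structure(atoms, label=path.stem)
    out.parameters_assigned = True
    return out


def assign_parameters(
    s: Structure,
    titration: TitrationModel | None = None,
    params: ParameterSet | None = None,
) -> Structure:
    """Assign charges and radii; returns a new Structure (idempotent).

    Every atom gets a Bondi radius; titratable residues get their formal
    charge on the canonical charged group; chain termini (first/last residue
    of each chain run, when enabled) get +1/-1 on N / OXT-or-O. Unknown
    residues get zero charge and are logged.
    """
    titration = titration or TitrationModel()
    params = params or ParameterSet()
    out = s.copy()

    for atom in out.atoms:
        atom.charge = 0.0
        atom.radius = params.radius_for(atom.element)

    runs = out.residues()
    # chain boundaries: first/last residue of each contiguous chain_id block
    chain_of = [key[0] for key, _ in runs]
    for idx, ((_, _), res_atoms) in enumerate(runs):
        res_name = res_atoms[0].residue_name.upper()
        if res_name not in _STANDARD_RESIDUES:
            logger.warning("unknown residue %s: assigned zero charge", res_name)
            continue
        q = titration.formal_charge(res_name)
        if q != 0:
            _place_charge(res_atoms, res_name, q, params)
        is_chain_start = idx == 0 or chain_of[idx - 1] != chain_of[idx]
        is_chain_end = idx == len(runs) - 1 or chain_of[idx + 1] != chain_of[idx]
        if is_chain_start and titration.nterm_charge():
            _add_on(res_atoms, ("N",), titration.nterm_charge())
        if is_chain_end and titration.cterm_charge():
            _add_on(res_atoms, ("OXT", "O"), titration.cterm_charge())

    out.parameters_assigned = True
    return out


def _place_charge(res_atoms, res_name: str, q: int, params: ParameterSet) -> None:
    sites = [a for a in res_atoms if a.name in params.charge_sites.get(res_name, ())]
    if not sites:
        sites = [a for a in res_atoms if a.name == "CB"] or \
                [a for a in res_atoms if a.name == "CA"] or [res_atoms[-1]]
        sites = sites[:1]
    for a in sites:
        a.charge += q / len(sites)


def _add_on(res_atoms, names: tuple, q: int) -> None:
    for name in names:
        for a in res_atoms:
            if a.name == name:
                a.charge += q
                return
    res_atoms[0].charge += q  # degenerate residue: keep the books balanced


def net_charge(s: Structure) -> tuple[int, float]:
    """Net molecular charge: (nearest integer, raw float sum of atom charges)."""
    if not s.parameters_assigned:
        raise ValueError("parameters not assigned; call assign_parameters first")
    raw = float(s.charges.sum())
    return int(round(raw)), raw


def charged_residues(s: Structure, titration: TitrationModel | None = None):
    """Residues with nonzero side-chain formal charge at the model's pH.

    Returns a list of ((chain_id, residue_number), residue_name, formal_charge).
    """
    titration = titration or TitrationModel()
    out = []
    for key, res_atoms in s.residues():
        res_name = res_atoms[0].residue_name.upper()
        q = titration.formal_charge(res_name)
        if q != 0:
            out.append((key, res_name, q))
    return out


def fetch_pdb(pdb_id: str, cache_dir) -> Path:
    """Download a PDB entry from RCSB into cache_dir (skipped if cached).

    Requires network access; raises IOError when offline.
    """
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    target = cache_dir / f"{pdb_id.upper()}.pdb"
    if target.exists():
        return target
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    try:
        with urllib.request.urlopen(url, timeout=30) as resp:
            target.write_bytes(resp.read())
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"could not fetch {pdb_id} from RCSB: {exc}") from exc
    return target
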