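"""Perturbed-structure families: alanine scans, ensembles, homologue sets.

A perturbation family is a parent structure plus N member structures whose
electrostatic potentials will all be solved on one shared grid and compared
back to the parent. Members come from three sources: single-position
alanine-scan charge neutralizations, conformational snapshots from a
multi-model PDB, or a directory of homologue models.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

from .structure_io import (
    ParameterSet,
    Structure,
    TitrationModel,
    assign_parameters,
    charged_residues,
    net_charge,
    read_pdb,
    write_pqr,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PerturbationFamily",
    "alanine_scan",
    "load_ensemble",
    "load_homologue_family",
    "write_family",
]

_ONE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

# atoms kept when a side chain is truncated to alanine
_ALA_KEEP = {"N", "CA", "C", "O", "OXT", "CB", "H", "HA", "H1", "H2", "H3"}


@dataclass
class PerturbationFamily:
    """Parent structure plus N perturbed members sharing one grid."""

    parent: Structure
    members: list[Structure]
    member_labels: list[str]
    kind: str  # alanine_scan | ensemble | homologues

    def __post_init__(self) -> None:
        if len(self.members) != len(self.member_labels):
            raise ValueError("members and member_labels length mismatch")

    @property
    def n(self) -> int:
        return len(self.members)


def alanine_scan(
    parent: Structure,
    titration: TitrationModel | None = None,
    params: ParameterSet | None = None,
) -> PerturbationFamily:
    """One member per charged residue, that residue neutralized to alanine.

    A residue counts as charged when its side chain has nonzero formal
    charge at the titration model's pH (Asp/Glu/Lys/Arg at pH 7.4; His is
    neutral there and excluded). In each member the target residue's
    side-chain atoms beyond CB are removed, the residue is renamed ALA,
    and parameters are re-assigned, so the member's net charge is the
    parent's minus the target's formal charge. Backbone atoms (and any
    terminal charge the residue carries) are untouched.
    """
    titration = titration or TitrationModel()
    params = params or ParameterSet()
    if not parent.parameters_assigned:
        parent = assign_parameters(parent, titration, params)

    targets = charged_residues(parent, titration)
    if not targets:
        logger.warning("alanine scan of %s: no charged residues", parent.label)
        return PerturbationFamily(parent, [], [], kind="alanine_scan")

    members, labels = [], []
    for (chain_id, res_num), res_name, _q in targets:
        atoms = []
        for a in parent.atoms:
            if a.chain_id == chain_id and a.residue_number == res_num:
                if a.name not in _ALA_KEEP:
                    continue  # truncate side chain beyond CB
                a = _as_alanine(a)
            atoms.append(a)
        label = f"{_ONE_LETTER.get(res_name, 'X')}{res_num}A"
        member = Structure(atoms, label=f"{parent.label}_{label}")
        member = assign_parameters(member, titration, params)
        members.append(member)
        labels.append(label)
    return PerturbationFamily(parent, members, labels, kind="alanine_scan")


def _as_alanine(atom):
    from dataclasses import replace

    return replace(atom, residue_name="ALA", position=atom.position.copy())


def load_ensemble(
    path,
    parent_index: int = 1,
    external_parent: Structure | None = None,
    titration: TitrationModel | None = None,
    params: ParameterSet | None = None,
) -> PerturbationFamily:
    """Load a multi-model PDB as an ensemble family.

    The designated model (1-based; default the first) is the parent and the
    remaining models are members, unless an external parent structure is
    given, in which case all models become members. Models must share one
    atom count.
    """
    models = read_pdb(path, model_index="all")
    if len(models) < 2 and external_parent is None:
        raise ValueError(f"ensemble file {path} has fewer than 2 models")
    counts = {len(m) for m in models}
    if len(counts) != 1:
        raise ValueError(f"mismatched atom counts across models: {sorted(counts)}")

    models = [assign_parameters(m, titration, params) for m in models]
    if external_parent is not None:
        parent = external_parent
        if not parent.parameters_assigned:
            parent = assign_parameters(parent, titration, params)
        members = models
    else:
        parent = models[parent_index - 1]
        members = [m for i, m in enumerate(models) if i != parent_index - 1]
    labels = [f"snapshot_{i:03d}" for i in range(1, len(members) + 1)]
    return PerturbationFamily(parent, members, labels, kind="ensemble")


def load_homologue_family(
    parent: Structure,
    member_dir,
    titration: TitrationModel | None = None,
    params: ParameterSet | None = None,
) -> PerturbationFamily:
    """Load a directory of homologue PDB models as a family.

    Members need not share atom counts with the parent — downstream the
    potentials, not the atoms, are compared. Files that fail to parse as
    PDB are skipped with a log message.
    """
    member_dir = Path(member_dir)
    if not parent.parameters_assigned:
        parent = assign_parameters(parent, titration, params)
    members, labels = [], []
    for f in sorted(member_dir.glob("*")):
        if not f.is_file() or f.suffix.lower() not in (".pdb", ".ent"):
            if f.is_file():
                logger.info("skipping non-PDB file %s", f.name)
            continue
        try:
            s = read_pdb(f)
        except (IOError, ValueError) as exc:
            logger.warning("skipping unparseable %s: %s", f.name, exc)
            continue
        members.append(assign_parameters(s, titration, params))
        labels.append(f.stem)
    if not members:
        raise ValueError(f"no PDB models found in {member_dir}")
    return PerturbationFamily(parent, members, labels, kind="homologues")


def write_family(family: PerturbationFamily, out_dir) -> Path:
    """Write the family as PQR files plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "kind", "role", "net_charge", "file"])
        pq = out_dir / "parent.pqr"
        write_pqr(family.parent, pq)
        writer.writerow([family.parent.label, family.kind, "parent",
                         net_charge(family.parent)[0], pq.name])
        for label, member in zip(family.member_labels, family.members):
            f = out_dir / f"{label}.pqr"
            write_pqr(member, f)
            writer.writerow([label, family.kind, "member",
                             net_charge(member)[0], f.name])
    return manifest
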