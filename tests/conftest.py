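import pytest

from esimap import (
    PBProblem,
    TitrationModel,
    ToySpec,
    alanine_scan,
    assign_parameters,
    build_gridspec,
    esi_field,
    make_hotspot_fixture,
    make_synthetic_family,
    make_toy_structure,
    solve_lpbe,
)


@pytest.fixture
def tripeptide():
    """D-K-H linear toy peptide: formal charges -1, +1, 0 at pH 7.4."""
    s = make_toy_structure(ToySpec(3, {1: -1, 2: +1}, label="dkh"),
                           residue_names={1: "ASP", 2: "LYS", 3: "HIS"})
    return assign_parameters(s, TitrationModel(termini_charged=False))


def write_multimodel_pdb(structures, path):
    """Write a multi-model PDB from same-topology structures."""
    with open(path, "w") as fh:
        for m, s in enumerate(structures, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for i, a in enumerate(s.atoms, start=1):
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                fh.write(
                    f"ATOM  {i:5d} {name:<4s} {a.residue_name:<3s} "
                    f"{a.chain_id[:1]:1s}{a.residue_number:4d}    "
                    f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {a.element.upper():>2s}\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


@pytest.fixture(scope="session")
def hotspot_scan_esi():
    """Alanine-scan ESI of the hot-spot fixture at 65^3 (shared; ~11 solves)."""
    hs = make_hotspot_fixture(cluster_size=5, n_dispersed=5, seed=0)
    cluster, dispersed = hs.cluster_residues, hs.dispersed_residues
    parent = assign_parameters(hs)
    family = alanine_scan(parent)
    spec = build_gridspec(family.parent, points=(65, 65, 65),
                          lengths=(116.0, 116.0, 116.0))
    phi_parent = solve_lpbe(PBProblem(family.parent, spec))
    members = [solve_lpbe(PBProblem(m, spec)) for m in family.members]
    esi = esi_field(phi_parent, members)
    return {"family": family, "esi": esi, "cluster": cluster,
            "dispersed": dispersed, "phi_parent": phi_parent,
            "phi_members": members}


@pytest.fixture(scope="session")
def homologue_family_esi():
    """Synthetic 23-member homologue family ESI at 65^3 (shared; 24 solves)."""
    parent, members, aln = make_synthetic_family(
        23, conserved_columns=[1, 3, 5, 7], scrambled_columns=[2, 4, 6, 8],
        seed=11, n_residues=20, radius=16.0)
    parent = assign_parameters(parent)
    members = [assign_parameters(m) for m in members]
    spec = build_gridspec(parent, points=(65, 65, 65), lengths=(60.0, 60.0, 60.0))
    phi_parent = solve_lpbe(PBProblem(parent, spec))
    phis = [solve_lpbe(PBProblem(m, spec)) for m in members]
    esi = esi_field(phi_parent, phis)
    return {"parent": parent, "members": members, "alignment": aln, "esi": esi}
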