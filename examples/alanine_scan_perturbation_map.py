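"""Alanine-scan perturbation map: recover an electrostatic hot-spot.

Builds the hot-spot fixture (a tight cluster of five acidic residues plus
five isolated acidic residues on a 44 A sphere scaffold), runs the
computational alanine scan (10 LPBE solves at 65^3 plus the parent), forms
the cumulative ESI field against the parent potential, and compares the
mean ESI in surface shells around the cluster vs the isolated charges.
Takes about a minute on one CPU.
"""

from esimap import (
    PBProblem,
    alanine_scan,
    assign_parameters,
    build_gridspec,
    esi_field,
    make_hotspot_fixture,
    region_summary,
    solve_lpbe,
)

hs = make_hotspot_fixture(cluster_size=5, n_dispersed=5, seed=0)
cluster_resnums, dispersed_resnums = hs.cluster_residues, hs.dispersed_residues
parent = assign_parameters(hs)
family = alanine_scan(parent)
print(f"alanine scan: {family.n} charged residues -> {family.n} mutants")

spec = build_gridspec(family.parent, points=(65, 65, 65),
                      lengths=(116.0, 116.0, 116.0))
phi_parent = solve_lpbe(PBProblem(family.parent, spec))
phi_members = [solve_lpbe(PBProblem(m, spec)) for m in family.members]
esi = esi_field(phi_parent, phi_members)


def cb_atoms(resnums):
    return [i for i, a in enumerate(family.parent.atoms)
            if a.residue_number in resnums and a.name == "CB"]


cluster = region_summary(esi, family.parent, cb_atoms(cluster_resnums))
dispersed = region_summary(esi, family.parent, cb_atoms(dispersed_resnums))
print(f"mean shell ESI, 5-charge cluster:   {cluster['mean']:.4f}")
print(f"mean shell ESI, isolated charges:   {dispersed['mean']:.4f}")
print(f"contrast: {cluster['mean'] - dispersed['mean']:+.4f}")
print("The cluster's potential resists single-charge removal (each mutation")
print("deletes only ~1/5 of the local source), so its ESI stays higher:")
print("that perturbation resistance is the electrostatic hot-spot signature.")
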