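# esimap

Electrostatic perturbation maps for protein surfaces: locate electrostatic
"hot-spots" — clusters of like-charged residues whose potential resists
perturbation — by comparing families of continuum-electrostatics potentials
against a parent structure, and corroborate them with charge-position
conservation analysis of sequence alignments.

The package was built around the complement C3d–CR2 system (C3d attaches
covalently to pathogen surfaces and binds complement receptor 2 on B cells;
both functional sites sit on charged surface patches), but every stage is
generic: any parent structure plus any family of perturbed structures —
computational alanine-scan mutants, molecular-dynamics snapshots, or
homology models of related species — can be mapped the same way.

## Method

1. **Structure preparation** (`structure_io`): formal charges from model
   pKa values at a stated pH (default 7.4: Asp/Glu −1, Lys/Arg +1, His 0),
   placed on the canonical charged-group atoms; Bondi van der Waals radii;
   PQR output.
2. **Perturbation families** (`perturbation`): a computational alanine scan
   (each charged residue neutralized one at a time, side chain truncated at
   Cβ), a conformational ensemble from a multi-model PDB, or a directory of
   homologue models.
3. **Electrostatic potentials** (`pb`): a finite-difference linearized
   Poisson–Boltzmann solver,

   ∇·(ε∇φ) − κ̄²φ = −4π l_B ρ,

   with φ in kT/e, a two-valued dielectric map (protein 20 / solvent 78.57)
   bounded by the probe-rolled (1.4 Å) molecular surface, 0 mM ionic
   strength by default, Debye–Hückel boundary conditions, and one shared
   grid centered on the parent so that all fields are node-aligned
   (defaults 129×129×129; the C3d/CR2 study grids are 98×116×116 Å and
   102×78×116 Å).
4. **Electrostatic similarity index** (`esi`): at each grid point the local
   Hodgkin index of the parent potential φ_A against each family member
   φ_B,n, averaged over the N members:

   ESI(i,j,k) = (1/N) Σₙ 2 φ_A φ_B,n / (φ_A² + φ_B,n²) ∈ [−1, 1].

   High-ESI surface regions are perturbation-resistant — the hot-spot
   signature. Surface-shell statistics quantify regions of interest.
5. **Surface projection** (`projection`): fields sampled just outside each
   atom's vdW surface, aggregated per residue, written as UCSF Chimera
   attribute files / B-factor PDBs / CSV.
6. **Sequence-side analysis** (`seqcharge`): pairwise identity and
   like-charge-position matrices (positions where both sequences have K/R
   or both have D/E) from an aligned FASTA, optionally restricted to a
   functional face defined by the x-coordinate rule (any atom at
   x ≤ mean(x)−5 Å vs x > mean(x)+5 Å), and complete-linkage hierarchical
   clustering with Newick output.
7. **Synthetic fixtures** (`fixtures`): deterministic pseudo-structures,
   hot-spot scaffolds and homologue families with controlled
   charge-position conservation, so the whole pipeline is testable with no
   downloads.

## Worked example

`python examples/alanine_scan_perturbation_map.py` builds a scaffold with a
five-residue acidic cluster plus five isolated acidic residues, runs the
alanine scan and the LPBE solves at 65³, and prints:

```
alanine scan: 10 charged residues -> 10 mutants
mean shell ESI, 5-charge cluster:   0.9832
mean shell ESI, isolated charges:   0.9762
contrast: +0.0070
```

The cluster's surface shell keeps a higher ESI than the isolated charges'
shells: removing one of five co-located charges perturbs the local
potential fractionally less than removing a lone charge, which is exactly
the perturbation resistance that marks an electrostatic hot-spot.

Other examples: `examples/prepare_structure.py` (charge assignment and net
charge), `examples/homologue_family_esi.py` (family ESI projected onto the
parent surface), `examples/charge_position_clustering.py` (face-restricted
charge clustering separating two lineages).

A command-line pipeline mirrors the library
(`esimap prep|perturb|solve|esi|project|seqclust|fixtures`), with files as
interfaces and a JSON manifest per run.

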