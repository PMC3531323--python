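# Methods

## Model

The package computes electrostatic perturbation maps: a parent structure's
linearized Poisson–Boltzmann (LPB) potential φ_A is compared, grid point by
grid point, against the potentials φ_B,n of N perturbed structures, and the
similarity is averaged over the family,

    ESI(i,j,k) = (1/N) Σₙ s(φ_A(i,j,k), φ_B,n(i,j,k)),
    s(a,b) = 2ab / (a² + b²).

s is the local (per-point) Hodgkin similarity index: +1 for identical
values, 0 when one value vanishes, −1 for sign-flipped values, and
invariant when both arguments are scaled by a common positive factor. The
per-point index is bounded by [−1, 1] and so is the ESI, which matches the
signed ranges such maps take in practice (homologue maps dipping below 0,
perturbation maps concentrated in 0.5–0.9). Where both potentials are
negligible (|a|, |b| < ε₀ = 1e−4 kT/e, configurable) the point is counted
as perfectly similar; this prevents far-field 0/0 noise from contaminating
the map. The ESI averages member-vs-parent similarities only; it is not a
full pairwise similarity matrix of the family.

A surface region whose ESI stays high under a family of charge deletions
(computational alanine scan) or conformational perturbations (ensemble) is
an electrostatic hot-spot: several co-located like charges each contribute
a fraction of the local potential, so deleting any one of them changes the
field there fractionally less than deleting an isolated charge. For small
fractional loss f the local index behaves as s ≈ 1 − f²/2, so a charge
shared k ways incurs roughly 1/k² of the penalty per mutation — the
quadratic mechanism the maps exploit.

## LPB solver

Equation: ∇·(ε∇φ) − κ̄²φ = −4π l_B ρ on a rectilinear grid, φ in kT/e,
lengths in Å, charges in e. l_B = e²/(4πε₀k_BT) ≈ 560.5 Å at 298.15 K
absorbs the unit conversion. Discretization and numerical choices:

- Symmetric 7-point stencil; face dielectrics are harmonic means of the two
  node values, the standard finite-difference treatment of a discontinuous
  coefficient.
- Charges spread to the 8 enclosing nodes by trilinear weights (total grid
  charge equals molecular charge to ~1e−15 relative).
- Dielectric map: two-valued (protein ε_in = 20, solvent ε_out = 78.57).
  The protein volume is the probe-rolled molecular (solvent-excluded)
  volume, realized on the grid as a morphological closing: nodes within
  (r_atom + r_probe) of an atom center form the probe-dilated volume, and a
  Euclidean distance transform erodes it back by r_probe, leaving the vdW
  interior plus all pockets a 1.4 Å probe cannot reach. ε_in = 20 (rather
  than the classical 2) reflects that charge-mutation energetics of highly
  charged proteins are better reproduced by a soft interior.
- Ionic screening: κ̄² = 8π l_B n (Å⁻²) for a 1:1 electrolyte with number
  density n per species, zeroed inside the vdW + 2.0 Å Stern layer, and
  identically zero at the 0 mM default (chosen because charge-perturbation
  similarity is computed more robustly without salt; the solver supports
  any ionic strength and reproduces the 7.86 Å Debye length at 150 mM).
- Boundary condition: Dirichlet values from the sum of single-sphere
  Debye–Hückel potentials of all charges (screened Coulomb of each charge,
  plain Coulomb/ε_s at 0 mM).
- Linear solve: Jacobi-preconditioned conjugate gradients on the symmetric
  positive-definite system, relative residual ≤ 1e−6, max 10 000
  iterations; non-convergence raises with the residual. The operator is
  linear, so superposed charge sets superpose their potentials (tested).
- One grid per family, centered on the parent's geometric center, reused
  verbatim for every member so fields are node-aligned for the ESI. Grids
  must be odd-sized and ≥ 33 points per axis; defaults are 129³ with the
  study lengths 98×116×116 Å (C3d) / 102×78×116 Å (CR2).

Verification: against the analytic Coulomb solution in a homogeneous
medium, the solver is within 2% (max, shell 4h…L/4) at 65³, and within
2.7% against the screened Debye–Hückel form at 150 mM; on a fixed physical
shell (5–10 Å) the Coulomb error falls 0.0198 → 0.0041 → 0.0010 from 33³ to
65³ to 129³, consistent with O(h²).

## Structure preparation

Formal charges only, no force field: each titratable residue carries the
integer charge of its majority protonation state at the given pH, from
model pKa values (Asp 3.65, Glu 4.25, Lys 10.53, Arg 12.48, His 6.30,
Cys 8.3, Tyr 10.1, N-term 8.0, C-term 3.1). The charge is split over the
canonical charged-group atoms (Asp OD1/OD2 −0.5 each, Glu OE1/OE2, Lys NZ,
Arg NH1/NH2, termini on N / OXT-or-O); for pared-down pseudo-residues the
fallback is CB, then CA — the similarity analysis depends on monopole
placement, not sub-group charge detail. Cys is neutral by default
(disulfide-agnostic). Termini are charged by default and cancel in single
chains. Radii are per-element Bondi values. Alanine-scan mutants truncate
the target side chain beyond Cβ without rebuilding geometry and re-assign
parameters, so each mutant's net charge is the parent's minus the target's
formal charge.

Exact at-the-pKa pH leaves a group neutral (a 50/50 state has no majority);
the choice only matters for pH set exactly to a table value.

## Synthetic data generator

The fixture generator produces pseudo-proteins carrying exactly what the
method consumes: monopole positions, radii, and residue identities. Each
residue is a five-atom unit (N, CA, C, O, CB) on a linear chain (3.8 Å CA
spacing) or a sphere-surface scatter; charges land on CB.

- **Hot-spot scaffold**: five acidic residues in a surface patch ≤ 8 Å
  across plus five isolated acidic residues ≥ 15 Å apart (in practice
  ~45 Å), on a 44 Å sphere. The radius was chosen so the isolated charges
  are genuinely isolated: all ten charges carry the same sign, so their
  coherent background potential must be kept subdominant to each charge's
  own near-field for "isolated" to mean anything; the resulting 116 Å box
  matches the scale of the real single-domain grids. The seed applies only
  a rigid rotation (all distances, hence all physics, invariant).
- **Homologue families**: members share one scaffold; charges at conserved
  columns are drawn once (sign and D/E vs K/R letter) and repeated across
  members, scrambled columns are redrawn per member. A gapless alignment
  matching the structures is emitted alongside.
- **Two-lineage clustering fixture**: group 1 conserves one charge pattern
  at every face column; group 2 emulates a second lineage — a sign-flipped
  pattern conserved at half the face columns, the rest scrambled per
  member. Pure per-member noise in group 2 would make its intra-group
  distances statistically identical to its distance from group 1 under the
  count normalization, which no clustering can separate; a partially
  conserved second pattern is also the more faithful model of a divergent
  lineage.

What the fixtures do not emulate: real rotamer geometry, mixed-sign charge
texture of natural surfaces, backbone flexibility, and sequence gaps.
Passing tests therefore demonstrate the machinery (solver accuracy, ESI
algebra, scan bookkeeping, clustering behavior) under controlled
electrostatics, not predictive performance on real proteins.

## Sequence-side analysis

Identity: matching non-gap pairs over columns where at least one row is
non-gap. Charge similarity: count of columns where both rows ∈ {K,R} or
both ∈ {D,E}; gaps and ambiguity codes (B, Z, X) never count. Functional
faces come from the x-coordinate rule (any atom at x ≤ mean(x) − 5 Å vs
x > mean(x) + 5 Å, strict on the high side; a residue qualifying for both
is flagged and set to "neither" so the faces stay disjoint), and alignment
columns are selected through the reference row's non-gap positions.

Clustering: similarities become distances via d = 1 − s (identity) or
d = 1 − c_ij / max(c_ii, c_jj) (charge counts; normalizing by the larger
self-count keeps d ∈ [0,1] and removes sequence-length and net-charge-
magnitude effects, consistent with position — not amount — of charge being
the signal). Agglomerative clustering uses complete linkage (the common
default of R's hclust-based heatmap workflows); items are pre-sorted by
label so equal-distance merges are deterministic. On an ultrametric input
the cophenetic distances reproduce the input exactly (tested by brute force
on 4-leaf trees).

## Surface projection

Fields are sampled by trilinear interpolation at points displaced radially
outward (from the structure's geometric center through each atom) to
r_vdW + offset, default offset 1.4 Å — the potential "just outside the
surface", which is what surface colorings display — rather than at
triangulated molecular-surface vertices, avoiding a meshing dependency.
Per-residue aggregate is the mean (median optional). Conventional display
thresholds ship as metadata: ±5 kT/e for potential surfaces, ±1.5 kT/e for
isopotential contours, 0.5/0.7/0.9 for perturbation maps, −0.10/0.15/0.40
for homologue maps. B-factor output clamps to ±999.99 (field width).

## Parameters that matter

| parameter | default | role |
|---|---|---|
| pH | 7.4 | protonation states via model pKa |
| ε_protein / ε_solvent | 20 / 78.57 | dielectric two-phase map |
| ionic strength | 0 mM | κ̄² screening (0 → pure Poisson) |
| probe radius | 1.4 Å | molecular-surface closing |
| Stern layer | 2.0 Å | ion exclusion for κ̄² (moot at 0 mM) |
| temperature | 298.15 K | kT/e scale inside l_B |
| grid | 129³, study lengths | potentials; ≥ 10 Å margin advised |
| solver tol / maxiter | 1e−6 / 10 000 | CG stopping rule |
| ESI guard ε₀ | 1e−4 kT/e | far-field 0/0 protection |
| shell offset / width | 2 / 5 Å | region ESI statistics |
| face margin | 5 Å | x-coordinate face rule |

Tests and the acceptance script run solves at 65³ (and refinement checks up
to 129³); at 65³ a single solve of a fixture takes ~1–2 s and the full
hot-spot scan about a minute, with accuracy documented above.

## Known limitations

- Linear PB only; no nonlinear term, no multigrid focusing, no energies
  (solvation/binding ΔG are out of scope — the artifact computes potentials
  and similarity).
- Formal-charge parameterization reproduces net-charge bookkeeping, not
  force-field dipoles; potentials inside 2–3 Å of atoms are not meaningful.
- The grid molecular surface is a discretized closing; boundary placement
  is accurate to about one grid spacing.
- The hard two-valued dielectric (no smoothing/splines) makes potentials
  near the boundary slightly grid-orientation dependent.
- Ensembles are consumed, not generated; alignments are consumed, not
  generated; no homology modeling.
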