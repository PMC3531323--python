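"""Finite-difference linearized Poisson-Boltzmann electrostatics on a grid.

Solves  div( eps * grad(phi) ) - kappa_bar^2 * phi = -4*pi*l_B*rho  on a
rectilinear grid, with phi in kT/e, lengths in Angstrom and charges in
elementary charges. l_B = e^2 / (4*pi*eps0*kB*T) is the vacuum Bjerrum
length (~560.5 A at 298.15 K), which folds the kT/e unit conversion into
the source term. The dielectric is a two-valued map (protein interior /
solvent) whose boundary is the probe-rolled molecular (solvent-excluded)
surface, built by morphological closing of the van der Waals volume with
the probe radius. kappa_bar^2 is the modified Debye screening in A^-2,
nonzero only in the ion-accessible region and identically zero at 0 mM.

Discretization: symmetric 7-point stencil with harmonic-mean face
dielectrics; Dirichlet boundary values from the sum of single-sphere
Debye-Hueckel potentials of all charges; preconditioned conjugate
gradients to a stated relative residual.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.constants as const
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import LinearOperator, cg

from .structure_io import Structure

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "ScalarField",
    "PBProblem",
    "build_gridspec",
    "charge_density",
    "dielectric_map",
    "kappa_map",
    "solve_lpbe",
    "write_dx",
    "read_dx",
    "bjerrum_length",
    "kappa_bar_squared",
]


def bjerrum_length(temperature: float = 298.15) -> float:
    """Vacuum Bjerrum length e^2/(4 pi eps0 kB T) in Angstrom."""
    lb_m = const.e**2 / (4 * np.pi * const.epsilon_0 * const.k * temperature)
    return lb_m * 1e10


def kappa_bar_squared(ionic_strength_mM: float, temperature: float = 298.15) -> float:
    """Modified screening constant kappa_bar^2 (A^-2) for a 1:1 electrolyte.

    kappa_bar^2 = 8 pi l_B n, with n the number density of each ion species;
    the Debye length in a solvent of dielectric eps is sqrt(eps/kappa_bar^2).
    """
    n_per_A3 = (ionic_strength_mM / 1000.0) * const.N_A * 1e-27
    return 8 * np.pi * bjerrum_length(temperature) * n_per_A3


@dataclass(frozen=True)
class GridSpec:
    """Rectilinear grid: points per axis, physical lengths (A), and center."""

    points: tuple[int, int, int]
    lengths: tuple[float, float, float]
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for n in self.points:
            if n % 2 == 0:
                raise ValueError(f"grid points per axis must be odd, got {n}")
            if n < 33:
                raise ValueError(f"grid needs >= 33 points per axis, got {n}")
        if any(length <= 0 for length in self.lengths):
            raise ValueError("grid lengths must be positive")

    @property
    def spacing(self) -> np.ndarray:
        """Node spacing h per axis: L/(n-1)."""
        return np.array([L / (n - 1) for n, L in zip(self.points, self.lengths)])

    @property
    def origin(self) -> np.ndarray:
        return np.asarray(self.center) - np.asarray(self.lengths) / 2.0

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + np.arange(self.points[axis]) * self.spacing[axis]

    @property
    def cell_volume(self) -> float:
        return float(np.prod(self.spacing))

    def world_to_grid(self, xyz: np.ndarray) -> np.ndarray:
        """Fractional grid coordinates of world positions (A)."""
        return (np.atleast_2d(xyz) - self.origin) / self.spacing

    def close_to(self, other: "GridSpec", tol: float = 1e-6) -> bool:
        return (self.points == other.points
                and np.allclose(self.lengths, other.lengths, atol=tol)
                and np.allclose(self.center, other.center, atol=tol))


@dataclass
class ScalarField:
    """Values on a GridSpec with a declared unit."""

    spec: GridSpec
    values: np.ndarray
    unit: str  # kT/e | dimensionless | A^-2 | e/A^3

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.spec.points):
            raise ValueError(
                f"field shape {self.values.shape} != grid {self.spec.points}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite values")


@dataclass
class PBProblem:
    """One LPBE solve: a parameterized structure on a grid with physics settings."""

    structure: Structure
    spec: GridSpec
    eps_protein: float = 20.0
    eps_solvent: float = 78.57
    ionic_strength: float = 0.0  # mM
    temperature: float = 298.15  # K
    probe_radius: float = 1.4  # A
    stern_layer: float = 2.0  # A, ion-exclusion beyond vdW
    tol: float = 1e-6
    max_iter: int = 10000

    def __post_init__(self) -> None:
        if self.eps_protein <= 0 or self.eps_solvent <= 0:
            raise ValueError("dielectric constants must be positive")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be non-negative")


def build_gridspec(parent: Structure, points=(129, 129, 129),
                   lengths=(98.0, 116.0, 116.0)) -> GridSpec:
    """Grid centered on the parent's geometric center.

    The same GridSpec must be reused for every member of a perturbation
    family so that potentials are node-aligned for similarity analysis.
    Errors if the structure does not fit; warns when the margin between
    structure and box edge falls below 10 A.
    """
    center = parent.center
    half = np.asarray(lengths) / 2.0
    extent = np.abs(parent.coords - center).max(axis=0)
    if np.any(extent >= half):
        raise ValueError(
            f"structure extent {extent} exceeds half-lengths {half}; enlarge the grid")
    margin = half - extent
    if np.any(margin < 10.0):
        warnings.warn(
            f"grid margin {margin.min():.1f} A < 10 A; boundary artifacts likely",
            stacklevel=2)
    return GridSpec(tuple(points), tuple(float(L) for L in lengths),
                    tuple(float(c) for c in center))


def charge_density(s: Structure, g: GridSpec) -> ScalarField:
    """Trilinear spreading of atomic charges to grid nodes, in e/A^3.

    Each charge is split over its 8 enclosing nodes with trilinear weights,
    so the grid total (values * cell volume) equals the molecular net charge
    exactly. Atoms outside the grid are an error.
    """
    if not s.parameters_assigned:
        raise ValueError("parameters not assigned")
    frac = g.world_to_grid(s.coords)
    n = np.asarray(g.points)
    if np.any(frac < 0) or np.any(frac > n - 1):
        bad = int(np.where((frac < 0) | (frac > n - 1))[0][0])
        a = s.atoms[bad]
        raise ValueError(
            f"atom {a.serial} ({a.residue_name}{a.residue_number} {a.name}) "
            f"at {a.position} lies outside the grid")
    rho = np.zeros(g.points)
    i0 = np.minimum(np.floor(frac).astype(int), n - 2)
    t = frac - i0
    q = s.charges
    for dx in (0, 1):
        wx = t[:, 0] if dx else 1 - t[:, 0]
        for dy in (0, 1):
            wy = t[:, 1] if dy else 1 - t[:, 1]
            for dz in (0, 1):
                wz = t[:, 2] if dz else 1 - t[:, 2]
                np.add.at(rho, (i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz),
                          q * wx * wy * wz)
    return ScalarField(g, rho / g.cell_volume, unit="e/A^3")


def _mark_spheres(g: GridSpec, centers: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Boolean grid mask of the union of spheres (centers, radii)."""
    mask = np.zeros(g.points, dtype=bool)
    h = g.spacing
    origin = g.origin
    n = np.asarray(g.points)
    axes = [g.axis_coords(k) for k in range(3)]
    for c, r in zip(centers, radii):
        if r <= 0:
            continue
        lo = np.maximum(np.ceil((c - r - origin) / h).astype(int), 0)
        hi = np.minimum(np.floor((c + r - origin) / h).astype(int), n - 1)
        if np.any(lo > hi):
            continue
        dx2 = (axes[0][lo[0]:hi[0] + 1] - c[0]) ** 2
        dy2 = (axes[1][lo[1]:hi[1] + 1] - c[1]) ** 2
        dz2 = (axes[2][lo[2]:hi[2] + 1] - c[2]) ** 2
        local = (dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]) <= r * r
        mask[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] |= local
    return mask


def molecular_volume_mask(s: Structure, g: GridSpec, probe_radius: float = 1.4
                          ) -> np.ndarray:
    """Probe-excluded molecular volume (solvent-excluded surface interior).

    Morphological closing of the van der Waals union with a probe-radius
    ball: nodes within (r_atom + probe) of an atom center are the probe-
    dilated volume; eroding it back by the probe (via a Euclidean distance
    transform to the probe-center-accessible region) leaves the nodes a
    probe sphere can never touch, plus the vdW interior.
    """
    coords, radii = s.coords, s.radii
    vdw = _mark_spheres(g, coords, radii)
    if probe_radius <= 0:
        return vdw
    dilated = _mark_spheres(g, coords, radii + probe_radius)
    # distance from each dilated node to the nearest probe-accessible node
    d_to_acc = ndimage.distance_transform_edt(dilated, sampling=g.spacing)
    return vdw | (dilated & (d_to_acc > probe_radius))


def dielectric_map(s: Structure, g: GridSpec, p: PBProblem) -> ScalarField:
    """Two-valued node dielectric: eps_protein inside the molecular volume."""
    mask = molecular_volume_mask(s, g, p.probe_radius)
    eps = np.where(mask, p.eps_protein, p.eps_solvent)
    return ScalarField(g, eps, unit="dimensionless")


def kappa_map(s: Structure, g: GridSpec, p: PBProblem) -> ScalarField:
    """Modified screening kappa_bar^2 (A^-2); zero inside vdW + Stern layer.

    Identically zero at 0 mM ionic strength.
    """
    if p.ionic_strength == 0:
        return ScalarField(g, np.zeros(g.points), unit="A^-2")
    kbar2 = kappa_bar_squared(p.ionic_strength, p.temperature)
    excluded = _mark_spheres(g, s.coords, s.radii + p.stern_layer)
    return ScalarField(g, np.where(excluded, 0.0, kbar2), unit="A^-2")


def _boundary_potential(s: Structure, g: GridSpec, p: PBProblem) -> np.ndarray:
    """Dirichlet values on the full grid (only the 6 faces are used).

    Sum of single-sphere Debye-Hueckel potentials of all charged atoms:
    phi = q*l_B*exp(-kappa*(r-a)) / (eps_s*(1+kappa*a)*r), reducing to
    Coulomb/eps_s at zero ionic strength.
    """
    lb = bjerrum_length(p.temperature)
    kappa = np.sqrt(kappa_bar_squared(p.ionic_strength, p.temperature)
                    / p.eps_solvent) if p.ionic_strength > 0 else 0.0
    charged = [(a.position, a.charge, a.radius) for a in s.atoms if a.charge != 0.0]
    phi = np.zeros(g.points)
    if not charged:
        return phi
    pos = np.array([c[0] for c in charged])
    q = np.array([c[1] for c in charged])
    rad = np.array([c[2] for c in charged])

    def face_values(points: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(points[:, None, :] - pos[None, :, :], axis=2)
        d = np.maximum(d, 1e-6)
        if kappa > 0:
            contrib = q * np.exp(-kappa * (d - rad)) / ((1 + kappa * rad) * d)
        else:
            contrib = q / d
        return (lb / p.eps_solvent) * contrib.sum(axis=1)

    ax = [g.axis_coords(k) for k in range(3)]
    nx, ny, nz = g.points
    for axis, idx in ((0, 0), (0, nx - 1), (1, 0), (1, ny - 1), (2, 0), (2, nz - 1)):
        sl = [slice(None)] * 3
        sl[axis] = idx
        shape = [g.points[k] for k in range(3) if k != axis]
        grids = np.meshgrid(*[ax[k] for k in range(3) if k != axis], indexing="ij")
        pts = np.empty((shape[0] * shape[1], 3))
        other = [k for k in range(3) if k != axis]
        pts[:, axis] = ax[axis][idx]
        pts[:, other[0]] = grids[0].ravel()
        pts[:, other[1]] = grids[1].ravel()
        phi[tuple(sl)] = face_values(pts).reshape(shape)
    return phi


def _harmonic_faces(eps: np.ndarray, axis: int) -> np.ndarray:
    a = eps
    sl_lo = [slice(None)] * 3
    sl_hi = [slice(None)] * 3
    sl_lo[axis] = slice(None, -1)
    sl_hi[axis] = slice(1, None)
    lo, hi = a[tuple(sl_lo)], a[tuple(sl_hi)]
    return 2.0 * lo * hi / (lo + hi)


def solve_lpbe(
    p: PBProblem,
    eps: ScalarField | None = None,
    kappa2: ScalarField | None = None,
    rho: ScalarField | None = None,
) -> ScalarField:
    """Solve the linearized PB equation; returns the potential in kT/e.

    The coefficient maps are built from the problem's structure unless
    passed in explicitly (which the analytic-oracle tests use to realize a
    homogeneous medium). The symmetric 7-point system is solved with
    Jacobi-preconditioned conjugate gradients to relative residual <= tol.
    """
    g = p.spec
    eps_v = (eps or dielectric_map(p.structure, g, p)).values
    kap_v = (kappa2 if kappa2 is not None else kappa_map(p.structure, g, p)).values
    rho_f = rho or charge_density(p.structure, g)
    q_node = rho_f.values * g.cell_volume  # e per node

    if not np.any(q_node):
        return ScalarField(g, np.zeros(g.points), unit="kT/e")

    lb = bjerrum_length(p.temperature)
    nx, ny, nz = g.points
    hx, hy, hz = g.spacing
    mx, my, mz = nx - 2, ny - 2, nz - 2
    m = mx * my * mz

    fx = _harmonic_faces(eps_v, 0) / hx**2  # (nx-1, ny, nz)
    fy = _harmonic_faces(eps_v, 1) / hy**2
    fz = _harmonic_faces(eps_v, 2) / hz**2

    inner = (slice(1, -1), slice(1, -1), slice(1, -1))
    diag = (fx[:-1, 1:-1, 1:-1] + fx[1:, 1:-1, 1:-1]
            + fy[1:-1, :-1, 1:-1] + fy[1:-1, 1:, 1:-1]
            + fz[1:-1, 1:-1, :-1] + fz[1:-1, 1:-1, 1:]
            + kap_v[inner]).ravel()

    def lin_index(i, j, k):
        return (i * my + j) * mz + k

    rows, cols, vals = [], [], []
    idx = np.arange(m).reshape(mx, my, mz)
    # x-direction couplings between interior nodes
    cx = fx[1:-1, 1:-1, 1:-1]  # faces between interior i and i+1
    rows.append(idx[:-1].ravel()); cols.append(idx[1:].ravel()); vals.append(-cx.ravel())
    cy = fy[1:-1, 1:-1, 1:-1]
    rows.append(idx[:, :-1].ravel()); cols.append(idx[:, 1:].ravel()); vals.append(-cy.ravel())
    cz = fz[1:-1, 1:-1, 1:-1]
    rows.append(idx[:, :, :-1].ravel()); cols.append(idx[:, :, 1:].ravel()); vals.append(-cz.ravel())

    rows = np.concatenate(rows); cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    all_rows = np.concatenate([rows, cols, np.arange(m)])
    all_cols = np.concatenate([cols, rows, np.arange(m)])
    all_vals = np.concatenate([vals, vals, diag])
    A = coo_matrix((all_vals, (all_rows, all_cols)), shape=(m, m)).tocsr()

    b = (4 * np.pi * lb / g.cell_volume) * q_node[inner].ravel()

    phi_bc = _boundary_potential(p.structure, g, p)
    bc = np.zeros((mx, my, mz))
    bc[0] += fx[0, 1:-1, 1:-1] * phi_bc[0, 1:-1, 1:-1]
    bc[-1] += fx[-1, 1:-1, 1:-1] * phi_bc[-1, 1:-1, 1:-1]
    bc[:, 0] += fy[1:-1, 0, 1:-1] * phi_bc[1:-1, 0, 1:-1]
    bc[:, -1] += fy[1:-1, -1, 1:-1] * phi_bc[1:-1, -1, 1:-1]
    bc[:, :, 0] += fz[1:-1, 1:-1, 0] * phi_bc[1:-1, 1:-1, 0]
    bc[:, :, -1] += fz[1:-1, 1:-1, -1] * phi_bc[1:-1, 1:-1, -1]
    b = b + bc.ravel()

    inv_diag = 1.0 / diag
    M = LinearOperator((m, m), matvec=lambda x: inv_diag * x)
    x, info = cg(A, b, rtol=p.tol, atol=0.0, maxiter=p.max_iter, M=M)
    if info != 0:
        resid = np.linalg.norm(A @ x - b) / np.linalg.norm(b)
        raise RuntimeError(
            f"LPBE solver did not converge in {p.max_iter} iterations "
            f"(relative residual {resid:.2e})")

    phi = phi_bc
    phi[inner] = x.reshape(mx, my, mz)
    return ScalarField(g, phi, unit="kT/e")


# ---------------------------------------------------------------------------
# OpenDX scalar-grid I/O (APBS dialect)

def write_dx(f: ScalarField, path) -> None:
    g = f.spec
    nx, ny, nz = g.points
    hx, hy, hz = g.spacing
    ox, oy, oz = g.origin
    vals = f.values.ravel(order="C")
    with open(path, "w") as fh:
        fh.write("# OpenDX scalar field\n")
        fh.write(f"# unit: {f.unit}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {ox:.6e} {oy:.6e} {oz:.6e}\n")
        fh.write(f"delta {hx:.6e} 0.000000e+00 0.000000e+00\n")
        fh.write(f"delta 0.000000e+00 {hy:.6e} 0.000000e+00\n")
        fh.write(f"delta 0.000000e+00 0.000000e+00 {hz:.6e}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {vals.size} "
                 "data follows\n")
        for i in range(0, vals.size, 3):
            fh.write(" ".join(f"{v:.6e}" for v in vals[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "regular positions regular connections" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')


def read_dx(path) -> ScalarField:
    """Read an OpenDX regular-grid scalar file (APBS dialect)."""
    counts = origin = None
    deltas = []
    unit = "dimensionless"
    values: list[float] = []
    n_items = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                mu = re.match(r"#\s*unit:\s*(\S+)", line)
                if mu:
                    unit = mu.group(1)
                continue
            if line.startswith("object 1"):
                mm = re.search(r"counts\s+(\d+)\s+(\d+)\s+(\d+)", line)
                if not mm:
                    raise ValueError(f"malformed gridpositions line: {line!r}")
                counts = tuple(int(x) for x in mm.groups())
            elif line.startswith("origin"):
                origin = np.array([float(x) for x in line.split()[1:4]])
            elif line.startswith("delta"):
                deltas.append([float(x) for x in line.split()[1:4]])
            elif "data follows" in line:
                mm = re.search(r"items\s+(\d+)", line)
                if not mm:
                    raise ValueError(f"malformed data header: {line!r}")
                n_items = int(mm.group(1))
            elif line.startswith(("attribute", "component", "object")):
                continue
            elif n_items is not None:
                values.extend(float(x) for x in line.split())
    if counts is None or origin is None or len(deltas) < 3 or n_items is None:
        raise ValueError(f"malformed or truncated DX header in {path}")
    if len(values) != n_items:
        raise ValueError(
            f"truncated DX data in {path}: expected {n_items} values, got {len(values)}")
    h = np.array([deltas[0][0], deltas[1][1], deltas[2][2]])
    lengths = tuple(float(hh * (n - 1)) for hh, n in zip(h, counts))
    center = tuple(float(o + L / 2.0) for o, L in zip(origin, lengths))
    spec = GridSpec(counts, lengths, center)
    arr = np.array(values).reshape(counts, order="C")
    return ScalarField(spec, arr, unit=unit)
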