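"""Electrostatic similarity index (ESI) fields.

Given a parent potential phi_A and a family of N perturbed potentials
phi_B,n on one shared grid, the ESI at grid point (i,j,k) is the mean over
members of the local Hodgkin index

    s(a, b) = 2ab / (a^2 + b^2),

which is +1 for identical values, -1 for sign-flipped values, bounded by
[-1, 1], and invariant when a and b are scaled by a common positive factor.
Grid points where both potentials are negligible (|a|, |b| < eps0) are
counted as perfectly similar, which keeps far-field nodes from turning a
0/0 into noise. A high-ESI surface region is one whose potential resists
the family's perturbations — an electrostatic hot-spot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pb import GridSpec, ScalarField
from .structure_io import Structure

__all__ = ["ESIField", "local_similarity", "esi_field", "skin_mask",
           "region_summary", "surface_distance_field"]

DEFAULT_EPS0 = 1e-4  # kT/e; below this both potentials count as negligible


@dataclass
class ESIField:
    """Per-node ESI over a family of N comparisons, with an optional mask."""

    spec: GridSpec
    values: np.ndarray
    n: int
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("ESI needs at least one comparison (N >= 1)")
        sel = self.values if self.mask is None else self.values[self.mask]
        if sel.size and (np.nanmin(sel) < -1 - 1e-12 or np.nanmax(sel) > 1 + 1e-12):
            raise ValueError("ESI values outside [-1, 1]")

    def as_scalar_field(self) -> ScalarField:
        return ScalarField(self.spec, self.values, unit="dimensionless")


def local_similarity(a, b, eps0: float = DEFAULT_EPS0):
    """Local Hodgkin index 2ab/(a^2+b^2) of two potential values (kT/e).

    Vectorized over arrays; returns 1 where both inputs are below eps0 in
    magnitude (identically negligible potentials are similar).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = a * a + b * b
    negligible = (np.abs(a) < eps0) & (np.abs(b) < eps0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(negligible, 1.0, 2.0 * a * b / np.where(denom == 0, 1.0, denom))
    if out.ndim == 0:
        return float(out)
    return out


def esi_field(
    parent: ScalarField,
    members: list[ScalarField],
    mask: np.ndarray | None = None,
    eps0: float = DEFAULT_EPS0,
) -> ESIField:
    """Cumulative ESI: mean local similarity of each member against the parent.

    All fields must share the parent's GridSpec — this is why every solve in
    a family is run on one grid centered on the parent.
    """
    if not members:
        raise ValueError("empty family: no member potentials")
    acc = np.zeros(parent.values.shape)
    for m in members:
        if not m.spec.close_to(parent.spec):
            raise ValueError("member GridSpec does not match parent GridSpec")
        acc += local_similarity(parent.values, m.values, eps0=eps0)
    values = acc / len(members)
    return ESIField(parent.spec, values, n=len(members), mask=mask)


def surface_distance_field(s: Structure, g: GridSpec,
                           atom_indices=None) -> np.ndarray:
    """Distance (A) from each grid node to the nearest vdW sphere surface.

    min over the selected atoms of |x - a| - r_a; negative inside an atom.
    """
    coords, radii = s.coords, s.radii
    if atom_indices is not None:
        atom_indices = np.asarray(atom_indices)
        if atom_indices.size == 0:
            raise ValueError("empty atom selection")
        coords, radii = coords[atom_indices], radii[atom_indices]
    axes = [g.axis_coords(k) for k in range(3)]
    dist = np.full(g.points, np.inf)
    # chunk over atoms to bound memory on large grids
    chunk = max(1, int(2e7 // np.prod(g.points)))
    for start in range(0, len(coords), chunk):
        c = coords[start:start + chunk]
        r = radii[start:start + chunk]
        d2 = ((axes[0][:, None, None, None] - c[:, 0]) ** 2
              + (axes[1][None, :, None, None] - c[:, 1]) ** 2
              + (axes[2][None, None, :, None] - c[:, 2]) ** 2)
        np.minimum(dist, (np.sqrt(d2) - r).min(axis=-1), out=dist)
    return dist


def skin_mask(s: Structure, g: GridSpec, sigma: float = 3.0,
              delta: float = 4.0) -> np.ndarray:
    """Boolean shell mask: nodes with vdW-surface distance in (sigma, sigma+delta]."""
    d = surface_distance_field(s, g)
    return (d > sigma) & (d <= sigma + delta)


def region_summary(
    e: ESIField,
    s: Structure,
    atom_indices=None,
    offset: float = 2.0,
    shell_width: float = 5.0,
) -> dict:
    """ESI statistics in a surface shell around a set of atoms.

    The shell holds grid nodes whose distance beyond the selected atoms'
    vdW surface lies in [offset, offset + shell_width]. Returns n_nodes,
    mean, median, q05 and q95 of the ESI there.
    """
    d = surface_distance_field(s, e.spec, atom_indices)
    sel = (d >= offset) & (d <= offset + shell_width)
    if e.mask is not None:
        sel &= e.mask
    if not np.any(sel):
        raise ValueError("empty region: no grid nodes in the requested shell")
    vals = e.values[sel]
    return {
        "n_nodes": int(sel.sum()),
        "mean": float(vals.mean()),
        "median": float(np.median(vals)),
        "q05": float(np.quantile(vals, 0.05)),
        "q95": float(np.quantile(vals, 0.95)),
    }
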