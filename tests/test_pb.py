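import numpy as np
import pytest

from esimap import (
    Atom,
    PBProblem,
    Structure,
    build_gridspec,
    charge_density,
    dielectric_map,
    kappa_map,
    read_dx,
    solve_lpbe,
    write_dx,
)
from esimap.pb import GridSpec, ScalarField, bjerrum_length, kappa_bar_squared

EPS_W = 78.57


def point_charge(position=(0.0, 0.0, 0.0), q=1.0, radius=0.0):
    s = Structure([Atom(1, "NZ", "LYS", "A", 1, np.array(position, float),
                        charge=q, radius=radius)], label="pt")
    s.parameters_assigned = True
    return s


def uniform_medium(g, eps=EPS_W, kbar2=0.0):
    return (ScalarField(g, np.full(g.points, eps), "dimensionless"),
            ScalarField(g, np.full(g.points, kbar2), "A^-2"))


def coulomb_exact(g, q=1.0, eps=EPS_W):
    ax = [g.axis_coords(k) for k in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    r = np.sqrt(X**2 + Y**2 + Z**2)
    return r, q * bjerrum_length() / (eps * np.maximum(r, 1e-9))


class TestGridSpec:
    def test_spacing(self):
        g = GridSpec((33, 33, 33), (40.0, 40.0, 40.0))
        assert np.allclose(g.spacing, 1.25)  # 40/32

    def test_even_points_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            GridSpec((34, 33, 33), (40.0, 40.0, 40.0))

    def test_centered_on_parent(self):
        s = point_charge(position=(3.0, -2.0, 7.0))
        g = build_gridspec(s, points=(33, 33, 33), lengths=(40.0, 40.0, 40.0))
        assert np.allclose(g.center, [3.0, -2.0, 7.0])

    def test_structure_larger_than_grid_errors(self):
        atoms = [Atom(1, "CA", "ALA", "A", 1, np.array([-30.0, 0, 0])),
                 Atom(2, "CA", "ALA", "A", 2, np.array([30.0, 0, 0]))]
        s = Structure(atoms, "wide")
        with pytest.raises(ValueError, match="exceeds"):
            build_gridspec(s, points=(33, 33, 33), lengths=(40.0, 40.0, 40.0))

    def test_small_margin_warns(self):
        s = Structure([Atom(1, "CA", "ALA", "A", 1, np.array([15.0, 0, 0])),
                       Atom(2, "CA", "ALA", "A", 2, np.array([-15.0, 0, 0]))], "m")
        with pytest.warns(UserWarning, match="margin"):
            build_gridspec(s, points=(33, 33, 33), lengths=(40.0, 40.0, 40.0))


class TestChargeSpreading:
    def test_charge_on_node(self):
        g = GridSpec((33, 33, 33), (32.0, 32.0, 32.0))
        rho = charge_density(point_charge((0.0, 0.0, 0.0)), g)
        q_node = rho.values * g.cell_volume
        assert q_node[16, 16, 16] == pytest.approx(1.0)
        assert q_node.sum() == pytest.approx(1.0)
        assert np.count_nonzero(q_node) == 1

    def test_charge_at_cell_center_splits_evenly(self):
        g = GridSpec((33, 33, 33), (32.0, 32.0, 32.0))  # h = 1
        rho = charge_density(point_charge((0.5, 0.5, 0.5)), g)
        q_node = rho.values * g.cell_volume
        nz = q_node[q_node != 0]
        assert len(nz) == 8
        assert np.allclose(nz, 0.125)

    def test_total_charge_conserved(self):
        rng = np.random.default_rng(42)
        atoms = [Atom(i + 1, "CB", "ASP", "A", i + 1,
                      rng.uniform(-10, 10, 3), charge=rng.uniform(-1, 1))
                 for i in range(50)]
        s = Structure(atoms, "rand")
        s.parameters_assigned = True
        g = GridSpec((33, 33, 33), (40.0, 40.0, 40.0))
        rho = charge_density(s, g)
        assert rho.values.sum() * g.cell_volume == pytest.approx(
            s.charges.sum(), abs=1e-10)

    def test_atom_outside_grid_errors(self):
        g = GridSpec((33, 33, 33), (20.0, 20.0, 20.0))
        with pytest.raises(ValueError, match="outside"):
            charge_density(point_charge((50.0, 0.0, 0.0)), g)


class TestDielectricBoundary:
    def test_inside_vdw_and_far_field(self):
        g = GridSpec((33, 33, 33), (16.0, 16.0, 16.0))  # h = 0.5
        s = point_charge(radius=2.0)
        p = PBProblem(s, g)
        eps = dielectric_map(s, g, p).values
        assert eps[16, 16, 18] == pytest.approx(20.0)  # 1 A from center
        assert eps[16, 16, 32] == pytest.approx(EPS_W)  # 8 A away

    @pytest.mark.parametrize("separation,expect_protein", [(4.5, True), (7.0, False)])
    def test_midpoint_against_probe_placement_oracle(self, separation, expect_protein):
        """Two 2 A spheres: can a 1.4 A probe touch the midpoint between them?"""
        r_atom, probe = 2.0, 1.4
        centers = np.array([[-separation / 2, 0, 0], [separation / 2, 0, 0]])
        # independent brute-force oracle: scan candidate probe centers
        grid_1d = np.linspace(-4, 4, 81)
        cand = np.stack(np.meshgrid(grid_1d, grid_1d, grid_1d, indexing="ij"),
                        axis=-1).reshape(-1, 3)
        ok_placement = np.all(
            np.linalg.norm(cand[:, None, :] - centers[None], axis=2)
            >= r_atom + probe, axis=1)
        covers_midpoint = np.linalg.norm(cand, axis=1) <= probe
        oracle_solvent = bool(np.any(ok_placement & covers_midpoint))
        assert oracle_solvent != expect_protein

        atoms = [Atom(i + 1, "CA", "ALA", "A", i + 1, c, radius=r_atom)
                 for i, c in enumerate(centers)]
        s = Structure(atoms, "pair")
        s.parameters_assigned = True
        g = GridSpec((65, 65, 65), (16.0, 16.0, 16.0))  # h = 0.25
        eps = dielectric_map(s, g, PBProblem(s, g)).values
        midpoint_protein = eps[32, 32, 32] == 20.0
        assert midpoint_protein == expect_protein


class TestKappa:
    def test_zero_ionic_strength_gives_zero_field(self):
        g = GridSpec((33, 33, 33), (20.0, 20.0, 20.0))
        s = point_charge(radius=2.0)
        kap = kappa_map(s, g, PBProblem(s, g, ionic_strength=0.0))
        assert np.all(kap.values == 0.0)

    def test_debye_length_closed_form(self):
        # 150 mM, eps 78.57, 298.15 K: lambda_D = sqrt(eps/kbar2) ~ 7.86 A
        lam = np.sqrt(EPS_W / kappa_bar_squared(150.0))
        assert lam == pytest.approx(7.86, abs=0.05)

    def test_zero_inside_protein(self):
        g = GridSpec((33, 33, 33), (20.0, 20.0, 20.0))
        s = point_charge(radius=2.0)
        kap = kappa_map(s, g, PBProblem(s, g, ionic_strength=150.0)).values
        assert kap[16, 16, 16] == 0.0
        assert kap[16, 16, 32] > 0.0


class TestSolver:
    def test_zero_charges_give_zero_potential(self):
        g = GridSpec((33, 33, 33), (20.0, 20.0, 20.0))
        s = point_charge(q=0.0, radius=2.0)
        phi = solve_lpbe(PBProblem(s, g))
        assert np.all(phi.values == 0.0)

    def test_coulomb_oracle_within_5pct(self):
        g = GridSpec((65, 65, 65), (40.0, 40.0, 40.0))
        s = point_charge()
        eps, kap = uniform_medium(g)
        phi = solve_lpbe(PBProblem(s, g), eps=eps, kappa2=kap)
        r, exact = coulomb_exact(g)
        shell = (r >= 4 * g.spacing[0]) & (r <= 10.0)  # [4h, L/4]
        rel = np.abs(phi.values - exact)[shell] / exact[shell]
        assert rel.max() < 0.05

    def test_debye_huckel_oracle_within_5pct(self):
        g = GridSpec((65, 65, 65), (40.0, 40.0, 40.0))
        s = point_charge()
        kbar2 = kappa_bar_squared(150.0)
        eps, kap = uniform_medium(g, kbar2=kbar2)
        phi = solve_lpbe(PBProblem(s, g, ionic_strength=150.0), eps=eps, kappa2=kap)
        r, coulomb = coulomb_exact(g)
        lam = np.sqrt(EPS_W / kbar2)
        exact = coulomb * np.exp(-r / lam)
        shell = (r >= 4 * g.spacing[0]) & (r <= 10.0)
        rel = np.abs(phi.values - exact)[shell] / exact[shell]
        assert rel.max() < 0.05

    def test_linearity_of_superposed_charges(self):
        g = GridSpec((33, 33, 33), (30.0, 30.0, 30.0))
        eps, kap = uniform_medium(g)
        s1 = point_charge((-3.0, 0, 0), q=1.0)
        s2 = point_charge((4.0, 1.0, 0), q=-2.0)
        both = Structure(s1.atoms + [Atom(2, "CB", "ASP", "A", 2,
                                          np.array([4.0, 1.0, 0.0]), charge=-2.0)],
                         "both")
        both.parameters_assigned = True
        phi1 = solve_lpbe(PBProblem(s1, g), eps=eps, kappa2=kap)
        phi2 = solve_lpbe(PBProblem(s2, g), eps=eps, kappa2=kap)
        phi12 = solve_lpbe(PBProblem(both, g), eps=eps, kappa2=kap)
        num = np.abs(phi12.values - phi1.values - phi2.values).max()
        assert num / np.abs(phi12.values).max() < 1e-6

    def test_positive_charge_positive_far_field(self):
        g = GridSpec((33, 33, 33), (30.0, 30.0, 30.0))
        s = point_charge(q=2.0, radius=2.0)
        phi = solve_lpbe(PBProblem(s, g)).values
        assert phi[1, :, :].min() > 0 and phi[-2, :, :].min() > 0

    def test_mirror_symmetric_charges_give_mirror_symmetric_potential(self):
        g = GridSpec((33, 33, 33), (30.0, 30.0, 30.0))
        atoms = [Atom(1, "NZ", "LYS", "A", 1, np.array([-4.0, 0, 0]), charge=1.0),
                 Atom(2, "NZ", "LYS", "A", 2, np.array([4.0, 0, 0]), charge=1.0)]
        s = Structure(atoms, "sym")
        s.parameters_assigned = True
        eps, kap = uniform_medium(g)
        phi = solve_lpbe(PBProblem(s, g), eps=eps, kappa2=kap).values
        assert np.abs(phi - phi[::-1, :, :]).max() < 1e-6 * np.abs(phi).max()

    def test_refinement_reduces_coulomb_error_monotonically(self):
        errs = []
        for n in (33, 65, 129):
            g = GridSpec((n, n, n), (40.0, 40.0, 40.0))
            eps, kap = uniform_medium(g)
            phi = solve_lpbe(PBProblem(point_charge(), g), eps=eps, kappa2=kap)
            r, exact = coulomb_exact(g)
            shell = (r >= 5.0) & (r <= 10.0)  # fixed physical shell
            errs.append((np.abs(phi.values - exact)[shell] / exact[shell]).max())
        assert errs[0] > errs[1] > errs[2]


class TestDxIO:
    def test_roundtrip_identity(self, tmp_path):
        g = GridSpec((33, 33, 33), (40.0, 40.0, 40.0), (1.0, -2.0, 3.0))
        rng = np.random.default_rng(3)
        f = ScalarField(g, rng.normal(size=g.points), "kT/e")
        path = tmp_path / "f.dx"
        write_dx(f, path)
        f2 = read_dx(path)
        assert f2.spec.close_to(g)
        assert f2.unit == "kT/e"
        assert np.abs(f2.values - f.values).max() < 1e-6

    def test_reads_apbs_style_header(self, tmp_path):
        # minimal file in the dialect APBS emits (comments, positions, deltas)
        n = 33
        vals = np.arange(n**3, dtype=float)
        lines = ["# Data from APBS",
                 "# POTENTIAL (kT/e)",
                 f"object 1 class gridpositions counts {n} {n} {n}",
                 "origin -1.6e+01 -1.6e+01 -1.6e+01",
                 "delta 1.0e+00 0.0e+00 0.0e+00",
                 "delta 0.0e+00 1.0e+00 0.0e+00",
                 "delta 0.0e+00 0.0e+00 1.0e+00",
                 f"object 2 class gridconnections counts {n} {n} {n}",
                 f"object 3 class array type double rank 0 items {n**3} data follows"]
        for i in range(0, n**3, 3):
            lines.append(" ".join(f"{v:.6e}" for v in vals[i:i + 3]))
        lines += ['attribute "dep" string "positions"',
                  'object "regular positions regular connections" class field']
        path = tmp_path / "apbs.dx"
        path.write_text("\n".join(lines) + "\n")
        f = read_dx(path)
        assert f.spec.points == (n, n, n)
        assert np.allclose(f.spec.origin, -16.0)
        assert np.allclose(f.spec.spacing, 1.0)
        assert f.values[0, 0, 1] == 1.0  # z fastest

    def test_truncated_file_errors(self, tmp_path):
        g = GridSpec((33, 33, 33), (40.0, 40.0, 40.0))
        f = ScalarField(g, np.zeros(g.points), "kT/e")
        path = tmp_path / "t.dx"
        write_dx(f, path)
        text = path.read_text().splitlines()
        path.write_text("\n".join(text[: len(text) // 2]))
        with pytest.raises(ValueError, match="truncated|malformed"):
            read_dx(path)
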