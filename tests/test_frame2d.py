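"""Solver verification against closed-form structural mechanics."""

import numpy as np
import pytest

from stentdeg.errors import ConfigError
from stentdeg.frame2d import FiberSection, Frame2D
from stentdeg.material import MaterialCurve

E = 1700.0
ELASTIC = MaterialCurve(0.0, E, np.array([[0.0, 1e6]]), 2.0)  # yield far above use


def make_section():
    return FiberSection(width=0.125, depth=0.15, n_fibers=8)


def make_cantilever(n_nodes=9, length=10.0):
    nodes = np.column_stack([np.linspace(0, length, n_nodes), np.zeros(n_nodes)])
    elems = np.column_stack([np.arange(n_nodes - 1), np.arange(1, n_nodes)])
    f = Frame2D(nodes, elems, make_section())
    f.set_material(ELASTIC)
    f.fix(0, (0, 1, 2))
    return f


def make_ring(n=24, radius=1.6875):
    C0 = 2 * np.pi * radius
    nodes = np.column_stack([np.linspace(0, C0, n, endpoint=False), np.zeros(n)])
    elems = np.column_stack([np.arange(n), np.r_[np.arange(1, n), 0]])
    wrap = np.zeros(n, bool)
    wrap[-1] = True
    f = Frame2D(nodes, elems, make_section(), wrap=wrap, circumference=C0)
    f.set_material(ELASTIC)
    f.fix(0, (0, 1))
    return f, C0, radius


class TestSection:
    def test_exact_area_and_inertia(self):
        s = make_section()
        assert s.area_weights.sum() == pytest.approx(s.area)
        assert (s.area_weights * s.z**2).sum() == pytest.approx(s.inertia)

    def test_exact_plastic_modulus(self):
        s = make_section()
        assert (s.area_weights * np.abs(s.z)).sum() == pytest.approx(s.plastic_modulus)

    def test_invalid_section(self):
        with pytest.raises(ConfigError):
            FiberSection(width=0.0, depth=0.1)
        with pytest.raises(ConfigError):
            FiberSection(width=0.1, depth=0.1, n_fibers=3)


class TestElasticOracles:
    def test_cantilever_tip_deflection(self):
        """Small tip load: w = PL^3 / 3EI within 2%."""
        f = make_cantilever()
        P = 1e-5
        f.nodal_loads[3 * 8 + 1] = -P
        f.load_factor = 1.0
        f.solve_equilibrium()
        expected = -P * 10.0**3 / (3 * E * f.section.inertia)
        assert f.u[3 * 8 + 1] == pytest.approx(expected, rel=0.02)

    def test_ring_radial_contraction(self):
        """Uniform radial line load: w = p R^2 / (E A) within 2%."""
        f, C0, R = make_ring()
        p = 1e-3
        del f.constraints[f.CDOF]
        f.nodal_loads[f.CDOF] = -p * R  # conjugate of C: F_total / 2 pi
        f.load_factor = 1.0
        f.solve_equilibrium()
        dR = f.u[f.CDOF] / (2 * np.pi)
        assert dR == pytest.approx(-p * R**2 / (E * f.section.area), rel=0.02)

    def test_equilibrium_residual_bound(self):
        f = make_cantilever()
        f.nodal_loads[3 * 8 + 1] = -1e-4
        f.load_factor = 1.0
        f.solve_equilibrium()
        assert f.residual_ratio() <= 1e-6

    def test_consistent_tangent(self):
        """Analytic tangent matches finite differences of the residual."""
        f = make_cantilever(n_nodes=4, length=3.0)
        rng = np.random.default_rng(0)
        u = np.zeros(f.ndof)
        u[3:-1] = 0.01 * rng.standard_normal(f.ndof - 4)
        f_int, K, _ = f._assemble(u)
        h = 1e-7
        for j in rng.choice(np.arange(3, f.ndof - 1), size=4, replace=False):
            up = u.copy()
            up[j] += h
            fp, _, _ = f._assemble(up, want_tangent=False)
            np.testing.assert_allclose(K[:, j], (fp - f_int) / h, atol=1e-4 * max(1, np.abs(K).max()))


class TestPlasticity:
    def test_pure_bending_limit_moment(self):
        """Prescribed end rotations drive a single element to its plastic
        limit moment sigma_y * w * h^2 / 4 within 5%."""
        sy = 60.0
        mat = MaterialCurve(0.0, E, np.array([[0.0, sy]]), 2.0)
        nodes = np.array([[0.0, 0.0], [1.0, 0.0]])
        f = Frame2D(nodes, np.array([[0, 1]]), make_section())
        f.set_material(mat)
        f.fix(0, (0, 1))
        f.fix(1, (1,))
        phi = 0.8

        def controls(lam):
            f.constraints[2] = -lam * phi
            f.constraints[5] = lam * phi

        f.run_stage(controls, n_inc=20)
        limit = sy * f.section.plastic_modulus
        assert abs(f.reaction(2)) == pytest.approx(limit, rel=0.05)

    def test_hardening_raises_moment_above_first_yield(self):
        hard = MaterialCurve(0.0, E, np.array([[0.0, 60.0], [0.5, 120.0]]), 2.0)
        nodes = np.array([[0.0, 0.0], [1.0, 0.0]])
        f = Frame2D(nodes, np.array([[0, 1]]), make_section())
        f.set_material(hard)
        f.fix(0, (0, 1))
        f.fix(1, (1,))

        def controls(lam):
            f.constraints[2] = -lam * 0.8
            f.constraints[5] = lam * 0.8

        f.run_stage(controls, n_inc=20)
        first_yield_limit = 60.0 * f.section.plastic_modulus
        assert abs(f.reaction(2)) > first_yield_limit

    def test_unload_leaves_residual_plastic_strain(self):
        sy = 60.0
        mat = MaterialCurve(0.0, E, np.array([[0.0, sy]]), 2.0)
        nodes = np.column_stack([np.linspace(0, 2, 3), np.zeros(3)])
        elems = np.array([[0, 1], [1, 2]])
        f = Frame2D(nodes, elems, make_section())
        f.set_material(mat)
        f.fix(0, (0, 1, 2))
        tip = 3 * 2 + 1

        def load(lam):
            f.load_factor = lam

        f.nodal_loads[tip] = -0.5  # enough to yield
        f.run_stage(load, n_inc=10)
        assert np.abs(f.eps_p).max() > 1e-4

        def unload(lam):
            f.load_factor = 1.0 - lam

        f.run_stage(unload, n_inc=10)
        assert abs(f.u[tip]) > 1e-4  # permanent set remains


class TestMeshValidation:
    def test_disconnected_mesh_rejected(self):
        nodes = np.array([[0.0, 0.0], [1.0, 0.0], [5.0, 5.0], [6.0, 5.0]])
        elems = np.array([[0, 1], [2, 3]])
        with pytest.raises(ConfigError):
            Frame2D(nodes, elems, make_section())

    def test_wrap_requires_circumference(self):
        nodes = np.array([[0.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ConfigError):
            Frame2D(nodes, np.array([[0, 1]]), make_section(), wrap=np.array([True]))
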