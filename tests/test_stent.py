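"""Staged scaffold simulation: deployment, fatigue, degradation."""

import numpy as np
import pytest

from stentdeg.errors import ConfigError, StateError
from stentdeg.material import MaterialCurve, build_curve_library
from stentdeg.stent import (
    StentGeometry,
    build_unit_cell,
    degrade_step,
    locate_max_degradation,
    new_state,
    radial_strength_curve,
    release_recoil,
    simulate_crimp,
    simulate_expansion,
    simulate_fatigue,
)
from stentdeg.surface import SurfaceParams

PARAMS = SurfaceParams(a=1.35, b=0.155, c=0.243, m=0.43, n=0.52)


def elastic_library():
    curve = MaterialCurve(0.0, 1700.0, np.array([[0.0, 1e6]]), 2.0)
    return [curve]


class TestBuildUnitCell:
    def test_nodes_on_mid_wall_cylinder(self, small_geometry):
        mesh = build_unit_cell(small_geometry)
        radii = np.hypot(*mesh.nodes_3d()[:, :2].T)
        np.testing.assert_allclose(radii, (3.5 - 0.125) / 2.0)

    def test_bridge_chain_count(self, small_geometry):
        mesh = build_unit_cell(small_geometry)
        n_bridge_elems = int(mesh.is_bridge.sum())
        assert n_bridge_elems == 3 * small_geometry.elements_per_bridge * (
            small_geometry.hoops - 1
        )

    def test_crowns_flagged(self, small_geometry):
        mesh = build_unit_cell(small_geometry)
        assert mesh.is_crown.any()
        assert not (mesh.is_crown & mesh.is_bridge).any()

    @pytest.mark.parametrize(
        "kw",
        [
            {"wall_thickness": 0.0},
            {"outer_diameter": -1.0},
            {"crowns_per_hoop": 2},
            {"crowns_per_hoop": 5},
        ],
    )
    def test_nonphysical_geometry_rejected(self, kw):
        with pytest.raises(ConfigError):
            StentGeometry(**kw)


class TestCrimpAndRecoil:
    def test_crimp_reaches_target(self, deployed_state_master):
        # the session state was crimped to 1.5 mm on its way to deployment;
        # verify the recorded diameter trajectory hit the target
        assert deployed_state_master.outer_diameter > 1.5

    def test_crimp_target_tolerance(self, small_geometry, curve_library):
        state = new_state(small_geometry, curve_library)
        simulate_crimp(state, 1.5, n_inc=30)
        assert state.outer_diameter == pytest.approx(1.5, rel=0.005)

    def test_crimp_to_current_diameter_is_identity(self, small_geometry, curve_library):
        state = new_state(small_geometry, curve_library)
        simulate_crimp(state, state.outer_diameter, n_inc=2)
        assert np.abs(state.frame.u[:-1]).max() < 1e-12
        assert abs(state.frame.reaction(state.frame.CDOF)) < 1e-9

    def test_crimp_above_current_rejected(self, small_geometry, curve_library):
        state = new_state(small_geometry, curve_library)
        with pytest.raises(ConfigError):
            simulate_crimp(state, 3.6)

    def test_elastic_crimp_fully_springs_back(self, small_geometry):
        state = new_state(small_geometry, elastic_library())
        simulate_crimp(state, 2.8, n_inc=15)
        release_recoil(state)
        assert state.outer_diameter == pytest.approx(3.5, rel=0.001)

    def test_plastic_recoil_lands_between_crimped_and_initial(
        self, small_geometry, curve_library
    ):
        state = new_state(small_geometry, curve_library)
        simulate_crimp(state, 1.5, n_inc=30)
        sigma_crimp = state.frame.max_abs_stress()
        release_recoil(state)
        assert 1.5 < state.outer_diameter < 3.5
        assert state.frame.max_abs_stress() < sigma_crimp

    def test_release_without_constraint_rejected(self, small_geometry, curve_library):
        state = new_state(small_geometry, curve_library)
        state.frame.constraints.pop(state.frame.CDOF)
        with pytest.raises(StateError):
            release_recoil(state)


class TestExpansion:
    def test_expansion_reaches_target_id(self, deployed_state):
        # deployment fixture expanded to ID 3.2 then recoiled; re-expand
        simulate_expansion(deployed_state, 3.2, n_inc=10)
        assert deployed_state.inner_diameter == pytest.approx(3.2, rel=0.005)

    def test_peak_strain_on_crown_elements(self, deployed_state):
        pk = deployed_state.frame.peak_strain.max(axis=1)
        assert deployed_state.mesh.is_crown[int(np.argmax(pk))]

    def test_zero_expansion_is_identity(self, deployed_state):
        u_before = deployed_state.frame.u.copy()
        simulate_expansion(deployed_state, deployed_state.inner_diameter, n_inc=2)
        np.testing.assert_allclose(deployed_state.frame.u, u_before, atol=1e-10)

    def test_shrinking_expansion_rejected(self, deployed_state):
        with pytest.raises(ConfigError):
            simulate_expansion(deployed_state, 1.0)


class TestFatigue:
    def test_goodman_points_match_brute_force(self, deployed_state):
        """Mean/alt equal (max+min)/2 and (max-min)/2 over the sampled cycle."""
        state, points = simulate_fatigue(deployed_state, 80.0, 160.0)
        snaps = np.stack(
            [state.fatigue_snapshots["sigma_dia"], state.fatigue_snapshots["sigma_sys"]]
        )
        mean_bf = 0.5 * (snaps.max(axis=0) + snaps.min(axis=0))
        alt_bf = 0.5 * (snaps.max(axis=0) - snaps.min(axis=0))
        for p in points:
            e, g = p.location
            assert p.mean_stress == pytest.approx(mean_bf[e, g], abs=1e-12)
            assert p.alternating_stress == pytest.approx(alt_bf[e, g], abs=1e-12)
        assert max(p.alternating_stress for p in points) > 0

    def test_equal_pressures_zero_alternating(self, deployed_state):
        _, points = simulate_fatigue(deployed_state, 100.0, 100.0)
        assert all(p.alternating_stress == 0.0 for p in points)

    def test_inverted_pressures_rejected(self, deployed_state):
        with pytest.raises(ConfigError):
            simulate_fatigue(deployed_state, 160.0, 80.0)

    def test_pressure_unit_conversion(self):
        from stentdeg.constants import MMHG_TO_MPA

        assert 80.0 * MMHG_TO_MPA == pytest.approx(0.010666, abs=1e-6)
        assert 160.0 * MMHG_TO_MPA == pytest.approx(0.021332, abs=1e-6)


class TestDegradation:
    def test_degradation_before_expansion_rejected(self, small_geometry, curve_library):
        state = new_state(small_geometry, curve_library)
        simulate_crimp(state, 3.0, n_inc=5)
        with pytest.raises(StateError):
            degrade_step(state, 10.0, PARAMS)

    def test_degree_non_decreasing_and_localized(self, deployed_state):
        d_prev = deployed_state.frame.D.copy()
        for _ in range(3):
            degrade_step(deployed_state, 10.0, PARAMS)
            assert np.all(deployed_state.frame.D >= d_prev - 1e-12)
            d_prev = deployed_state.frame.D.copy()
        e, dmax, coords = locate_max_degradation(deployed_state)
        assert deployed_state.mesh.is_crown[e]
        # the most degraded point is the most strained point
        assert np.unravel_index(
            np.argmax(deployed_state.frame.D), deployed_state.frame.D.shape
        ) == np.unravel_index(
            np.argmax(deployed_state.frame.peak_strain),
            deployed_state.frame.peak_strain.shape,
        )

    def test_locate_matches_exhaustive_scan(self, deployed_state):
        degrade_step(deployed_state, 30.0, PARAMS)
        e, dmax, _ = locate_max_degradation(deployed_state)
        assert dmax == pytest.approx(float(deployed_state.frame.D.max()))

    def test_uniform_strain_gives_uniform_degree(self, curve_library):
        # degenerate plain ring: pure membrane, every point equally strained
        geo = StentGeometry(hoop_height=0.0, hoops=1, bridges_per_ring=0,
                            elements_per_strut=4)
        state = new_state(geo, curve_library)
        simulate_expansion(state, state.inner_diameter + 0.05, n_inc=5)
        state.step_label = "expand"
        degrade_step(state, 10.0, PARAMS)
        assert np.ptp(state.frame.D) < 1e-9

    def test_tie_break_lowest_element(self, deployed_state):
        deployed_state.degradation_stepped = True
        deployed_state.frame.D[:] = 0.25
        e, dmax, _ = locate_max_degradation(deployed_state)
        assert (e, dmax) == (0, 0.25)

    def test_requires_history(self, deployed_state):
        with pytest.raises(StateError):
            locate_max_degradation(deployed_state)


class TestRadialStrength:
    def test_degraded_not_stronger_than_pristine(self, deployed_state):
        pristine = radial_strength_curve(deployed_state, 2.2, n_points=6)
        degrade_step(deployed_state, 30.0, PARAMS)
        degraded = radial_strength_curve(deployed_state, 2.2, n_points=6)
        assert degraded.peak_force <= pristine.peak_force + 1e-9
        assert pristine.peak_force > 0

    def test_curve_shape(self, deployed_state):
        curve = radial_strength_curve(deployed_state, 2.2, n_points=6)
        assert np.all(np.diff(curve.diameters) < 0)
        assert np.all(curve.forces >= 0)
        assert curve.complete

    def test_probe_does_not_mutate_state(self, deployed_state):
        od = deployed_state.outer_diameter
        u = deployed_state.frame.u.copy()
        radial_strength_curve(deployed_state, 2.5, n_points=4)
        assert deployed_state.outer_diameter == od
        np.testing.assert_array_equal(deployed_state.frame.u, u)

    def test_bad_min_diameter(self, deployed_state):
        with pytest.raises(ConfigError):
            radial_strength_curve(deployed_state, deployed_state.outer_diameter + 0.1)

    def test_initial_slope_matches_ring_stiffness(self):
        """Degenerate plain-ring scaffold: dF/dOD = pi E A / R within 10%."""
        geo = StentGeometry(hoop_height=0.0, hoops=1, bridges_per_ring=0,
                            elements_per_strut=4)
        state = new_state(geo, elastic_library())
        d0 = state.outer_diameter
        curve = radial_strength_curve(state, d0 - 0.01, n_points=4)
        slope = np.diff(curve.forces) / np.diff(curve.diameters)
        E, A = 1700.0, state.frame.section.area
        R = geo.mid_wall_radius
        assert -slope.mean() == pytest.approx(np.pi * E * A / R, rel=0.10)
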