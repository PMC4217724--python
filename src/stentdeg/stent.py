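"""Stent unit-cell mechanics with degradation-coupled material.

The scaffold — sinusoidal in-phase hoops linked by straight bridges on a
cylinder of 3.5 mm outer diameter and 0.125 mm wall — is modeled on the
unrolled mid-wall surface: circumferential coordinate x, axial y. The
ring closure becomes a periodic *circumference* parameter; prescribing
it reproduces rigid-cylinder crimping/ballooning (the total radial force
equals 2π times its conjugate force), freeing it is elastic recoil, and
a calibrated scalar spring on it is the compliant mock vessel of the
fatigue stage.

The analysis sequence mirrors the implant's life: crimp (3.5 → 1.5 mm
OD), recoil, balloon expansion (to 3.2 mm ID), recoil, pulsatile fatigue
between diastolic and systolic pressure, then staggered degradation
stepping — each Gauss point's degradation degree follows the strain- and
time-dependent surface evaluated at its peak historical tensile strain,
material properties are re-interpolated from the degradation-indexed
curve library, points beyond the fracture threshold are deactivated, and
equilibrium is re-solved.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import DEFAULT_FRACTURE_THRESHOLD, MMHG_TO_MPA
from .errors import ConfigError, SolverError, StateError
from .frame2d import FiberSection, Frame2D, VesselSpring
from .material import MaterialCurve, fracture_check, interpolate_properties
from .surface import SurfaceParams, evaluate_degree

__all__ = [
    "StentGeometry",
    "BeamMesh",
    "SimulationState",
    "GoodmanPoint",
    "RadialStrengthCurve",
    "build_unit_cell",
    "new_state",
    "simulate_crimp",
    "release_recoil",
    "simulate_expansion",
    "simulate_fatigue",
    "degrade_step",
    "radial_strength_curve",
    "locate_max_degradation",
]


@dataclass(frozen=True)
class StentGeometry:
    """Scaffold geometry. Lengths in mm.

    ``hoop_height`` is the peak-to-peak height of the sinusoidal hoop;
    it may be zero to degenerate the hoop into a plain ring (useful for
    closed-form checks). ``crowns_per_hoop`` must be even so the
    sinusoid closes periodically around the circumference.
    """

    outer_diameter: float = 3.5
    wall_thickness: float = 0.125
    strut_width: float = 0.15
    crowns_per_hoop: int = 6
    hoops: int = 2
    bridges_per_ring: int = 3
    elements_per_strut: int = 8
    hoop_height: float = 1.0
    bridge_length: float = 0.4
    elements_per_bridge: int = 2
    n_fibers: int = 8

    def __post_init__(self):
        for name in ("outer_diameter", "wall_thickness", "strut_width"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.wall_thickness >= self.outer_diameter / 2:
            raise ConfigError("wall_thickness too large for the outer diameter")
        if self.crowns_per_hoop < 3:
            raise ConfigError("crowns_per_hoop must be >= 3")
        if self.crowns_per_hoop % 2:
            raise ConfigError("crowns_per_hoop must be even (periodic sinusoid)")
        if self.hoops < 1 or self.elements_per_strut < 1 or self.elements_per_bridge < 1:
            raise ConfigError("hoops and element counts must be >= 1")
        if self.hoop_height < 0 or self.bridge_length <= 0:
            raise ConfigError("hoop_height must be >= 0 and bridge_length > 0")
        if self.hoops > 1 and self.bridges_per_ring < 1:
            raise ConfigError("multi-hoop scaffolds need >= 1 bridge per ring")
        if self.bridges_per_ring > self.crowns_per_hoop // 2:
            raise ConfigError("at most one bridge per crown pair")

    @property
    def mid_wall_diameter(self) -> float:
        return self.outer_diameter - self.wall_thickness

    @property
    def mid_wall_radius(self) -> float:
        return self.mid_wall_diameter / 2.0

    @property
    def circumference(self) -> float:
        return np.pi * self.mid_wall_diameter


@dataclass
class BeamMesh:
    """Beam discretisation of the scaffold on the unrolled mid-wall surface."""

    geometry: StentGeometry
    nodes: np.ndarray  # (N, 2) unrolled coordinates (x circumferential, y axial)
    elements: np.ndarray  # (nel, 2) node indices
    wrap: np.ndarray  # (nel,) periodic-closure flags
    is_crown: np.ndarray  # (nel,) element sits at a crown (inner curvature)
    is_bridge: np.ndarray  # (nel,)

    @property
    def circumference(self) -> float:
        return self.geometry.circumference

    @property
    def length(self) -> float:
        """Axial extent of the modeled scaffold segment."""
        span = float(self.nodes[:, 1].max() - self.nodes[:, 1].min())
        return max(span, self.geometry.strut_width)

    def nodes_3d(self, circumference: float | None = None) -> np.ndarray:
        """Wrap the unrolled nodes back onto the mid-wall cylinder."""
        C = circumference or self.circumference
        r = C / (2.0 * np.pi)
        theta = 2.0 * np.pi * self.nodes[:, 0] / C
        return np.column_stack([r * np.cos(theta), r * np.sin(theta), self.nodes[:, 1]])


def build_unit_cell(geometry: StentGeometry) -> BeamMesh:
    """Mesh the repeating scaffold cell.

    Hoops are sinusoids sampled so crowns fall on nodes; bridges run from
    a crown of one hoop to the facing crown of the next (straight,
    slightly inclined links). The hoop's closing element wraps through
    the periodic circumference.
    """
    g = geometry
    C0 = g.circumference
    k = g.crowns_per_hoop // 2  # full sinusoid periods per hoop
    nseg = g.crowns_per_hoop * g.elements_per_strut
    A = g.hoop_height / 2.0
    pitch = g.hoop_height + g.bridge_length

    nodes: list[tuple[float, float]] = []
    elements: list[tuple[int, int]] = []
    wrap: list[bool] = []
    is_bridge: list[bool] = []

    hoop_start = []
    for h in range(g.hoops):
        hoop_start.append(len(nodes))
        y0 = h * pitch
        for j in range(nseg):
            x = j * C0 / nseg
            nodes.append((x, y0 + A * np.cos(2.0 * np.pi * k * x / C0)))
        base = hoop_start[h]
        for j in range(nseg):
            elements.append((base + j, base + (j + 1) % nseg))
            wrap.append(j == nseg - 1)
            is_bridge.append(False)

    # bridges: hoop h crown (peak) -> hoop h+1 facing crown (trough)
    for h in range(g.hoops - 1):
        for b in range(g.bridges_per_ring):
            # spread bridges evenly over the k peaks of the hoop
            j_peak = (2 * g.elements_per_strut) * (int(round(b * k / g.bridges_per_ring)) % k)
            j_trough = j_peak + g.elements_per_strut
            n_from = hoop_start[h] + j_peak
            n_to = hoop_start[h + 1] + (j_trough % nseg)
            p0 = np.array(nodes[n_from])
            p1 = np.array(nodes[n_to])
            prev = n_from
            for e in range(1, g.elements_per_bridge):
                t = e / g.elements_per_bridge
                nodes.append(tuple(p0 + t * (p1 - p0)))
                elements.append((prev, len(nodes) - 1))
                wrap.append(False)
                is_bridge.append(True)
                prev = len(nodes) - 1
            elements.append((prev, n_to))
            wrap.append(False)
            is_bridge.append(True)

    nodes_arr = np.array(nodes)
    elems_arr = np.array(elements, dtype=int)
    wrap_arr = np.array(wrap, dtype=bool)
    bridge_arr = np.array(is_bridge, dtype=bool)

    # crown elements: hoop elements whose midpoint sits near a sinusoid extremum
    mids = 0.5 * (nodes_arr[elems_arr[:, 0], 0] + nodes_arr[elems_arr[:, 1], 0])
    mids = np.where(wrap_arr, nodes_arr[elems_arr[:, 0], 0] + 0.5 * C0 / nseg, mids)
    if A > 0:
        phase = np.abs(np.cos(2.0 * np.pi * k * mids / C0))
        is_crown = (~bridge_arr) & (phase >= 0.8)
    else:
        is_crown = np.zeros(len(elems_arr), dtype=bool)

    return BeamMesh(
        geometry=g,
        nodes=nodes_arr,
        elements=elems_arr,
        wrap=wrap_arr,
        is_crown=is_crown,
        is_bridge=bridge_arr,
    )


@dataclass(frozen=True)
class GoodmanPoint:
    """Mean/alternating stress pair of one material point over the pulse cycle."""

    mean_stress: float
    alternating_stress: float
    location: tuple[int, int]  # (element, gauss point)

    def __post_init__(self):
        if self.alternating_stress < 0:
            raise ConfigError("alternating stress must be >= 0")


@dataclass
class RadialStrengthCurve:
    """Total radial force vs outer diameter during a rigid-cylinder crimp."""

    diameters: np.ndarray  # mm, strictly decreasing
    forces: np.ndarray  # N, total radial force (>= 0)
    length: float  # modeled axial length, mm
    complete: bool = True

    @property
    def peak_force(self) -> float:
        return float(np.max(self.forces)) if len(self.forces) else 0.0

    @property
    def forces_per_length(self) -> np.ndarray:
        return self.forces / self.length

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "diameter_mm": self.diameters,
                "force_N": self.forces,
                "force_N_per_mm": self.forces_per_length,
            }
        )


@dataclass
class SimulationState:
    """Mesh + solver + per-point history for the staged analysis."""

    mesh: BeamMesh
    frame: Frame2D
    curve_library: list[MaterialCurve]
    step_label: str = "initial"
    elapsed_days: float = 0.0
    degradation_stepped: bool = field(default=False)
    fatigue_snapshots: dict | None = None

    @property
    def outer_diameter(self) -> float:
        return self.frame.circumference / np.pi + self.mesh.geometry.wall_thickness

    @property
    def inner_diameter(self) -> float:
        return self.frame.circumference / np.pi - self.mesh.geometry.wall_thickness

    def copy(self) -> "SimulationState":
        return copy.deepcopy(self)

    def point_table(self) -> pd.DataFrame:
        """Per-Gauss-point state: stress, peak strain, D, activity."""
        fr = self.frame
        nel = len(fr.elems)
        el, gp = np.meshgrid(np.arange(nel), np.arange(2), indexing="ij")
        s_mid = 0.5 * (
            self.mesh.nodes[fr.elems[:, 0], 0] + self.mesh.nodes[fr.elems[:, 1], 0]
        )
        return pd.DataFrame(
            {
                "element": el.ravel(),
                "gauss": gp.ravel(),
                "s_coordinate": np.repeat(s_mid, 2),
                "stress_MPa": fr.point_stress().ravel(),
                "peak_strain": fr.peak_strain.ravel(),
                "D": fr.D.ravel(),
                "active": fr.active.ravel(),
                "is_crown": np.repeat(self.mesh.is_crown, 2),
            }
        )


def new_state(
    geometry: StentGeometry, curve_library: list[MaterialCurve]
) -> SimulationState:
    """Fresh pristine state: mesh built, node 0 pinned, material at D = 0."""
    if not curve_library:
        raise ConfigError("curve library must not be empty")
    mesh = build_unit_cell(geometry)
    section = FiberSection(
        width=geometry.wall_thickness, depth=geometry.strut_width, n_fibers=geometry.n_fibers
    )
    frame = Frame2D(
        mesh.nodes, mesh.elements, section, wrap=mesh.wrap, circumference=mesh.circumference
    )
    frame.set_material(interpolate_properties(0.0, curve_library))
    frame.fix(0, (0, 1))
    return SimulationState(mesh=mesh, frame=frame, curve_library=list(curve_library))


def _drive_circumference(state: SimulationState, c_target: float, n_inc: int) -> None:
    fr = state.frame
    c_start = fr.circumference
    fr.constraints[fr.CDOF] = fr.u[fr.CDOF]

    def controls(lam):
        fr.constraints[fr.CDOF] = (c_start + lam * (c_target - c_start)) - fr.C0

    fr.run_stage(controls, n_inc=n_inc)


def simulate_crimp(
    state: SimulationState, target_outer_diameter: float, n_inc: int = 40
) -> SimulationState:
    """Rigid-cylinder crimp to the target outer diameter (displacement
    controlled through the circumference parameter)."""
    if target_outer_diameter > state.outer_diameter + 1e-9:
        raise ConfigError("crimp target must not exceed the current outer diameter")
    if target_outer_diameter <= 2 * state.mesh.geometry.wall_thickness:
        raise ConfigError("crimp target smaller than twice the wall thickness")
    c_target = np.pi * (target_outer_diameter - state.mesh.geometry.wall_thickness)
    _drive_circumference(state, c_target, n_inc)
    state.step_label = "crimp" if state.step_label in ("initial", "crimp") else "recrimp"
    return state


def release_recoil(state: SimulationState, n_inc: int = 10) -> SimulationState:
    """Remove the rigid surrogate and let the scaffold spring back.

    The unilateral contact surface is withdrawn displacement-controlled:
    the prescribed circumference marches from its current value toward
    the reference until the contact reaction changes sign (contact
    opens), the zero-force circumference is bracketed and bisected, and
    the circumference dof is then freed. Displacement control keeps the
    unloading stable even when the elastic spring-back is severe.
    """
    fr = state.frame
    if fr.CDOF not in fr.constraints:
        raise StateError("no active constraint surface to release")
    g0 = fr.reaction(fr.CDOF)
    ftol = max(1e-9, 1e-3 * abs(g0))
    if abs(g0) > 1e-9:
        # march the surrogate toward the reference circumference, never
        # re-loading: a step that overshoots the contact-opening point
        # (reaction sign flip) is undone and halved. Plasticity makes the
        # unloading path irreversible, so approaching from one side only
        # keeps the state physical.
        c = fr.circumference
        c_end = fr.C0
        dc = (c_end - c) / n_inc
        dc_min = abs(dc) / 2**14
        while abs(dc) > 0 and (c_end - c) * np.sign(dc) > 1e-12:
            step = dc if abs(c_end - c) > abs(dc) else (c_end - c)
            saved = (fr.u.copy(), fr.ep_sub.copy(), fr.eps_p.copy(), fr.sigma.copy(),
                     fr.eps_total.copy(), fr.peak_strain.copy())
            _drive_circumference(state, c + step, n_inc=1)
            g = fr.reaction(fr.CDOF)
            if abs(g) <= ftol:
                break
            if np.sign(g) != np.sign(g0):  # overshot the opening point
                fr.u, fr.ep_sub, fr.eps_p, fr.sigma, fr.eps_total, fr.peak_strain = saved
                fr.constraints[fr.CDOF] = fr.u[fr.CDOF]
                dc *= 0.5
                if abs(dc) < dc_min:
                    break
                continue
            c += step
    del fr.constraints[fr.CDOF]
    fr.solve_equilibrium()
    state.step_label = {
        "crimp": "recoil1",
        "expand": "recoil2",
    }.get(state.step_label, "recoil")
    return state


def simulate_expansion(
    state: SimulationState, target_inner_diameter: float, n_inc: int = 40
) -> SimulationState:
    """Balloon expansion (rigid cylinder from inside) to the target inner
    diameter."""
    if target_inner_diameter < state.inner_diameter - 1e-9:
        raise ConfigError("expansion target must not be below the current inner diameter")
    c_target = np.pi * (target_inner_diameter + state.mesh.geometry.wall_thickness)
    _drive_circumference(state, c_target, n_inc)
    state.step_label = "expand"
    return state


def simulate_fatigue(
    state: SimulationState,
    p_dia_mmhg: float = 80.0,
    p_sys_mmhg: float = 160.0,
    vessel_compliance: float = 0.05,
    vessel_diameter_ratio: float = 0.95,
    n_inc: int = 5,
) -> tuple[SimulationState, list[GoodmanPoint]]:
    """Pulsatile loading between diastole and systole in an elastic vessel.

    The vessel is a linear radial spring whose unstented diameter change
    over the pressure range equals ``vessel_compliance``; its natural
    diameter at diastole is ``vessel_diameter_ratio`` x the current stent
    outer diameter (the deployed scaffold is oversized, so it props the
    vessel open). Two quasi-static solves give per-point mean stress
    (σ_sys + σ_dia)/2 and alternating stress |σ_sys − σ_dia|/2.
    """
    if not p_sys_mmhg >= p_dia_mmhg or not p_dia_mmhg > 0:
        raise ConfigError("need p_sys >= p_dia > 0")
    if not 0 < vessel_compliance < 1:
        raise ConfigError("vessel_compliance must be a fraction in (0, 1)")
    fr = state.frame
    p_dia = p_dia_mmhg * MMHG_TO_MPA
    p_sys = p_sys_mmhg * MMHG_TO_MPA
    r_nat = vessel_diameter_ratio * state.outer_diameter / 2.0
    # degenerate zero-amplitude pulse: calibrate stiffness on the nominal
    # physiological range so the spring is still well defined
    p_hi = p_sys if p_sys > p_dia else p_dia + 80.0 * MMHG_TO_MPA
    vessel = VesselSpring.from_compliance(
        r_nat, p_dia, p_hi, vessel_compliance, state.mesh.length
    )
    fr.vessel = vessel
    fr.constraints.pop(fr.CDOF, None)

    # engage the vessel at diastole
    vessel.pressure = p_dia

    def engage(lam):
        fr.vessel_scale = lam

    fr.run_stage(engage, n_inc=n_inc)
    sigma_dia = fr.point_stress().copy()

    def pressurize(lam):
        vessel.pressure = p_dia + lam * (p_sys - p_dia)

    fr.run_stage(pressurize, n_inc=n_inc)
    sigma_sys = fr.point_stress().copy()

    # park the state at diastole again for subsequent stages
    def depressurize(lam):
        vessel.pressure = p_sys + lam * (p_dia - p_sys)

    fr.run_stage(depressurize, n_inc=n_inc)

    mean = 0.5 * (sigma_sys + sigma_dia)
    alt = 0.5 * np.abs(sigma_sys - sigma_dia)
    points = [
        GoodmanPoint(float(mean[e, g]), float(alt[e, g]), (int(e), int(g)))
        for e in range(mean.shape[0])
        for g in range(2)
    ]
    # raw cycle snapshots, kept for diagnostics and cross-checks
    state.fatigue_snapshots = {"sigma_dia": sigma_dia, "sigma_sys": sigma_sys}
    state.step_label = "fatigue"
    return state, points


def degrade_step(
    state: SimulationState,
    dt_days: float,
    params: SurfaceParams,
    threshold: float = DEFAULT_FRACTURE_THRESHOLD,
) -> SimulationState:
    """Advance degradation by ``dt_days`` and re-equilibrate.

    Each point's degree follows the surface at its peak historical
    tensile strain and the new elapsed time; properties are
    re-interpolated from the curve library; points at or beyond the
    fracture threshold are deactivated (stress zeroed, stiffness reduced
    to a numerical residual).
    """
    if dt_days <= 0:
        raise ConfigError("dt_days must be > 0")
    if state.step_label in ("initial", "crimp", "recoil1"):
        raise StateError("degradation stepping requires a completed expansion")
    fr = state.frame
    state.elapsed_days += dt_days
    nel = len(fr.elems)
    newly_failed = []
    for e in range(nel):
        for g in range(2):
            d = float(
                evaluate_degree(params, max(fr.peak_strain[e, g], 0.0), state.elapsed_days)
            )
            d = max(d, fr.D[e, g])  # degradation is irreversible
            fr.D[e, g] = d
            fr.set_point_material(e, g, interpolate_properties(d, state.curve_library))
            if fr.active[e, g] and fracture_check(d, threshold):
                fr.active[e, g] = False
                newly_failed.append((e, g))
    try:
        fr.solve_equilibrium()
    except SolverError as exc:
        raise SolverError(
            "equilibrium lost after degradation update",
            {**exc.diagnostics, "deactivated_points": newly_failed},
        ) from exc
    state.degradation_stepped = True
    state.step_label = "degrade"
    return state


def radial_strength_curve(
    state: SimulationState, min_diameter: float, n_points: int = 12
) -> RadialStrengthCurve:
    """Radial force vs diameter while crimping the (possibly degraded)
    scaffold on a rigid cylinder. Works on a copy; the input state is
    untouched. A non-converged sweep returns the partial curve flagged
    incomplete."""
    if min_diameter >= state.outer_diameter - 1e-9:
        raise ConfigError("min_diameter must be below the current outer diameter")
    probe = state.copy()
    fr = probe.frame
    fr.vessel = None
    fr.vessel_scale = 0.0
    fr.constraints[fr.CDOF] = fr.u[fr.CDOF]
    d_start = probe.outer_diameter
    diam_targets = np.linspace(d_start, min_diameter, n_points + 1)[1:]
    diameters = [d_start]
    forces = [max(-2.0 * np.pi * fr.reaction(fr.CDOF), 0.0)]
    complete = True
    t = probe.mesh.geometry.wall_thickness
    for d in diam_targets:
        try:
            _drive_circumference(probe, np.pi * (d - t), n_inc=4)
        except SolverError:
            complete = False
            break
        diameters.append(d)
        # inward reaction (negative conjugate force) = crimping force
        forces.append(max(-2.0 * np.pi * fr.reaction(fr.CDOF), 0.0))
    return RadialStrengthCurve(
        diameters=np.array(diameters),
        forces=np.array(forces),
        length=probe.mesh.length,
        complete=complete,
    )


def locate_max_degradation(state: SimulationState) -> tuple[int, float, np.ndarray]:
    """(element, D, mid-wall 3-D coordinates) of the most degraded point;
    ties resolve to the lowest element index."""
    if not state.degradation_stepped:
        raise StateError("no degradation history: run degrade_step first")
    fr = state.frame
    flat = np.round(fr.D, 12).ravel()
    idx = int(np.argmax(flat))  # argmax returns the first (lowest) max index
    e = idx // 2
    n1, n2 = fr.elems[e]
    xy = 0.5 * (state.mesh.nodes[n1] + state.mesh.nodes[n2])
    C = fr.circumference
    r = C / (2.0 * np.pi)
    theta = 2.0 * np.pi * xy[0] / C
    coords = np.array([r * np.cos(theta), r * np.sin(theta), xy[1]])
    return e, float(fr.D.ravel()[idx]), coords
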