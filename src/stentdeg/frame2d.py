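"""Corotational 2-D elastoplastic beam solver.

The stent mechanics is reduced to planar frames of 2-node corotational
beam elements (3 dof/node: two translations and a rotation). Each
element carries two Gauss points along its length; each Gauss point a
fiber discretisation of the rectangular cross-section (Gauss–Legendre
per half-depth, so both the elastic second moment and the fully plastic
section modulus integrate exactly). Fibers follow one-dimensional
plasticity with multilinear kinematic (Masing) hardening, realised as a
Besseling overlay of elastic-perfectly-plastic sublayers — under load
reversal the stress magnitude stays bounded by the forward envelope,
the appropriate behaviour for crimp/recoil/re-expansion cycling.

Large rotations are handled corotationally (Crisfield): element strains
are measured in a frame that follows the chord, so arbitrarily large
rigid rotations cost nothing and local strains stay moderate for
reasonable meshes.

A closed ring unrolled into the plane is represented by *wrap* elements
whose second node is the periodic image of a node shifted by the current
circumference ``C = C0 + u[-1]``; the last dof of the system is this
circumference change. Prescribing it is a rigid cylindrical
crimper/balloon surrogate (total radial force = 2π x its conjugate
force); leaving it free with zero conjugate force is free recoil; a
scalar spring on it is an elastic vessel.

Quasi-static implicit Newton with backtracking line search and adaptive
increment bisection.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigError, SolverError

__all__ = ["FiberSection", "Frame2D", "VesselSpring"]

#: Stiffness retention factor for deactivated (fractured) material points;
#: keeps the tangent matrix regular while contributing negligible force.
RESIDUAL_STIFFNESS = 1e-6

_XI = np.array([0.5 - 0.5 / np.sqrt(3.0), 0.5 + 0.5 / np.sqrt(3.0)])  # Gauss pts on [0,1]


class FiberSection:
    """Rectangular beam section integrated by fibers across the depth.

    ``depth`` is the in-plane bending dimension, ``width`` the
    out-of-plane one. Fibers are Gauss–Legendre points per half-depth:
    EA, EI and the plastic limit moment are all integrated exactly.
    """

    def __init__(self, width: float, depth: float, n_fibers: int = 8):
        if width <= 0 or depth <= 0:
            raise ConfigError("section width and depth must be > 0")
        if n_fibers < 2 or n_fibers % 2:
            raise ConfigError("n_fibers must be an even integer >= 2")
        self.width = float(width)
        self.depth = float(depth)
        self.n_fibers = int(n_fibers)
        xg, wg = np.polynomial.legendre.leggauss(n_fibers // 2)
        half = depth / 2.0
        z_half = 0.5 * half * (xg + 1.0)  # map [-1,1] -> [0, h/2]
        w_half = 0.5 * half * wg
        self.z = np.concatenate([-z_half[::-1], z_half])
        self.area_weights = np.concatenate([w_half[::-1], w_half]) * width

    @property
    def area(self) -> float:
        return self.width * self.depth

    @property
    def inertia(self) -> float:
        return self.width * self.depth**3 / 12.0

    @property
    def plastic_modulus(self) -> float:
        return self.width * self.depth**2 / 4.0


class VesselSpring:
    """Linear radial vessel surrogate acting on the circumference dof.

    The unstented vessel has natural mid-wall radius ``R_nat(p)``
    growing linearly with lumen pressure so that its diameter change over
    (p_dia, p_sys) equals the prescribed compliance. When the stent's
    radius exceeds ``R_nat`` the vessel pushes back with radial stiffness
    ``k_radial`` (N/mm of radial interference, total over the modeled
    stent); when smaller, contact is open and the force vanishes.
    """

    def __init__(self, r_natural_dia: float, p_dia: float, p_sys: float,
                 compliance: float, k_radial: float):
        if p_sys <= p_dia:
            raise ConfigError("p_sys must exceed p_dia")
        if compliance <= 0 or k_radial <= 0 or r_natural_dia <= 0:
            raise ConfigError("vessel parameters must be positive")
        self.r_dia = float(r_natural_dia)
        self.p_dia = float(p_dia)
        self.p_sys = float(p_sys)
        self.compliance = float(compliance)
        self.k_radial = float(k_radial)
        self.pressure = float(p_dia)

    @classmethod
    def from_compliance(cls, r_natural_dia: float, p_dia_mpa: float, p_sys_mpa: float,
                        compliance: float, stent_length: float) -> "VesselSpring":
        """Calibrate stiffness so the unstented diameter change over the
        pressure range equals the compliance.

        The pressure rise loads the vessel by its projected area
        (2 R x length); equating that to k x (compliance x R) fixes k.
        """
        dF = (p_sys_mpa - p_dia_mpa) * 2.0 * r_natural_dia * stent_length
        k = dF / (compliance * r_natural_dia)
        return cls(r_natural_dia, p_dia_mpa, p_sys_mpa, compliance, k)

    def natural_radius(self, pressure: float) -> float:
        frac = (pressure - self.p_dia) / (self.p_sys - self.p_dia)
        return self.r_dia * (1.0 + self.compliance * frac)

    def force_and_stiffness(self, radius: float, scale: float = 1.0):
        """(radial force on stent [N, negative=inward], d force / d radius)."""
        gap = radius - self.natural_radius(self.pressure)
        if gap <= 0.0:
            return 0.0, 0.0
        return -scale * self.k_radial * gap, -scale * self.k_radial


class Frame2D:
    """Planar corotational elastoplastic frame with a circumference dof.

    Parameters
    ----------
    nodes : (N, 2) array
        Reference coordinates (circumferential x, axial y) in mm.
    elements : (nel, 2) int array
        Node pairs.
    wrap : (nel,) bool array, optional
        Elements whose second node is the periodic image offset by the
        ring circumference.
    section : FiberSection
    circumference : float, optional
        Reference period C0 of the unrolled ring; required if any
        element wraps.
    """

    def __init__(self, nodes, elements, section: FiberSection, *, wrap=None,
                 circumference: float | None = None):
        self.X = np.asarray(nodes, dtype=float)
        self.elems = np.asarray(elements, dtype=int)
        nel = len(self.elems)
        self.wrap = np.zeros(nel, bool) if wrap is None else np.asarray(wrap, bool)
        if self.wrap.any() and circumference is None:
            raise ConfigError("wrap elements need a reference circumference")
        self.C0 = float(circumference) if circumference is not None else 0.0
        self.section = section
        self.n_nodes = len(self.X)
        self.ndof = 3 * self.n_nodes + 1  # last dof: circumference change
        self.CDOF = self.ndof - 1
        self._check_connected()

        # reference element geometry
        off = np.zeros((nel, 2))
        off[self.wrap, 0] = self.C0
        d = self.X[self.elems[:, 1]] + off - self.X[self.elems[:, 0]]
        self.L0 = np.hypot(d[:, 0], d[:, 1])
        if np.any(self.L0 <= 0):
            raise ConfigError("zero-length element")
        self.beta0 = np.arctan2(d[:, 1], d[:, 0])

        nf = section.n_fibers
        # committed history; ep_sub holds the overlay sublayers' plastic
        # strains, eps_p is the derived total plastic strain per fiber
        self.u = np.zeros(self.ndof)
        self.ep_sub = np.zeros((nel, 2, nf, 1))
        self.eps_p = np.zeros((nel, 2, nf))
        self.sigma = np.zeros((nel, 2, nf))
        self.eps_total = np.zeros((nel, 2, nf))
        self.peak_strain = np.zeros((nel, 2))
        self.D = np.zeros((nel, 2))
        self.active = np.ones((nel, 2), bool)

        # per-gauss material: modulus plus overlay sublayer parameters
        self.E = np.full((nel, 2), np.nan)
        self.ep_grid = None
        self.sub_E = None
        self.sub_eps_y = None
        self.fail_strain = np.full((nel, 2), np.inf)

        self.constraints: dict[int, float] = {self.CDOF: 0.0}
        self.nodal_loads = np.zeros(self.ndof)
        self.load_factor = 0.0
        self.vessel: VesselSpring | None = None
        self.vessel_scale = 0.0
        self.log: list[dict] = []
        self.rtol = 1e-6
        self.atol = 1e-9
        self.max_iter = 50

    # -- setup ---------------------------------------------------------------

    def _check_connected(self):
        import scipy.sparse as sp
        from scipy.sparse.csgraph import connected_components

        rows, cols = self.elems[:, 0], self.elems[:, 1]
        adj = sp.coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(self.n_nodes, self.n_nodes)
        )
        ncomp, _ = connected_components(adj, directed=False)
        if ncomp != 1:
            raise ConfigError(f"mesh must be a single connected component, found {ncomp}")

    @staticmethod
    def _overlay(E: float, ep: np.ndarray, sy: np.ndarray):
        """Besseling overlay decomposition of a multilinear hardening curve.

        The fiber is represented as parallel elastic-perfectly-plastic
        sublayers: sublayer j has modulus w_j E and yields at total
        strain eps_j = ep_j + sy_j / E. The weights w_j reproduce the
        tabulated tangent moduli, the response is multilinear kinematic
        (Masing) under load reversal, and the return mapping is closed
        form per sublayer. Requires non-increasing tangent moduli
        (a concave hardening curve); the response is flat beyond the
        last tabulated point.

        Returns (sublayer moduli, sublayer yield strains), each (ns,).
        """
        eps_y = ep + sy / E
        n = len(eps_y)
        if n == 1:
            return np.array([E]), eps_y.copy()
        tangents = np.diff(sy) / np.diff(eps_y)
        if np.any(tangents > E * (1 + 1e-9)) or np.any(np.diff(tangents) > 1e-9 * E):
            raise ConfigError(
                "hardening curve must be concave with tangent modulus below E"
            )
        r = np.concatenate([[1.0], np.clip(tangents, 0.0, None) / E, [0.0]])
        w = r[:-1] - r[1:]
        return np.clip(w, 0.0, None) * E, eps_y.copy()

    def set_material(self, curve) -> None:
        """Assign one material curve to every Gauss point."""
        nel = len(self.elems)
        nf = self.section.n_fibers
        self.ep_grid = np.array(curve.plastic_curve[:, 0], dtype=float)
        ns = len(self.ep_grid)
        sub_E, sub_eps = self._overlay(
            curve.elastic_modulus, self.ep_grid, curve.plastic_curve[:, 1]
        )
        self.sub_E = np.tile(sub_E, (nel, 2, 1)).astype(float)
        self.sub_eps_y = np.tile(sub_eps, (nel, 2, 1)).astype(float)
        self.ep_sub = np.zeros((nel, 2, nf, ns))
        self.E[:] = curve.elastic_modulus
        self.fail_strain[:] = curve.failure_strain

    def set_point_material(self, el: int, g: int, curve) -> None:
        """Assign a material curve to one Gauss point (resampled onto the
        shared plastic-strain grid). Sublayer plastic memory is kept."""
        if self.ep_grid is None:
            raise ConfigError("call set_material before per-point updates")
        sy = np.interp(self.ep_grid, curve.plastic_curve[:, 0], curve.plastic_curve[:, 1])
        sub_E, sub_eps = self._overlay(curve.elastic_modulus, self.ep_grid, sy)
        self.sub_E[el, g] = sub_E
        self.sub_eps_y[el, g] = sub_eps
        self.E[el, g] = curve.elastic_modulus
        self.fail_strain[el, g] = curve.failure_strain

    def fix(self, node: int, dofs=(0, 1, 2), value: float = 0.0) -> None:
        for d in dofs:
            self.constraints[3 * node + d] = value

    @property
    def circumference(self) -> float:
        return self.C0 + self.u[self.CDOF]

    # -- mechanics -----------------------------------------------------------

    def _constitutive(self, eps):
        """Closed-form overlay update of every fiber.

        ``eps`` is (nel, 2, nf). Returns (sigma, tangent modulus,
        updated sublayer plastic strains), the first two (nel, 2, nf),
        the last (nel, 2, nf, ns).
        """
        scale = np.where(self.active, 1.0, RESIDUAL_STIFFNESS)[:, :, None, None]
        Ej = self.sub_E[:, :, None, :] * scale  # (nel, 2, nf, ns)
        Yj = Ej * self.sub_eps_y[:, :, None, :]
        trial = Ej * (eps[..., None] - self.ep_sub)
        yielded = np.abs(trial) > Yj * (1 + 1e-12)
        sig_sub = np.clip(trial, -Yj, Yj)
        ep_sub = np.where(
            yielded,
            eps[..., None] - np.sign(trial) * self.sub_eps_y[:, :, None, :],
            self.ep_sub,
        )
        sigma = sig_sub.sum(axis=3)
        Et = np.where(yielded, 0.0, Ej).sum(axis=3)
        # keep a numerical floor so tangents stay positive definite
        Et = np.maximum(Et, RESIDUAL_STIFFNESS * self.E[..., None] * scale[..., 0])
        return sigma, Et, ep_sub

    def _element_kinematics(self, u):
        """Current element geometry and local generalized strains."""
        nel = len(self.elems)
        disp = u[: 3 * self.n_nodes].reshape(-1, 3)
        xy = self.X + disp[:, :2]
        off = np.zeros((nel, 2))
        off[self.wrap, 0] = self.C0 + u[self.CDOF]
        d = xy[self.elems[:, 1]] + off - xy[self.elems[:, 0]]
        Ln = np.hypot(d[:, 0], d[:, 1])
        if np.any(Ln < 1e-12):
            raise SolverError("element collapsed to zero length")
        beta = np.arctan2(d[:, 1], d[:, 0])
        rigid = beta - self.beta0
        th1 = disp[self.elems[:, 0], 2]
        th2 = disp[self.elems[:, 1], 2]
        wrap_angle = lambda x: (x + np.pi) % (2 * np.pi) - np.pi
        tl1 = wrap_angle(th1 - rigid)
        tl2 = wrap_angle(th2 - rigid)
        ubar = Ln - self.L0
        return d, Ln, beta, ubar, tl1, tl2

    def _assemble(self, u, want_tangent=True):
        """Internal force vector, tangent, and trial state arrays."""
        nel = len(self.elems)
        nf = self.section.n_fibers
        z = self.section.z
        aw = self.section.area_weights

        d, Ln, beta, ubar, tl1, tl2 = self._element_kinematics(u)
        eps0 = ubar / self.L0
        # curvature at the two Gauss points from the local rotation field
        b2_1 = (6.0 * _XI - 4.0)  # x 1/L0
        b2_2 = (6.0 * _XI - 2.0)
        kappa = (tl1[:, None] * b2_1[None, :] + tl2[:, None] * b2_2[None, :]) / self.L0[:, None]
        eps = eps0[:, None, None] + kappa[:, :, None] * z[None, None, :]

        sigma, Et, ep_sub = self._constitutive(eps)
        N = np.einsum("egf,f->eg", sigma, aw)
        M = np.einsum("egf,f->eg", sigma * z[None, None, :], aw)
        # local nodal forces (conjugates of ubar, tl1, tl2); Gauss weight L0/2
        Nbar = N.mean(axis=1)
        M1 = 0.5 * (M * b2_1[None, :]).sum(axis=1)
        M2 = 0.5 * (M * b2_2[None, :]).sum(axis=1)

        c = np.cos(beta)
        s = np.sin(beta)
        zero = np.zeros(nel)
        b1 = np.stack([-c, -s, zero, c, s, zero], axis=1)
        b2 = np.stack([s, -c, zero, -s, c, zero], axis=1)
        e3 = np.zeros((nel, 6))
        e3[:, 2] = 1.0
        e6 = np.zeros((nel, 6))
        e6[:, 5] = 1.0
        r1 = e3 - b2 / Ln[:, None]
        r2 = e6 - b2 / Ln[:, None]
        f_el = b1 * Nbar[:, None] + r1 * M1[:, None] + r2 * M2[:, None]

        f_int = np.zeros(self.ndof)
        edofs = np.empty((nel, 6), dtype=int)
        edofs[:, 0:3] = 3 * self.elems[:, 0:1] + np.arange(3)
        edofs[:, 3:6] = 3 * self.elems[:, 1:2] + np.arange(3)
        np.add.at(f_int, edofs, f_el)
        # gross force scale: |element force| assembly; unlike f_int it does
        # not cancel in self-equilibrated states and anchors the relative
        # convergence measure
        f_gross = np.zeros(self.ndof)
        np.add.at(f_gross, edofs, np.abs(f_el))
        self._gross_norm = float(np.linalg.norm(f_gross))
        w = self.wrap
        if w.any():
            f_int[self.CDOF] += f_el[w, 3].sum()

        K = None
        if want_tangent:
            # section tangents per Gauss point
            EtA = np.einsum("egf,f->eg", Et, aw)
            EtS = np.einsum("egf,f->eg", Et * z[None, None, :], aw)
            EtI = np.einsum("egf,f->eg", Et * z[None, None, :] ** 2, aw)
            kl = np.zeros((nel, 3, 3))
            for g in range(2):
                Bl = np.zeros((nel, 2, 3))
                Bl[:, 0, 0] = 1.0 / self.L0
                Bl[:, 1, 1] = b2_1[g] / self.L0
                Bl[:, 1, 2] = b2_2[g] / self.L0
                Dg = np.zeros((nel, 2, 2))
                Dg[:, 0, 0] = EtA[:, g]
                Dg[:, 0, 1] = Dg[:, 1, 0] = EtS[:, g]
                Dg[:, 1, 1] = EtI[:, g]
                kl += (self.L0 / 2.0)[:, None, None] * np.einsum(
                    "eji,ejk,ekl->eil", Bl, Dg, Bl
                )
            B = np.stack([b1, r1, r2], axis=1)  # (nel, 3, 6)
            K_el = np.einsum("eij,eik,ekl->ejl", B, kl, B)
            K_el += (Nbar / Ln)[:, None, None] * np.einsum("ei,ej->eij", b2, b2)
            mm = ((M1 + M2) / Ln**2)[:, None, None]
            K_el += mm * (
                np.einsum("ei,ej->eij", b1, b2) + np.einsum("ei,ej->eij", b2, b1)
            )
            K = np.zeros((self.ndof, self.ndof))
            np.add.at(K, (edofs[:, :, None], edofs[:, None, :]), K_el)
            if w.any():
                np.add.at(K, (np.full(w.sum(), self.CDOF)[:, None], edofs[w]), K_el[w, 3, :])
                np.add.at(K, (edofs[w], np.full(w.sum(), self.CDOF)[:, None]), K_el[w, :, 3])
                K[self.CDOF, self.CDOF] += K_el[w, 3, 3].sum()

        trial = {"sigma": sigma, "eps": eps, "ep_sub": ep_sub}
        return f_int, K, trial

    def _external(self, u, want_tangent=True):
        f_ext = self.load_factor * self.nodal_loads.copy()
        kc = 0.0
        if self.vessel is not None and self.vessel_scale > 0.0:
            R = (self.C0 + u[self.CDOF]) / (2.0 * np.pi)
            F, dFdR = self.vessel.force_and_stiffness(R, self.vessel_scale)
            f_ext[self.CDOF] += F / (2.0 * np.pi)
            kc = dFdR / (2.0 * np.pi) ** 2
        return f_ext, kc

    # -- solving -------------------------------------------------------------

    def _free_dofs(self):
        fixed = np.fromiter(self.constraints.keys(), int) if self.constraints else np.array([], int)
        mask = np.ones(self.ndof, bool)
        mask[fixed] = False
        return np.flatnonzero(mask)

    def solve_equilibrium(self) -> dict:
        """Newton iteration to equilibrium at the current constraint and
        load settings; commits plastic state on convergence."""
        free = self._free_dofs()
        u = self.u.copy()
        for dof, val in self.constraints.items():
            u[dof] = val
        stats = {"iterations": 0, "residual": np.inf, "reference": 0.0}
        res_prev = None
        for it in range(self.max_iter):
            f_int, K, trial = self._assemble(u)
            f_ext, kc = self._external(u)
            R = f_int - f_ext
            ref = max(self._gross_norm, np.linalg.norm(f_ext), 1e-12)
            rn = np.linalg.norm(R[free])
            stats.update(iterations=it, residual=float(rn), reference=float(ref))
            if rn <= self.rtol * ref + self.atol:
                self.u = u
                self._commit(trial)
                self.log.append({"event": "converged", **stats})
                return stats
            Kff = K[np.ix_(free, free)].copy()
            if kc != 0.0 and self.CDOF in free:
                i = int(np.flatnonzero(free == self.CDOF)[0])
                Kff[i, i] -= kc
            try:
                du = np.linalg.solve(Kff, -R[free])
            except np.linalg.LinAlgError as exc:
                raise SolverError("singular tangent", {"iteration": it}) from exc
            # shallow line search: prefer a descent step, otherwise the
            # best of a few large fractions of the Newton step — full
            # steps may transiently raise the residual on their way to
            # quadratic convergence, and deep backtracking would stall
            best = None
            for step in (1.0, 0.5, 0.25, 0.125):
                u_try = u.copy()
                u_try[free] += step * du
                try:
                    f_i, _, _ = self._assemble(u_try, want_tangent=False)
                except SolverError:
                    continue
                f_e, _ = self._external(u_try)
                rn_try = np.linalg.norm((f_i - f_e)[free])
                if best is None or rn_try < best[0]:
                    best = (rn_try, step)
                if rn_try < rn:
                    break
            if best is None:
                raise SolverError("line search failed", {"iteration": it})
            u[free] += best[1] * du
            res_prev = rn
        raise SolverError(
            "no convergence within max iterations",
            {"iterations": self.max_iter, "residual": float(res_prev or np.inf)},
        )

    def _commit(self, trial):
        self.ep_sub = trial["ep_sub"]
        self.sigma = np.where(self.active[..., None], trial["sigma"], 0.0)
        self.eps_total = trial["eps"]
        self.eps_p = trial["eps"] - trial["sigma"] / self.E[..., None]
        self.peak_strain = np.maximum(self.peak_strain, trial["eps"].max(axis=2))

    def run_stage(self, set_controls, n_inc: int = 10, max_bisect: int = 7) -> dict:
        """Drive a loading stage from its current point to completion.

        ``set_controls(lam)`` with lam in (0, 1] updates constraints,
        load factor or vessel scale; the stage is walked in ``n_inc``
        increments with recursive bisection on non-convergence.
        """
        lam = 0.0
        dlam = 1.0 / n_inc
        min_dlam = dlam / 2**max_bisect
        last = {}
        while lam < 1.0 - 1e-12:
            step = min(dlam, 1.0 - lam)
            target = lam + step
            saved = (self.u.copy(), self.ep_sub.copy(), self.eps_p.copy(),
                     self.sigma.copy(), self.eps_total.copy(), self.peak_strain.copy())
            set_controls(target)
            try:
                last = self.solve_equilibrium()
            except SolverError as exc:
                self.u, self.ep_sub, self.eps_p, self.sigma, self.eps_total, self.peak_strain = saved
                dlam = step / 2.0
                if dlam < min_dlam:
                    raise SolverError(
                        f"stage failed near lambda={lam:.4f}", exc.diagnostics
                    ) from exc
                continue
            lam = target
            if last["iterations"] <= 5:
                dlam = min(dlam * 1.5, 1.0 / n_inc)
        return last

    # -- reporting -----------------------------------------------------------

    def point_stress(self) -> np.ndarray:
        """Signed extreme-fiber stress per Gauss point, (nel, 2)."""
        idx = np.argmax(np.abs(self.sigma), axis=2)
        g = np.indices(idx.shape)
        return self.sigma[g[0], g[1], idx]

    def max_abs_stress(self) -> float:
        return float(np.max(np.abs(self.sigma)))

    def reaction(self, dof: int) -> float:
        f_int, _, _ = self._assemble(self.u, want_tangent=False)
        f_ext, _ = self._external(self.u)
        return float(f_int[dof] - f_ext[dof])

    def residual_ratio(self) -> float:
        """||R_free|| relative to the gross force scale at the committed state."""
        free = self._free_dofs()
        f_int, _, _ = self._assemble(self.u, want_tangent=False)
        f_ext, _ = self._external(self.u)
        ref = max(self._gross_norm, np.linalg.norm(f_ext), 1e-12)
        return float(np.linalg.norm((f_int - f_ext)[free]) / ref)
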