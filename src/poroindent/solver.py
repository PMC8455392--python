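"""Axisymmetric biphasic finite-element solver for cartilage indentation.

Discretization
--------------
Mixed displacement/pressure (u-p) formulation of incompressible-constituent
poroelasticity on the structured Taylor-Hood meshes of :mod:`poroindent.mesh`
(biquadratic displacement, bilinear pressure).  Kinematics are finite-strain
(total Lagrangian); the solid stress is the FRPE law of
:mod:`poroindent.material` (tension-only fibrils aligned with the articular
surface, i.e. the radial and hoop directions, plus a compressible
Neo-Hookean non-fibrillar matrix), and Darcy flow uses the strain-dependent
permeability k = k0 * J^M (void-ratio power law with incompressible
constituents).  Time stepping is backward Euler with geometric step growth
during relaxation holds.  The Newton tangent is assembled element-by-element
from finite differences of the element residual, evaluated in one batched
vectorized pass.

Boundary conditions (indentation mode)
--------------------------------------
Bottom bonded to bone (fixed, impermeable); symmetry on the axis; free
draining (p = 0) on the outer radius and on the top surface outside the
indenter; impermeable and displacement-driven under the indenter
('bonded' contact fixes u_r there too, 'smooth' leaves it free).
A 'confined' mode reproduces confined compression: zero radial displacement
everywhere, the whole top surface displaced and drained, sealed elsewhere.

Units: mm, s, N, MPa; permeability in mm^4 N^-1 s^-1 internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .exceptions import ConvergenceError, DegenerateDeformationError, ProtocolError
from .material import ConstitutiveConstants, FRPEParameters, lame_parameters
from .mesh import Mesh, SampleGeometry, build_mesh
from .protocol import (
    PRE_STRESS_MPA,
    LoadingProtocol,
    paper_protocol,
)

__all__ = [
    "SolverSettings",
    "SimulationResult",
    "simulate",
    "simulate_paper_protocol",
    "solve_drained",
    "find_prestress_depth",
]

#: smoothing half-width (strain) of the tension-only switch in the solver
_FIBRIL_SMOOTH = 2e-3

_GAUSS_1D = (-np.sqrt(0.6), 0.0, np.sqrt(0.6))
_GAUSS_W = (5.0 / 9.0, 8.0 / 9.0, 5.0 / 9.0)

# Q9 node positions in the reference square, matching mesh connectivity
_Q9_NODES = [(-1, -1), (1, -1), (1, 1), (-1, 1), (0, -1), (1, 0), (0, 1), (-1, 0), (0, 0)]
_Q4_NODES = [(-1, -1), (1, -1), (1, 1), (-1, 1)]


def _lag3(x, pos):
    if pos == -1:
        return 0.5 * x * (x - 1.0)
    if pos == 0:
        return 1.0 - x * x
    return 0.5 * x * (x + 1.0)


def _dlag3(x, pos):
    if pos == -1:
        return x - 0.5
    if pos == 0:
        return -2.0 * x
    return x + 0.5


@dataclass(frozen=True)
class SolverSettings:
    """Newton and time-grid controls.

    ramp_steps      : time steps per displacement ramp
    hold_steps      : time steps per relaxation hold (geometric growth)
    hold_growth     : ratio between successive hold time steps
    steps_per_cycle : time steps per sinusoid cycle
    newton_rtol/atol, max_iterations : Newton convergence controls
    """

    ramp_steps: int = 5
    hold_steps: int = 16
    hold_growth: float = 1.6
    steps_per_cycle: int = 24
    newton_rtol: float = 1e-6
    newton_atol: float = 1e-9
    newton_stall_frac: float = 1e-2
    max_iterations: int = 60

    @classmethod
    def preset(cls, name: str) -> "SolverSettings":
        presets = {
            "coarse": cls(ramp_steps=3, hold_steps=10, hold_growth=1.9, steps_per_cycle=16),
            "default": cls(),
            "fine": cls(ramp_steps=8, hold_steps=24, hold_growth=1.4, steps_per_cycle=32),
        }
        try:
            return presets[name]
        except KeyError:
            raise ValueError(f"unknown preset {name!r}") from None


@dataclass
class SimulationResult:
    """Reaction-force history of a displacement-driven simulation.

    time         : s, strictly increasing, starting at 0
    displacement : indentation depth (mm, >= 0 into the tissue)
    force        : axial reaction force on the indenter (N, compression > 0)
    segments     : protocol annotations [{label, kind, t_start, t_end, ...}]
    start_depth  : equilibrated pre-test depth (mm) the record starts from
    """

    time: np.ndarray
    displacement: np.ndarray
    force: np.ndarray
    segments: list
    start_depth: float = 0.0

    def window(self, t0, t1):
        m = (self.time >= t0 - 1e-12) & (self.time <= t1 + 1e-12)
        return self.time[m], self.displacement[m], self.force[m]


class _Assembler:
    """Precomputed element data plus batched residual/tangent evaluation."""

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        conn9, conn4 = mesh.conn9, mesh.conn4
        ne = mesh.n_elements

        pts, wts = [], []
        for i, xi in enumerate(_GAUSS_1D):
            for j, eta in enumerate(_GAUSS_1D):
                pts.append((xi, eta))
                wts.append(_GAUSS_W[i] * _GAUSS_W[j])
        self.nq = len(pts)

        N9 = np.empty((self.nq, 9))
        dN9xi = np.empty((self.nq, 9))
        dN9eta = np.empty((self.nq, 9))
        N4 = np.empty((self.nq, 4))
        dN4xi = np.empty((self.nq, 4))
        dN4eta = np.empty((self.nq, 4))
        for q, (xi, eta) in enumerate(pts):
            for n, (px, pe) in enumerate(_Q9_NODES):
                N9[q, n] = _lag3(xi, px) * _lag3(eta, pe)
                dN9xi[q, n] = _dlag3(xi, px) * _lag3(eta, pe)
                dN9eta[q, n] = _lag3(xi, px) * _dlag3(eta, pe)
            for n, (px, pe) in enumerate(_Q4_NODES):
                N4[q, n] = 0.25 * (1 + xi * px) * (1 + eta * pe)
                dN4xi[q, n] = 0.25 * px * (1 + eta * pe)
                dN4eta[q, n] = 0.25 * pe * (1 + xi * px)

        r0 = mesh.r9[conn9[:, 0]]
        r1 = mesh.r9[conn9[:, 1]]
        z0 = mesh.z9[conn9[:, 0]]
        z1 = mesh.z9[conn9[:, 3]]
        hr = 0.5 * (r1 - r0)  # (ne,)
        hz = 0.5 * (z1 - z0)
        rc = 0.5 * (r1 + r0)
        zc = 0.5 * (z1 + z0)

        xi_q = np.array([p[0] for p in pts])
        eta_q = np.array([p[1] for p in pts])
        self.Rq = rc[:, None] + hr[:, None] * xi_q[None, :]  # (ne, nq)
        self.Zq = zc[:, None] + hz[:, None] * eta_q[None, :]
        wq = np.array(wts)
        self.w = 2.0 * np.pi * self.Rq * (hr * hz)[:, None] * wq[None, :]

        # physical shape-function gradients, (ne, nq, nodes)
        self.N9 = np.broadcast_to(N9, (ne, self.nq, 9))
        self.N4 = np.broadcast_to(N4, (ne, self.nq, 4))
        self.dN9r = dN9xi[None] / hr[:, None, None]
        self.dN9z = dN9eta[None] / hz[:, None, None]
        self.dN4r = dN4xi[None] / hr[:, None, None]
        self.dN4z = dN4eta[None] / hz[:, None, None]

        self.ndof_u = 2 * mesh.n_disp_nodes
        self.ndof = self.ndof_u + mesh.n_pressure_nodes
        # element dof map: [u_r(9), u_z(9), p(4)] -> global
        self.edof = np.concatenate(
            [2 * conn9, 2 * conn9 + 1, self.ndof_u + conn4], axis=1
        )  # (ne, 22)

    # -- kinematics + constitutive evaluation on a batch ------------------

    def _stress_state(self, ur, uz, pe, params, constants):
        """Batched kinematics and Cauchy stress.

        ur, uz : (..., ne, 9); pe : (..., ne, 4).  Returns dict of (..., ne, nq)
        fields.
        """
        dN9r, dN9z, N9, N4 = self.dN9r, self.dN9z, self.N9, self.N4
        Frr = 1.0 + np.einsum("eqi,...ei->...eq", dN9r, ur)
        Frz = np.einsum("eqi,...ei->...eq", dN9z, ur)
        Fzr = np.einsum("eqi,...ei->...eq", dN9r, uz)
        Fzz = 1.0 + np.einsum("eqi,...ei->...eq", dN9z, uz)
        ur_q = np.einsum("eqi,...ei->...eq", N9, ur)
        Ftt = 1.0 + ur_q / self.Rq
        detp = Frr * Fzz - Frz * Fzr
        J = Ftt * detp
        if np.any(J <= 0.0) or np.any(detp <= 0.0):
            raise DegenerateDeformationError("element inversion (J <= 0)")

        lam, mu = lame_parameters(params.Enf, constants.nu_nf)
        lnJ = np.log(J)
        # Neo-Hookean Cauchy, in-plane components + hoop
        s_rr = (mu * (Frr * Frr + Frz * Frz - 1.0) + lam * lnJ) / J
        s_zz = (mu * (Fzr * Fzr + Fzz * Fzz - 1.0) + lam * lnJ) / J
        s_rz = mu * (Frr * Fzr + Frz * Fzz) / J
        s_tt = (mu * (Ftt * Ftt - 1.0) + lam * lnJ) / J

        # tension-only fibrils: radial family (deforms with F e_R) and hoop.
        # The tensile ramp max(eps, 0) is smoothed over ~_FIBRIL_SMOOTH strain
        # so the Newton tangent is continuous at the tension/compression
        # switch (raw kinks cause active-set chatter at the punch edge); the
        # stress perturbation is O(Ef0 * _FIBRIL_SMOOTH), far below solver
        # tolerance.
        def tension(eps):
            # C1 ramp: exactly zero in compression, eps - d/2 beyond the
            # blend, quadratic in between (d = _FIBRIL_SMOOTH)
            d = _FIBRIL_SMOOTH
            ep = np.where(
                eps <= 0.0, 0.0,
                np.where(eps >= d, eps - 0.5 * d, eps * eps / (2.0 * d)),
            )
            return (params.Ef0 + params.EfEps * ep) * ep

        lam_r = np.sqrt(Frr * Frr + Fzr * Fzr)
        mag_r = tension(lam_r - 1.0)
        mr_r = Frr / lam_r
        mr_z = Fzr / lam_r
        s_rr = s_rr + mag_r * mr_r * mr_r
        s_rz = s_rz + mag_r * mr_r * mr_z
        s_zz = s_zz + mag_r * mr_z * mr_z
        s_tt = s_tt + tension(Ftt - 1.0)

        p_q = np.einsum("eqi,...ei->...eq", N4, pe)
        s_rr = s_rr - p_q
        s_zz = s_zz - p_q
        s_tt = s_tt - p_q

        return dict(
            Frr=Frr, Frz=Frz, Fzr=Fzr, Fzz=Fzz, Ftt=Ftt, detp=detp, J=J,
            s_rr=s_rr, s_rz=s_rz, s_zz=s_zz, s_tt=s_tt,
        )

    def jacobian_field(self, x):
        """Volumetric Jacobian J at every quadrature point for state x."""
        ur, uz, pe = self._gather(x[None])
        st = self._stress_state(ur, uz, pe, _NEUTRAL_PARAMS, _NEUTRAL_CONSTANTS)
        return st["J"][0]

    def _gather(self, X):
        """X: (B, ndof) -> per-element dof blocks (B, ne, ...)."""
        el = X[:, self.edof]  # (B, ne, 22)
        return el[..., 0:9], el[..., 9:18], el[..., 18:22]

    def residual_batch(self, X, J_old, dt, params, constants, transient=True):
        """Element residuals (B, ne, 22) for a batch of global states X (B, ndof)."""
        return self._residual_from_element_dofs(
            X[:, self.edof], J_old, dt, params, constants, transient
        )

    def residual_and_tangent(self, x, J_old, dt, params, constants, transient=True):
        """Global residual (ndof,) and element tangent blocks (ne, 22, 22)."""
        ne = self.mesh.n_elements
        base = x[self.edof]  # (ne, 22)
        h = 1e-8 * (1.0 + np.abs(base))  # (ne, 22)
        # batch: index 0 = base, 1+j = dof j perturbed
        X = np.repeat(x[None, :], 23, axis=0)
        # perturbations must be applied per-element, so work in element space:
        EL = np.repeat(base[None, :, :], 23, axis=0)  # (23, ne, 22)
        for j in range(22):
            EL[1 + j, :, j] += h[:, j]
        Rel = self._residual_from_element_dofs(EL, J_old, dt, params, constants, transient)
        R0 = Rel[0]  # (ne, 22)
        K = (Rel[1:] - R0[None]) / h.T[:, :, None]  # (22, ne, 22)
        K = np.transpose(K, (1, 2, 0))  # (ne, i, j)
        Rg = np.zeros(self.ndof)
        np.add.at(Rg, self.edof.ravel(), R0.ravel())
        return Rg, K

    def _residual_from_element_dofs(self, EL, J_old, dt, params, constants, transient):
        ur, uz, pe = EL[..., 0:9], EL[..., 9:18], EL[..., 18:22]
        st = self._stress_state(ur, uz, pe, params, constants)
        # reuse residual_batch internals by faking gather: inline computation
        J = st["J"]
        detp = st["detp"]
        Ftt = st["Ftt"]
        P_rR = Ftt * (st["s_rr"] * st["Fzz"] - st["s_rz"] * st["Fzr"])
        P_rZ = Ftt * (-st["s_rr"] * st["Frz"] + st["s_rz"] * st["Frr"])
        P_zR = Ftt * (st["s_rz"] * st["Fzz"] - st["s_zz"] * st["Fzr"])
        P_zZ = Ftt * (-st["s_rz"] * st["Frz"] + st["s_zz"] * st["Frr"])
        P_tt = J * st["s_tt"] / Ftt
        w = self.w
        R_ur = (
            np.einsum("...eq,eqi->...ei", w * P_rR, self.dN9r)
            + np.einsum("...eq,eqi->...ei", w * P_rZ, self.dN9z)
            + np.einsum("...eq,eqi->...ei", w * P_tt / self.Rq, self.N9)
        )
        R_uz = (
            np.einsum("...eq,eqi->...ei", w * P_zR, self.dN9r)
            + np.einsum("...eq,eqi->...ei", w * P_zZ, self.dN9z)
        )
        if transient:
            dp_dR = np.einsum("eqi,...ei->...eq", self.dN4r, pe)
            dp_dZ = np.einsum("eqi,...ei->...eq", self.dN4z, pe)
            g_r = (st["Fzz"] * dp_dR - st["Fzr"] * dp_dZ) / detp
            g_z = (-st["Frz"] * dp_dR + st["Frr"] * dp_dZ) / detp
            k = params.k0_internal * J ** params.M
            c_r = w * k * J * g_r
            c_z = w * k * J * g_z
            q_R = (st["Fzz"] * c_r - st["Frz"] * c_z) / detp
            q_Z = (-st["Fzr"] * c_r + st["Frr"] * c_z) / detp
            R_p = (
                np.einsum("...eq,eqi->...ei", w * (J - J_old) / dt, self.N4)
                + np.einsum("...eq,eqi->...ei", q_R, self.dN4r)
                + np.einsum("...eq,eqi->...ei", q_Z, self.dN4z)
            )
        else:
            R_p = np.zeros(pe.shape)
        return np.concatenate([R_ur, R_uz, R_p], axis=-1)


_NEUTRAL_PARAMS = FRPEParameters(Ef0=0.0, EfEps=0.0, Enf=1.0, k0=1.0, M=0.0)
_NEUTRAL_CONSTANTS = ConstitutiveConstants()


@dataclass
class _BC:
    """Dirichlet bookkeeping: fixed mask and value vector over all dofs."""

    fixed: np.ndarray  # bool (ndof,)
    values: np.ndarray  # float (ndof,)
    contact_zdofs: np.ndarray  # dof indices carrying the indenter reaction

    def free(self):
        return ~self.fixed


def _make_bc(asm: _Assembler, mode: str, contact: str, transient: bool) -> _BC:
    mesh = asm.mesh
    ndof_u = asm.ndof_u
    fixed = np.zeros(asm.ndof, dtype=bool)
    ns, ps = mesh.node_sets, mesh.pnode_sets
    zdof = lambda m: 2 * np.flatnonzero(m) + 1
    rdof = lambda m: 2 * np.flatnonzero(m)

    if mode == "indentation":
        fixed[rdof(ns["bottom"])] = True
        fixed[zdof(ns["bottom"])] = True
        fixed[rdof(ns["axis"])] = True
        contact_nodes = ns["contact"]
        fixed[zdof(contact_nodes)] = True
        if contact == "bonded":
            fixed[rdof(contact_nodes & ~ns["axis"])] = True
        elif contact != "smooth":
            raise ValueError(f"unknown contact model {contact!r}")
        pfix = ps["top_outside"] | ps["outer"]
        contact_zdofs = zdof(contact_nodes)
    elif mode == "confined":
        fixed[0:ndof_u:2] = True  # all radial dofs
        fixed[zdof(ns["bottom"])] = True
        fixed[zdof(ns["top"])] = True
        pfix = ps["top"]
        contact_zdofs = zdof(ns["top"])
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if transient:
        fixed[ndof_u + np.flatnonzero(pfix)] = True
    else:
        fixed[ndof_u:] = True  # drained: no pressure unknowns
    return _BC(fixed=fixed, values=np.zeros(asm.ndof), contact_zdofs=contact_zdofs)


def _bc_index_cache(asm, bc):
    if getattr(bc, "_cache", None) is None:
        free = bc.free()
        nfree = int(free.sum())
        free_index = -np.ones(asm.ndof, dtype=np.int64)
        free_index[free] = np.arange(nfree)
        er = free_index[asm.edof]  # (ne, 22)
        rows = np.repeat(er[:, :, None], 22, axis=2)
        cols = np.repeat(er[:, None, :], 22, axis=1)
        keep = (rows >= 0) & (cols >= 0)
        bc._cache = (free, nfree, rows[keep], cols[keep], keep)
    return bc._cache


def _newton(asm, x, J_old, dt, params, constants, bc, settings, transient, t=None,
            force_scale=0.0):
    """Newton with a lazily re-assembled finite-difference tangent: the
    factorized tangent is reused across iterations while the residual keeps
    contracting, which is where nearly all assembly cost is saved."""
    free, nfree, rows, cols, keep = _bc_index_cache(asm, bc)

    def residual_only(x):
        Rel = asm.residual_batch(x[None], J_old, dt, params, constants, transient)[0]
        Rg = np.zeros(asm.ndof)
        np.add.at(Rg, asm.edof.ravel(), Rel.ravel())
        return Rg

    scale = 1.0 / np.sqrt(max(nfree, 1))  # RMS norm: size-independent tolerances

    Rg = residual_only(x)
    nrm = scale * np.linalg.norm(Rg[free]) if nfree else 0.0
    ref = max(nrm, settings.newton_atol)
    tol = max(settings.newton_atol, settings.newton_rtol * ref)
    # near-singular (wrinkling-like) modes at the punch edge bound the
    # attainable residual at deep indentation; a stalled iterate whose
    # imbalance is negligible against the simulation's force scale is accepted
    stall = max(10.0 * settings.newton_atol, settings.newton_stall_frac * force_scale)
    it = 0
    while it < settings.max_iterations:
        if nrm <= tol:
            return x, Rg, it
        _, K = asm.residual_and_tangent(x, J_old, dt, params, constants, transient)
        A = sp.coo_matrix((K[keep], (rows, cols)), shape=(nfree, nfree)).tocsc()
        # symmetric diagonal equilibration tames the disparate u/p scales
        d = np.sqrt(np.abs(A.diagonal()))
        d[d <= 0] = 1.0
        Dinv = sp.diags(1.0 / d)
        lu = spla.splu((Dinv @ A @ Dinv).tocsc())

        def solve_lin(b):
            y = lu.solve(b / d) / d
            r2 = A @ y - b  # one step of iterative refinement
            y -= lu.solve(r2 / d) / d
            return y

        fresh = True
        while it < settings.max_iterations:
            dx = solve_lin(-Rg[free])
            # backtracking line search: only strictly decreasing steps accepted
            step, accepted = 1.0, False
            for _bt in range(11):
                x_try = x.copy()
                x_try[free] += step * dx
                try:
                    Rg_try = residual_only(x_try)
                except DegenerateDeformationError:
                    step *= 0.5
                    continue
                nrm_try = scale * np.linalg.norm(Rg_try[free])
                if np.isfinite(nrm_try) and nrm_try < nrm:
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                if fresh:
                    # even the exact Newton direction fails to decrease:
                    # accept a physically negligible stalled imbalance
                    if nrm <= stall:
                        return x, Rg, it
                    raise ConvergenceError(
                        f"Newton stalled at |R|={nrm:.3e}", time=t
                    )
                break  # stale tangent: refresh and retry
            x, Rg = x_try, Rg_try
            prev, nrm = nrm, nrm_try
            it += 1
            fresh = False
            if nrm <= tol:
                return x, Rg, it
            if step < 1.0 or nrm > 0.33 * prev:
                break  # slow progress: refresh the tangent
    if nrm <= stall:
        return x, Rg, it
    raise ConvergenceError(
        f"Newton failed after {it} iterations (|R|={nrm:.3e})", time=t
    )


def _reaction(Rg, bc) -> float:
    # compression (u_z < 0 prescribed) -> positive reported force
    return float(-np.sum(Rg[bc.contact_zdofs]))


def _time_grid(protocol: LoadingProtocol, settings: SolverSettings):
    """Per-segment solution times (excluding t=0) and annotations."""
    times = []
    annotations = []
    t0 = 0.0
    for s in protocol.segments:
        t1 = t0 + s.duration
        if s.kind == "ramp":
            seg_t = np.linspace(t0, t1, settings.ramp_steps + 1)[1:]
        elif s.kind == "hold":
            n, g = settings.hold_steps, settings.hold_growth
            dts = g ** np.arange(n)
            dts = dts / dts.sum() * s.duration
            seg_t = t0 + np.cumsum(dts)
        else:
            n_cycles = max(1, int(round(s.duration * s.frequency)))
            n = settings.steps_per_cycle * n_cycles
            seg_t = np.linspace(t0, t1, n + 1)[1:]
        times.append(seg_t)
        annotations.append(
            dict(
                label=s.label,
                kind=s.kind,
                t_start=t0,
                t_end=t1,
                frequency=s.frequency,
                amplitude=s.amplitude,
                target=s.target,
            )
        )
        t0 = t1
    return np.concatenate(times), annotations


def solve_drained(
    mesh_or_asm,
    params: FRPEParameters,
    constants: ConstitutiveConstants,
    depth: float,
    contact: str = "smooth",
    mode: str = "indentation",
    settings: SolverSettings = None,
    x0: np.ndarray = None,
    max_increment_strain: float = 0.02,
):
    """Static drained (equilibrium, p = 0) solve at indentation depth ``depth``.

    Returns (state vector, reaction force N).  The depth is applied in
    displacement increments of at most ``max_increment_strain`` of thickness
    for Newton robustness.
    """
    asm = mesh_or_asm if isinstance(mesh_or_asm, _Assembler) else _Assembler(mesh_or_asm)
    settings = settings or SolverSettings()
    bc = _make_bc(asm, mode, contact, transient=False)
    x = np.zeros(asm.ndof) if x0 is None else x0.copy()
    h = asm.mesh.geometry.thickness
    current = -x[bc.contact_zdofs[0]] if x0 is not None else 0.0
    n_inc = max(1, int(np.ceil(abs(depth - current) / (max_increment_strain * h))))
    Rg = np.zeros(asm.ndof)
    for w in np.linspace(current, depth, n_inc + 1)[1:]:
        x[bc.contact_zdofs] = -w
        x, Rg, _ = _newton(asm, x, None, None, params, constants, bc, settings, transient=False)
    if n_inc == 0 or depth == current:
        x, Rg, _ = _newton(asm, x, None, None, params, constants, bc, settings, transient=False)
    return x, _reaction(Rg, bc)


def find_prestress_depth(
    mesh_or_asm,
    params: FRPEParameters,
    constants: ConstitutiveConstants,
    target_stress: float = PRE_STRESS_MPA,
    contact: str = "smooth",
    settings: SolverSettings = None,
    max_strain: float = 0.2,
    rtol: float = 1e-4,
):
    """Depth (mm) whose drained equilibrium mean contact stress equals
    ``target_stress`` (MPa), by bisection on monotone force-depth response.

    Raises ProtocolError if the target is unreachable below ``max_strain``.
    """
    asm = mesh_or_asm if isinstance(mesh_or_asm, _Assembler) else _Assembler(mesh_or_asm)
    geom = asm.mesh.geometry
    target_force = target_stress * geom.contact_area
    h = geom.thickness

    lo, flo = 0.0, 0.0
    hi = 0.02 * h
    x_warm = None
    f_hi = None
    while True:
        x_warm, f_hi = solve_drained(asm, params, constants, hi, contact, settings=settings, x0=x_warm)
        if f_hi >= target_force:
            break
        if hi >= max_strain * h:
            raise ProtocolError(
                f"pre-stress {target_stress} MPa unreachable below strain {max_strain}"
            )
        lo, flo = hi, f_hi
        hi = min(2.0 * hi, max_strain * h)

    for _ in range(60):
        mid = 0.5 * (lo + hi)
        x_warm, f = solve_drained(asm, params, constants, mid, contact, settings=settings, x0=x_warm)
        if f < target_force:
            lo, flo = mid, f
        else:
            hi, f_hi = mid, f
        if abs(f - target_force) <= rtol * target_force:
            return mid, f
    return 0.5 * (lo + hi), f


def simulate(
    mesh: Mesh,
    params: FRPEParameters,
    constants: ConstitutiveConstants,
    protocol: LoadingProtocol,
    settings: SolverSettings = None,
    mode: str = "indentation",
    contact: str = "smooth",
    initial_state: np.ndarray = None,
) -> SimulationResult:
    """Run a displacement-driven transient simulation of the protocol.

    The record starts at t = 0 from ``initial_state`` (default: the drained
    equilibrium at the protocol's start depth, which is the physically
    equilibrated configuration after pre-stress seeking).
    """
    settings = settings or SolverSettings()
    asm = _Assembler(mesh)
    h = mesh.geometry.thickness
    w_fn = protocol.displacement(mesh.geometry)
    start_depth = protocol.start_strain * h

    if initial_state is None:
        x, f0 = solve_drained(asm, params, constants, start_depth, contact, mode, settings)
    else:
        x = initial_state.copy()
        bc0 = _make_bc(asm, mode, contact, transient=False)
        Rg = asm.residual_and_tangent(x, None, None, params, constants, False)[0]
        f0 = _reaction(Rg, bc0)

    bc = _make_bc(asm, mode, contact, transient=True)
    times, annotations = _time_grid(protocol, settings)
    t_hist = [0.0]
    w_hist = [start_depth]
    f_hist = [f0]

    def advance(x, t_prev, t, x_before=None, dt_before=None, depth=0):
        """One backward-Euler step with a linear predictor for the free dofs
        and recursive time-step bisection on failure.

        Without the predictor, the jump of the prescribed contact
        displacement against unmoved interior nodes can invert the small
        punch-edge elements before Newton even starts.
        """
        dt = t - t_prev
        J_old = asm.jacobian_field(x)
        starts = []
        if x_before is not None and dt_before and dt_before > 0:
            fac = min(dt / dt_before, 2.0)
            starts.append(x + (x - x_before) * fac)
        starts.append(x.copy())
        err = None
        for x0 in starts:
            x_try = x0.copy()
            x_try[bc.contact_zdofs] = -float(w_fn(t))
            try:
                return _newton(
                    asm, x_try, J_old, dt, params, constants, bc, settings,
                    transient=True, t=t,
                )
            except (ConvergenceError, DegenerateDeformationError) as e:
                err = e
        if depth >= 4:
            raise err
        tm = 0.5 * (t_prev + t)
        x_mid, _, _ = advance(x, t_prev, tm, x_before, dt_before, depth + 1)
        return advance(x_mid, tm, t, x, tm - t_prev, depth + 1)

    def force_scale():
        return float(np.max(np.abs(f_hist)))

    t_prev = 0.0
    x_before, dt_before = None, None
    for t in times:
        x_new, Rg, _ = advance(x, t_prev, t, x_before, dt_before)
        x_before, dt_before = x, t - t_prev
        x = x_new
        t_hist.append(t)
        w_hist.append(float(w_fn(t)))
        f_hist.append(_reaction(Rg, bc))
        t_prev = t

    return SimulationResult(
        time=np.array(t_hist),
        displacement=np.array(w_hist),
        force=np.array(f_hist),
        segments=annotations,
        start_depth=start_depth,
    )


def simulate_paper_protocol(
    mesh: Mesh,
    params: FRPEParameters,
    constants: ConstitutiveConstants,
    settings: SolverSettings = None,
    contact: str = "smooth",
    cycles: int = 5,
    include_dynamic: bool = True,
    n_steps: int = 4,
) -> SimulationResult:
    """Simulate the full reference protocol: 12.5 kPa pre-stress seek, then
    4 x 5% stress-relaxation steps (900 s holds), then the 8-frequency sweep.

    The pre-stress seek is realized as a drained-equilibrium bisection to the
    target mean contact stress, which is the state the experiment reaches
    after its pre-stress hold; the transient record then starts from it.
    """
    settings = settings or SolverSettings()
    asm = _Assembler(mesh)
    h = mesh.geometry.thickness
    depth, _ = find_prestress_depth(asm, params, constants, contact=contact, settings=settings)
    start_strain = depth / h
    if include_dynamic:
        proto = paper_protocol(start_strain, n_steps=n_steps, cycles=cycles, thickness=h)
    else:
        from .protocol import relaxation_protocol

        proto = relaxation_protocol(start_strain, n_steps=n_steps, thickness=h)
    return simulate(mesh, params, constants, proto, settings, contact=contact)
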