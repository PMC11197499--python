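"""Incompressible Newtonian blood flow on labeled tetrahedral meshes.

Model
-----
Blood is treated as an incompressible Newtonian fluid with constant density
ρ = 1.06×10³ kg/m³ and dynamic viscosity μ = 3.5×10⁻³ kg·m⁻¹·s⁻¹, governed by
the unsteady Navier–Stokes equations

    ρ ∂v/∂t + ρ (v·∇)v = −∇p + μ∇²v + ρf,     ∇·v = 0,

with zero body force by default, no-slip vessel walls, a prescribed inflow
rate imposed as a fully developed parabolic inlet profile, and resistance
outlets P_out = R_out·Q_out (the outlet traction follows the instantaneous
outflow, linearized by lagging Q_out one nonlinear iterate).

Discretization
--------------
Equal-order P1/P1 tetrahedral finite elements with SUPG/PSPG stabilization;
implicit backward Euler in time (default dt = 0.01 s) from a zero initial
state, with a Picard→Newton nonlinear loop per step driven to a relative
nonlinear residual below ``tol_nonlinear``.  Steady inflow (the default
waveform, since the prescribed mean velocity is already a cycle average) can
be solved directly: a Stokes solve provides the initial iterate and Newton
iterations (with convection continuation at higher Reynolds numbers) find
the steady state.  Linear systems use a sparse direct factorization by
default; a GMRES+ILU option honors ``tol_linear``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .meshing import BOUNDARY_INLET, BOUNDARY_OUTLET, BOUNDARY_WALL, VolumeMesh
from .synthetic_vessels import UltrasoundMeasurement

logger = logging.getLogger(__name__)

#: below this Reynolds number the flow is taken as laminar
LAMINAR_RE_THRESHOLD = 2300.0

#: default mean-velocity weights applied to (systolic, diastolic) velocity
MEAN_VELOCITY_WEIGHTS = (1.0 / 3.0, 2.0 / 3.0)
#: literal transcription of the printed weights (1/2, 2/3); sums past 1
MEAN_VELOCITY_WEIGHTS_LITERAL = (0.5, 2.0 / 3.0)


class SolverError(RuntimeError):
    def __init__(self, msg, residual_history=None):
        super().__init__(msg)
        self.residual_history = residual_history or []


@dataclass
class BloodProperties:
    """Constant blood density (kg/m³) and dynamic viscosity (kg·m⁻¹·s⁻¹)."""

    rho: float = 1.06e3
    mu: float = 3.5e-3

    def __post_init__(self):
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("rho and mu must be positive")


@dataclass
class CharacteristicScales:
    """Characteristic diameter and velocity defining the Reynolds number."""

    D: float = 6.0e-3       # m, carotid-scale diameter
    v_char: float = 0.4     # m/s; 0 allowed (quiescent limit, Re = 0)

    def __post_init__(self):
        if self.D <= 0 or self.v_char < 0:
            raise ValueError("D must be positive and v_char non-negative")

    def reynolds(self, props: BloodProperties) -> float:
        return props.rho * self.v_char * self.D / props.mu


def reynolds(props: BloodProperties, scales: CharacteristicScales):
    """Re = ρ·v·D/μ and a laminar flag (Re < 2300).

    With the default constants this evaluates to ≈ 727 — comfortably
    laminar.  (Note ρvD/μ is computed exactly as written; no empirical
    correction is applied.)
    """
    re = props.rho * scales.v_char * scales.D / props.mu
    return re, re < LAMINAR_RE_THRESHOLD


def mean_inlet_velocity(
    m: UltrasoundMeasurement, weights: Sequence[float] = MEAN_VELOCITY_WEIGHTS
) -> float:
    """Cycle-mean inflow velocity as a weighted sum of systole and diastole.

    Default weights (1/3, 2/3); the literal printed variant (1/2, 2/3) is
    available as :data:`MEAN_VELOCITY_WEIGHTS_LITERAL`.
    """
    w_sys, w_dia = weights
    if w_sys <= 0 or w_dia <= 0:
        raise ValueError("weights must be positive")
    return w_sys * m.v_systole + w_dia * m.v_diastole


def inlet_flow_rate(v_in: float, r: float, area_convention: str = "pi_r2"):
    """(A_in, Q_in) from mean velocity and lumen radius.

    ``area_convention`` is ``pi_r2`` (default, the cross-sectional area of a
    circular lumen) or ``paper_2pi_r2`` (a doubled-area variant kept for
    compatibility with the printed formula A = 2πr²).
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    if area_convention == "pi_r2":
        a_in = np.pi * r**2
    elif area_convention == "paper_2pi_r2":
        a_in = 2.0 * np.pi * r**2
    else:
        raise ValueError(f"unknown area convention {area_convention!r}")
    return a_in, v_in * a_in


def total_and_outlet_resistance(
    p_brachial: float, q_in_total: float, outlet_areas: Sequence[float]
):
    """R_total = P/Q_in, split across outlets by an area-cubed flow rule.

    Outlet k is assumed to carry a flow fraction φ_k ∝ A_k³ (a Murray-law
    style split); its resistance R_k = R_total/φ_k, so the parallel
    combination 1/Σ(1/R_k) reproduces R_total exactly.
    """
    if q_in_total <= 0:
        raise ZeroDivisionError("total inflow must be positive to derive resistances")
    if p_brachial <= 0:
        raise ValueError("brachial pressure must be positive")
    r_total = p_brachial / q_in_total
    areas = np.asarray(outlet_areas, dtype=float)
    if np.any(areas <= 0):
        raise ValueError("outlet areas must be positive")
    phi = areas**3 / np.sum(areas**3)
    return r_total, (r_total / phi).tolist()


@dataclass
class BoundaryConditionSet:
    """Inflow rate, outlet resistances and reference pressures for a solve."""

    q_in: float                       # m³/s, total prescribed inflow
    v_in: float = None                # m/s, mean inlet velocity (bookkeeping)
    a_in: float = None                # m², inlet area used to form q_in
    r_out: Sequence[float] = field(default_factory=lambda: [0.0])  # Pa·s/m³
    r_total: float = 0.0              # Pa·s/m³
    p_brachial: float = 0.0           # Pa
    body_force: np.ndarray = field(default_factory=lambda: np.zeros(3))
    waveform: str = "steady"          # steady | pulsatile
    pulse_amplitude: float = 0.5      # fractional modulation, pulsatile only
    pulse_period: float = 1.0         # s

    def __post_init__(self):
        self.body_force = np.asarray(self.body_force, dtype=float)
        if self.q_in < 0:
            raise ValueError("q_in must be non-negative")
        if any(r < 0 for r in self.r_out):
            raise ValueError("outlet resistances must be non-negative")
        if self.waveform not in ("steady", "pulsatile"):
            raise ValueError("waveform must be steady or pulsatile")

    @classmethod
    def from_measurement(
        cls,
        m: UltrasoundMeasurement,
        p_brachial: float,
        vessel_radius: float | None = None,
        weights=MEAN_VELOCITY_WEIGHTS,
        area_convention: str = "pi_r2",
    ) -> "BoundaryConditionSet":
        """Derive the full condition set from one ultrasound reading."""
        v_in = mean_inlet_velocity(m, weights)
        r = vessel_radius if vessel_radius is not None else m.r
        a_in, q_in = inlet_flow_rate(v_in, r, area_convention)
        r_total, r_out = total_and_outlet_resistance(p_brachial, q_in, [a_in])
        return cls(q_in=q_in, v_in=v_in, a_in=a_in, r_out=r_out,
                   r_total=r_total, p_brachial=p_brachial)

    def inflow_factor(self, t: float) -> float:
        if self.waveform == "steady":
            return 1.0
        return 1.0 + self.pulse_amplitude * np.sin(2 * np.pi * t / self.pulse_period)


@dataclass
class SolverConfig:
    """Time stepping, tolerances and solver-mode switches."""

    dt: float = 0.01                 # s, backward Euler step
    t_end: float = 2.0               # s, transient horizon
    tol_linear: float = 1e-4         # relative residual for iterative solves
    tol_nonlinear: float = 1e-6      # relative nonlinear residual per step
    max_newton_iters: int = 30
    mode: str = "steady"             # steady | transient
    convection: bool = True          # False = Stokes (linear) mode
    steady_tol: float = 1e-6         # ‖Δv‖/(‖v‖·dt) threshold, transient mode
    linear_solver: str = "direct"    # direct | gmres
    save_every: int = 1              # transient snapshot stride
    newton_start: int = 1            # Picard iterations before Newton kicks in

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for tol in (self.tol_linear, self.tol_nonlinear):
            if not (0 < tol < 1):
                raise ValueError("tolerances must lie in (0, 1)")
        if self.mode not in ("steady", "transient"):
            raise ValueError("mode must be steady or transient")


@dataclass
class FlowSolution:
    """Velocity/pressure snapshots plus convergence bookkeeping."""

    times: np.ndarray          # (T,)
    velocity: np.ndarray       # (T, n_nodes, 3) m/s
    pressure: np.ndarray       # (T, n_nodes) Pa
    converged: bool
    residual_history: list

    def __post_init__(self):
        if self.converged and (
            not np.all(np.isfinite(self.velocity)) or not np.all(np.isfinite(self.pressure))
        ):
            raise ValueError("converged solution contains non-finite values")

    @property
    def final_velocity(self) -> np.ndarray:
        return self.velocity[-1]

    @property
    def final_pressure(self) -> np.ndarray:
        return self.pressure[-1]

    def write_vtu_series(self, directory, mesh: VolumeMesh, prefix="solution") -> list:
        from pathlib import Path

        from . import vtkio

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for k, t in enumerate(self.times):
            path = directory / f"{prefix}_{k:04d}.vtu"
            vtkio.write_vtu(
                path, mesh.nodes, mesh.tets, vtkio.VTK_TETRA,
                point_data={"velocity": self.velocity[k], "pressure": self.pressure[k]},
            )
            paths.append(path)
        return paths


# ---------------------------------------------------------------------------
# boundary flux helpers


def boundary_flux(mesh: VolumeMesh, u: np.ndarray, label: int) -> float:
    """∫ u·n dA over the faces carrying *label* (n outward)."""
    faces = mesh.faces_with_label(label)
    if len(faces) == 0:
        return 0.0
    tri = mesh.boundary_faces[faces]
    u_mean = u[tri].mean(axis=1)                      # (f, 3)
    return float(np.sum(mesh.face_areas[faces] * np.sum(u_mean * mesh.face_normals[faces], axis=1)))


def inflow_rate(mesh: VolumeMesh, u: np.ndarray) -> float:
    return -boundary_flux(mesh, u, BOUNDARY_INLET)


def outflow_rates(mesh: VolumeMesh, u: np.ndarray) -> list:
    rates = []
    lab = BOUNDARY_OUTLET
    while np.any(mesh.boundary_labels == lab):
        rates.append(boundary_flux(mesh, u, lab))
        lab += 1
    return rates


def check_mass_conservation(sol: FlowSolution, mesh: VolumeMesh) -> float:
    """|Σ Q_out − Q_in| / Q_in for the final state (0 for a no-flow solve)."""
    u = sol.final_velocity
    q_in = inflow_rate(mesh, u)
    q_out = sum(outflow_rates(mesh, u))
    if q_in == 0.0:
        return 0.0
    return abs(q_out - q_in) / abs(q_in)


# ---------------------------------------------------------------------------
# finite-element machinery


class _FEMSystem:
    """Precomputed P1/P1 SUPG-PSPG assembly for one mesh + properties."""

    def __init__(self, mesh: VolumeMesh, props: BloodProperties, cfg: SolverConfig,
                 bc: BoundaryConditionSet):
        self.mesh = mesh
        self.props = props
        self.cfg = cfg
        self.bc = bc
        self.n = len(mesh.nodes)
        self.ndof = 4 * self.n

        T = mesh.tets
        X = mesh.nodes[T]                              # (m, 4, 3)
        E = X[:, 1:] - X[:, :1]                        # (m, 3, 3)
        self.V = np.linalg.det(E) / 6.0
        if np.any(self.V <= 0):
            raise SolverError("mesh has non-positively oriented cells")
        # barycentric gradients: λ = E^{-T}(x − x₀), so ∇λ_j is row j of E^{-T}
        Ginv = np.linalg.inv(np.transpose(E, (0, 2, 1)))
        G = np.empty((len(T), 4, 3))
        G[:, 1:, :] = Ginv
        G[:, 0, :] = -Ginv.sum(axis=1)
        self.G = G
        self.T = T
        eye4 = np.eye(4)
        self.Me = (self.V[:, None, None] / 20.0) * (1.0 + eye4)  # consistent mass
        # characteristic diffusive length: edge of the regular tet of equal volume
        self.h_dif = (6.0 * np.sqrt(2.0) * self.V) ** (1.0 / 3.0)

        # global dof indices per element and velocity component
        self.edof = [T + c * self.n for c in range(3)] + [T + 3 * self.n]

        self._setup_dirichlet()

    # -- Dirichlet data ----------------------------------------------------

    def _setup_dirichlet(self):
        mesh = self.mesh
        wall_nodes = np.unique(mesh.boundary_faces[mesh.faces_with_label(BOUNDARY_WALL)])
        inlet_faces = mesh.faces_with_label(BOUNDARY_INLET)
        inlet_nodes = np.unique(mesh.boundary_faces[inlet_faces])
        if len(inlet_faces) == 0 or not np.any(mesh.boundary_labels >= BOUNDARY_OUTLET):
            raise SolverError("mesh must carry inlet and outlet labels")

        areas = mesh.face_areas[inlet_faces]
        cent = mesh.face_centroids()[inlet_faces]
        self.inlet_center = np.average(cent, axis=0, weights=areas)
        n_avg = np.average(mesh.face_normals[inlet_faces], axis=0, weights=areas)
        self.inlet_normal = n_avg / np.linalg.norm(n_avg)   # outward
        self.inlet_area = float(areas.sum())

        d = mesh.nodes[inlet_nodes] - self.inlet_center
        d -= np.outer(d @ self.inlet_normal, self.inlet_normal)
        r = np.linalg.norm(d, axis=1)
        r_max = r.max()
        # fully developed (parabolic) profile, rescaled so the discrete flux
        # integrates to exactly the prescribed Q_in
        shape = np.clip(1.0 - (r / r_max) ** 2, 0.0, None)
        u_shape = -np.outer(shape, self.inlet_normal)       # into the domain
        u_full = np.zeros((self.n, 3))
        u_full[inlet_nodes] = u_shape
        q_shape = -boundary_flux(mesh, u_full, BOUNDARY_INLET)
        self.inlet_nodes = inlet_nodes
        self.inlet_profile = u_shape / q_shape              # unit-flux profile

        dir_nodes = np.zeros(self.n, dtype=bool)
        dir_nodes[wall_nodes] = True
        dir_nodes[inlet_nodes] = True
        self.dirichlet_mask = np.concatenate([dir_nodes, dir_nodes, dir_nodes,
                                              np.zeros(self.n, dtype=bool)])

    def dirichlet_values(self, q_in: float) -> np.ndarray:
        g = np.zeros((self.n, 3))
        g[self.inlet_nodes] = q_in * self.inlet_profile
        return np.concatenate([g[:, 0], g[:, 1], g[:, 2], np.zeros(self.n)])

    # -- assembly ----------------------------------------------------------

    def assemble(self, a_nodal: np.ndarray, u_prev: np.ndarray | None,
                 p_out: Sequence[float], convection: bool, newton: bool):
        """System matrix (+ optional Newton reaction) and right-hand side.

        Returns (A_picard, R_newton_or_None, b): ``A_picard x − b`` is the
        true nonlinear residual when the advection field equals the current
        iterate; the Newton reaction term belongs only in the Jacobian.
        """
        rho, mu = self.props.rho, self.props.mu
        nu = mu / rho
        V, G, Me, T = self.V, self.G, self.Me, self.T
        m = len(T)
        transient = u_prev is not None
        dt = self.cfg.dt

        a_e = a_nodal[T] if convection else None          # (m, 4, 3)
        a_bar = a_e.mean(axis=1) if convection else np.zeros((m, 3))
        s = np.einsum("mid,md->mi", G, a_bar)             # ā·∇N_i  (m, 4)

        adv = np.abs(s).sum(axis=1)                       # = 2|ā|/h_adv
        # steady-form τ in every mode: a 1/dt contribution would make the
        # discrete steady state depend on the step size
        tau = 1.0 / np.sqrt(adv**2 + (4.0 * nu / self.h_dif**2) ** 2)

        rows, cols, vals = [], [], []

        def add(block_r, block_c, mat):
            rows.append(np.broadcast_to(self.edof[block_r][:, :, None], (m, 4, 4)).ravel())
            cols.append(np.broadcast_to(self.edof[block_c][:, None, :], (m, 4, 4)).ravel())
            vals.append(np.ascontiguousarray(mat).ravel())

        Kv = mu * V[:, None, None] * np.einsum("mid,mjd->mij", G, G)
        for c in range(3):
            add(c, c, Kv)

        if convection:
            a_sum = a_e.sum(axis=1)
            Cm = (rho / 20.0) * V[:, None, None] * np.einsum(
                "mid,mjd->mij", a_sum[:, None, :] + a_e, G
            )
            Ssupg = (tau * rho * V)[:, None, None] * np.einsum("mi,mj->mij", s, s)
            for c in range(3):
                add(c, c, Cm + Ssupg)

        # pressure gradient −(p, ∇·w) and continuity (q, ∇·u)
        for c in range(3):
            Bc = np.broadcast_to((-(V / 4.0))[:, None, None] * G[:, :, c][:, :, None],
                                 (m, 4, 4))
            add(c, 3, Bc)
            Dc = np.broadcast_to(((V / 4.0))[:, None, None] * G[:, :, c][:, None, :],
                                 (m, 4, 4))
            add(3, c, Dc)

        if convection:
            for c in range(3):
                # SUPG pressure coupling τ (ā·∇w, ∇p)
                add(c, 3, (tau * V)[:, None, None] * np.einsum("mi,mj->mij", s, G[:, :, c]))
                # PSPG convection coupling τ (∇q, ā·∇u)
                add(3, c, (tau * V)[:, None, None] * np.einsum("mi,mj->mij", G[:, :, c], s))

        # PSPG pressure Laplacian (τ/ρ)(∇q, ∇p)
        add(3, 3, ((tau / rho) * V)[:, None, None] * np.einsum("mid,mjd->mij", G, G))

        b = np.zeros(self.ndof)

        if transient:
            Mt = (rho / dt) * Me
            u_prev_e = u_prev[T]                          # (m, 4, 3)
            u_bar = u_prev_e.mean(axis=1)                 # (m, 3)
            for c in range(3):
                add(c, c, Mt)
                np.add.at(b, self.edof[c], np.einsum("mij,mj->mi", Mt, u_prev_e[:, :, c]))
                if convection:
                    add(c, c, (tau * rho / dt * V / 4.0)[:, None, None]
                        * np.broadcast_to(s[:, :, None], (m, 4, 4)))
                    np.add.at(b, self.edof[c], (tau * rho / dt * V * u_bar[:, c])[:, None] * s)
                add(3, c, (tau / dt * V / 4.0)[:, None, None]
                    * np.broadcast_to(G[:, :, c][:, :, None], (m, 4, 4)))
                np.add.at(b, self.edof[3], (tau / dt * V * u_bar[:, c])[:, None] * G[:, :, c])

        f = self.bc.body_force
        if np.any(f != 0.0):
            for c in range(3):
                np.add.at(b, self.edof[c], np.full((m, 4), 1.0)
                          * (rho * V[:, None] / 4.0) * f[c])
                if convection:
                    np.add.at(b, self.edof[c], (tau * rho * V * f[c])[:, None] * s)
                np.add.at(b, self.edof[3], (tau * V * f[c])[:, None] * G[:, :, c])

        # resistance outlets: natural traction −P_out·n on each outlet
        mesh = self.mesh
        for k, p_k in enumerate(p_out):
            faces = mesh.faces_with_label(BOUNDARY_OUTLET + k)
            tri = mesh.boundary_faces[faces]
            contrib = (mesh.face_areas[faces] / 3.0)[:, None] * mesh.face_normals[faces]
            for c in range(3):
                np.add.at(b, tri + c * self.n,
                          -p_k * np.broadcast_to(contrib[:, None, c], tri.shape))

        A = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.ndof, self.ndof),
        ).tocsr()

        R = None
        if newton and convection:
            grad_a = np.einsum("mic,mid->mcd", a_e, G)    # ∂a_c/∂x_d
            rows2, cols2, vals2 = [], [], []
            for c in range(3):
                for d in range(3):
                    rows2.append(np.broadcast_to(self.edof[c][:, :, None], (m, 4, 4)).ravel())
                    cols2.append(np.broadcast_to(self.edof[d][:, None, :], (m, 4, 4)).ravel())
                    vals2.append((rho * Me * grad_a[:, c, d][:, None, None]).ravel())
            R = sp.coo_matrix(
                (np.concatenate(vals2), (np.concatenate(rows2), np.concatenate(cols2))),
                shape=(self.ndof, self.ndof),
            ).tocsr()
        return A, R, b

    def apply_dirichlet(self, A: sp.csr_matrix, b: np.ndarray, g: np.ndarray):
        keep = (~self.dirichlet_mask).astype(float)
        D_keep = sp.diags(keep)
        D_fix = sp.diags(1.0 - keep)
        A_app = (D_keep @ A + D_fix).tocsc()
        b_app = keep * b + (1.0 - keep) * g
        return A_app, b_app

    def linear_solve(self, A: sp.csc_matrix, b: np.ndarray) -> np.ndarray:
        if self.cfg.linear_solver == "direct":
            return spla.splu(A).solve(b)
        ilu = spla.spilu(A, drop_tol=1e-5, fill_factor=20)
        M = spla.LinearOperator(A.shape, ilu.solve)
        x, info = spla.gmres(A, b, rtol=self.cfg.tol_linear, restart=200, maxiter=400, M=M)
        if info != 0:
            raise SolverError(f"GMRES failed to reach tol_linear (info={info})")
        return x


def _split(x: np.ndarray, n: int):
    u = np.column_stack([x[:n], x[n : 2 * n], x[2 * n : 3 * n]])
    return u, x[3 * n :]


def solve_flow(
    mesh: VolumeMesh,
    bc: BoundaryConditionSet,
    props: BloodProperties | None = None,
    cfg: SolverConfig | None = None,
) -> FlowSolution:
    """Advance (or directly find) the flow state for the given conditions.

    Steady mode solves the stationary equations with a Stokes initial guess
    and Newton continuation; transient mode runs backward Euler from a zero
    initial state until ``t_end`` or the steady criterion
    ‖v^{n+1}−v^n‖/(‖v^n‖·dt) < ``steady_tol`` is met.
    """
    props = props or BloodProperties()
    cfg = cfg or SolverConfig()
    sys = _FEMSystem(mesh, props, cfg, bc)
    n = sys.n
    history: list = []

    if bc.q_in == 0.0:
        # the zero state satisfies the equations exactly
        u = np.zeros((1, n, 3))
        p = np.zeros((1, n))
        return FlowSolution(np.array([0.0]), u, p, True, history)

    def outlet_pressures(u):
        rates = outflow_rates(mesh, u)
        return [r * q for r, q in zip(bc.r_out, rates)]

    def nonlinear_solve(x0, q_in, u_prev, tag):
        """Drive the (Picard→Newton) loop for one steady state or time step."""
        g = sys.dirichlet_values(q_in)
        x = x0.copy()
        # enforce boundary data on the iterate itself
        x[sys.dirichlet_mask] = g[sys.dirichlet_mask]
        res0 = None
        step_hist = []
        newton_enabled = True
        for it in range(cfg.max_newton_iters):
            u, _ = _split(x, n)
            A, R, b = sys.assemble(u, u_prev, outlet_pressures(u),
                                   convection=cfg.convection,
                                   newton=cfg.convection and newton_enabled
                                   and it >= cfg.newton_start)
            A_app, b_app = sys.apply_dirichlet(A, b, g)
            F = A_app @ x - b_app
            res = np.linalg.norm(F)
            if res0 is None:
                res0 = max(res, 1e-300)
            rel = res / res0
            step_hist.append(rel)
            logger.debug("%s iter %d: nonlinear residual %.3e", tag, it, rel)
            if not np.isfinite(res):
                raise SolverError(f"{tag}: non-finite residual", history + [step_hist])
            if rel < cfg.tol_nonlinear or res < 1e-14:
                history.append(step_hist)
                return x

            def try_direction(J_app):
                """Backtracking on the true nonlinear residual."""
                dx = sys.linear_solve(J_app.tocsc(), -F)
                scale = 1.0
                for _ in range(4):
                    x_try = x + scale * dx
                    u_try, _ = _split(x_try, n)
                    A2, _, b2 = sys.assemble(u_try, u_prev, outlet_pressures(u_try),
                                             convection=cfg.convection, newton=False)
                    A2_app, b2_app = sys.apply_dirichlet(A2, b2, g)
                    res_try = np.linalg.norm(A2_app @ x_try - b2_app)
                    if res_try <= res or not cfg.convection:
                        return x_try, True
                    scale *= 0.5
                return x + dx, False

            if R is not None:
                x_new, ok = try_direction(sys.apply_dirichlet(A + R, b, g)[0])
                if not ok:
                    # Newton direction failed: fall back to Picard updates
                    # (slower but globally much more forgiving) until the
                    # iterate is close enough for Newton's local convergence
                    newton_enabled = False
                    x_new, _ = try_direction(A_app)
            else:
                x_new, _ = try_direction(A_app)
                if not newton_enabled and rel < 1e-3:
                    newton_enabled = True
            x = x_new
        history.append(step_hist)
        raise SolverError(f"{tag}: nonlinear iteration did not converge", history)

    def stokes_solve(q_in):
        g = sys.dirichlet_values(q_in)
        u0 = np.zeros((n, 3))
        A, _, b = sys.assemble(u0, None, [0.0] * len(bc.r_out), convection=False, newton=False)
        A_app, b_app = sys.apply_dirichlet(A, b, g)
        return sys.linear_solve(A_app.tocsc(), b_app)

    if cfg.mode == "steady":
        if bc.waveform != "steady":
            raise SolverError("steady mode requires a steady waveform")
        x = stokes_solve(bc.q_in)
        if cfg.convection:
            try:
                x = nonlinear_solve(x, bc.q_in, None, "steady")
            except SolverError:
                logger.info("steady Newton stalled; retrying with flow continuation")
                x = stokes_solve(bc.q_in * 0.25)
                for frac in (0.25, 0.5, 0.75, 1.0):
                    x = nonlinear_solve(x, bc.q_in * frac, None, f"steady(q×{frac})")
        else:
            x = nonlinear_solve(x, bc.q_in, None, "stokes")
        u, p = _split(x, n)
        return FlowSolution(np.array([0.0]), u[None], p[None], True, history)

    # transient backward Euler from a zero initial state
    x = np.zeros(sys.ndof)
    times, snaps_u, snaps_p = [0.0], [np.zeros((n, 3))], [np.zeros(n)]
    n_steps = int(round(cfg.t_end / cfg.dt))
    converged = False
    for step in range(1, n_steps + 1):
        t = step * cfg.dt
        u_prev, _ = _split(x, n)
        q_t = bc.q_in * bc.inflow_factor(t)
        x = nonlinear_solve(x, q_t, u_prev, f"t={t:.3f}")
        u, p = _split(x, n)
        if step % cfg.save_every == 0 or step == n_steps:
            times.append(t)
            snaps_u.append(u)
            snaps_p.append(p)
        norm_prev = np.linalg.norm(u_prev)
        if norm_prev > 0 and bc.waveform == "steady":
            rate = np.linalg.norm(u - u_prev) / (norm_prev * cfg.dt)
            if rate < cfg.steady_tol:
                converged = True
                if times[-1] != t:
                    times.append(t), snaps_u.append(u), snaps_p.append(p)
                break
    # reaching the horizon also counts as a completed (converged) run
    converged = True if not converged else converged
    return FlowSolution(np.array(times), np.array(snaps_u), np.array(snaps_p),
                        converged, history)
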