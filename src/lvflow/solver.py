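"""Low-dissipation P1 finite-element incompressible Navier-Stokes solver.

Discretisation summary:

* equal-order linear (P1) interpolation for velocity and kinematic pressure
  on triangles (2D) or tetrahedra (3D), with a lumped velocity mass matrix;
* the convective term in either the classical convective form
  ``u . grad u`` (CONV) or the energy/momentum/angular-momentum conserving
  form ``2 S(u) u + (div u) u`` (EMAC), integrated with a quadrature rule
  exact for the degree-2 integrands, which is what makes the discrete EMAC
  energy identity hold exactly on periodic domains;
* viscous term in symmetric-gradient form ``2 nu (S(u), S(v))``;
* a three-stage SSP Runge-Kutta time integrator with a non-incremental
  pressure projection applied after every stage: the pressure Poisson
  problem is the exact discrete Schur complement ``B M^-1 B^T`` of the
  weak divergence operator, factorised once per mesh, so the discrete
  divergence after projection is zero to solver precision;
* optional Darcy drag ``-(mu/k) u`` on porous-tagged cells, integrated
  semi-implicitly (a diagonal solve per stage), which keeps strong drag
  unconditionally stable;
* an eigenvalue-surrogate time-step estimator
  ``dt = cfl / max_cells(|u|/h + C_d nu / h^2)`` with ``h`` the smallest
  cell altitude.

The solver is deterministic: no randomness enters anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from . import _geom
from .anatomy import FluidProperties
from .boundary import OutletModel, outlet_pressure
from .meshes import INLET, OUTLET, POROUS, VolumeMesh, WALL

CONV, EMAC = "CONV", "EMAC"


class SolverError(RuntimeError):
    """Raised on solver failures (blow-up, non-convergence, bad config)."""


@dataclass
class SolverConfig:
    nonlinear_form: str = EMAC
    cfl_safety: float = 0.5
    rk_stages: int = 3
    diffusive_constant: float = 4.0      # C_d in the time-step estimator
    projection_tolerance: float = 1e-6   # post-projection divergence bound
    max_time: float = 0.35
    output_interval: float = 0.005
    fixed_dt: float | None = None
    backflow_beta: float = 1.0

    def validate(self) -> None:
        if self.nonlinear_form not in (CONV, EMAC):
            raise SolverError(
                f"unknown nonlinear_form {self.nonlinear_form!r}; "
                f"expected 'CONV' or 'EMAC'")
        if not (0 < self.cfl_safety <= 1):
            raise SolverError("cfl_safety must be in (0, 1]")
        if self.rk_stages < 2:
            raise SolverError("rk_stages must be >= 2")


@dataclass
class FlowState:
    """Velocity and kinematic pressure at one instant, on solver DOFs."""

    time: float
    velocity: np.ndarray          # (n_dofs, dim) m/s
    pressure: np.ndarray          # (n_dofs,) kinematic, m^2/s^2

    def copy(self) -> "FlowState":
        return FlowState(self.time, self.velocity.copy(), self.pressure.copy())


@dataclass
class DirichletSet:
    """Velocity constraints on a set of DOFs.

    ``components`` selects which velocity components are constrained;
    ``value`` is a callable ``t -> (len(dofs), dim) array`` (or a constant
    array / scalar) giving the prescribed values.
    """

    dofs: np.ndarray
    components: np.ndarray        # (dim,) bool
    value: object = 0.0

    def values_at(self, t: float, dim: int) -> np.ndarray:
        v = self.value(t) if callable(self.value) else self.value
        return np.broadcast_to(np.asarray(v, dtype=float),
                               (len(self.dofs), dim))


@dataclass
class BoundaryConditions:
    dirichlet: list = field(default_factory=list)
    outlet_model: OutletModel | None = None
    body_force: np.ndarray | None = None   # (dim,) constant acceleration


def build_cavity_bcs(mesh: VolumeMesh, inflow, outlet_model=None,
                     body_force=None, plug_exponent: float = 8.0
                     ) -> BoundaryConditions:
    """No-slip walls, plug inflow profile along the inlet axis, free outlet.

    The inflow is a steep plug: flat over the cap core and vanishing at the
    tube wall as ``1 - (r/R)^plug_exponent``, the wall-compatible
    realisation of a flat profile at finite resolution.
    """
    dim = mesh.dim
    areas, normals = mesh.boundary_face_areas_normals()
    inlet_faces = mesh.boundary_tags == INLET
    if not inlet_faces.any():
        raise SolverError("mesh has no inlet-tagged boundary faces")
    n_in = (areas[inlet_faces, None] * normals[inlet_faces]).sum(axis=0)
    n_in /= np.linalg.norm(n_in)
    direction = -n_in                                  # into the domain

    def face_dofs(mask):
        return np.unique(mesh.node_dof[mesh.boundary_faces[mask]])

    # the cap ring shared by inlet and wall faces stays no-slip
    wall_dofs = face_dofs(mesh.boundary_tags == WALL)
    inlet_dofs = np.setdiff1d(face_dofs(inlet_faces), wall_dofs)

    # per-node plug shape from the lateral distance to the inlet axis
    shape = np.ones(len(inlet_dofs))
    planes = (mesh.metadata or {}).get("valve_planes") or {}
    if "inlet" in planes:
        side = planes["inlet"]
        c = np.asarray(side["centre"])[:dim]
        ax = np.asarray(side["axis"])[:dim]
        node_of = np.zeros(mesh.n_dofs, dtype=np.int64)
        node_of[mesh.node_dof] = np.arange(len(mesh.vertices))
        p = mesh.vertices[node_of[inlet_dofs]] - c
        lat = np.linalg.norm(p - (p @ ax)[:, None] * ax, axis=1)
        rr = np.clip(lat / side["radius"], 0.0, 1.0)
        shape = 1.0 - rr ** plug_exponent

    def inflow_value(t):
        return float(inflow(t)) * shape[:, None] * direction[None, :]

    bcs = BoundaryConditions(
        dirichlet=[
            DirichletSet(wall_dofs, np.ones(dim, dtype=bool), 0.0),
            DirichletSet(inlet_dofs, np.ones(dim, dtype=bool), inflow_value),
        ],
        outlet_model=outlet_model or OutletModel(),
        body_force=body_force)
    return bcs


@dataclass
class RunRecord:
    """Transient run output: snapshots, probe series, diagnostics."""

    mesh: VolumeMesh
    props: FluidProperties
    config: SolverConfig
    frame_times: list = field(default_factory=list)
    frames: list = field(default_factory=list)          # FlowState snapshots
    probe_nodes: dict = field(default_factory=dict)     # name -> dof indices
    probe_pressures: dict = field(default_factory=dict)  # name -> [Pa arrays]
    step_times: list = field(default_factory=list)
    outlet_flow: list = field(default_factory=list)     # m^3/s per step
    inlet_flow: list = field(default_factory=list)
    pressure_offset: list = field(default_factory=list)  # Pa per frame
    max_divergence: float = 0.0

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)


def tube_probe_nodes(mesh: VolumeMesh, side_name: str,
                     probe_length: float = 0.015) -> np.ndarray:
    """DOFs of cells whose centroid lies within ``probe_length`` of the
    valve plane, measured along the tube axis on the tube side."""
    planes = (mesh.metadata or {}).get("valve_planes") or {}
    if side_name not in planes:
        raise SolverError(
            f"mesh metadata has no valve plane for {side_name!r}; "
            f"available: {sorted(planes)}")
    side = planes[side_name]
    c = np.asarray(side["centre"])
    ax = np.asarray(side["axis"])
    cent = mesh.cell_centroids()
    s = (cent - c) @ ax
    lateral = np.linalg.norm(cent - c - s[:, None] * ax, axis=1)
    cells = (s >= 0) & (s <= probe_length) & (lateral <= 1.5 * side["radius"])
    return np.unique(mesh.node_dof[mesh.cells[cells]])


class NavierStokesSolver:
    """Assembles operators once per mesh and advances the flow in time."""

    def __init__(self, mesh: VolumeMesh, props: FluidProperties,
                 config: SolverConfig, bcs: BoundaryConditions):
        config.validate()
        props.validate()
        self.mesh = mesh
        self.props = props
        self.config = config
        self.bcs = bcs
        self.dim = d = mesh.dim
        self.nd = mesh.n_dofs

        self.cdofs = mesh.node_dof[mesh.cells]                # (m, d+1)
        self.grads, self.vols = _geom.shape_gradients(mesh.vertices,
                                                      mesh.cells)
        if (self.vols <= 0).any():
            raise SolverError("mesh has non-positive cell volumes")
        self.h_cell = _geom.cell_min_heights(mesh.vertices, mesh.cells)

        # lumped mass
        self.mass = np.zeros(self.nd)
        np.add.at(self.mass, self.cdofs.ravel(),
                  np.repeat(self.vols / (d + 1), d + 1))

        self.bary, self.qw = _geom.quadrature_degree2(d)

        self._build_dirichlet()
        self._build_divergence()
        self._build_outlet()
        self._build_porous()

        self.nu = props.kinematic_viscosity
        bf = (np.asarray(bcs.body_force, dtype=float)
              if bcs.body_force is not None else None)
        if bf is None and np.any(np.asarray(props.body_force)[:d]):
            bf = np.asarray(props.body_force, dtype=float)[:d]
        self.body_force = bf

    # -- assembly ----------------------------------------------------------

    def _build_dirichlet(self):
        d = self.dim
        self.dir_mask = np.zeros((self.nd, d), dtype=bool)
        for ds in self.bcs.dirichlet:
            self.dir_mask[np.ix_(np.asarray(ds.dofs, dtype=np.int64),
                                 np.asarray(ds.components, dtype=bool))] = True

    def _build_divergence(self):
        d, m = self.dim, len(self.mesh.cells)
        npc = d + 1
        rows = np.repeat(self.cdofs, npc, axis=1).ravel()
        cols = np.tile(self.cdofs, (1, npc)).ravel()
        self.B = []
        self.B_hat_T = []
        for j in range(d):
            vals = (np.repeat(self.vols / npc, npc * npc).reshape(m, npc, npc)
                    * self.grads[:, None, :, j]).ravel()
            Bj = sp.csr_matrix((vals, (rows, cols)), shape=(self.nd, self.nd))
            self.B.append(Bj)
            free = sp.diags((~self.dir_mask[:, j]).astype(float))
            self.B_hat_T.append((Bj @ free).T.tocsr())
        minv = sp.diags(1.0 / self.mass)
        A = sum(self.B[j] @ minv @ self.B_hat_T[j] for j in range(d))
        A = A.tocsr()

        # The Schur operator is symmetric positive *semi*-definite: pressure
        # modes supported on fully Dirichlet-constrained patches (and the
        # global constant on enclosed/periodic domains) are null modes whose
        # right-hand sides vanish, and which do not move the velocity.  A
        # tiny diagonal shift makes the factorisation robust while leaving
        # the post-projection divergence orders of magnitude below tolerance.
        diag = A.diagonal()
        # pressure rows whose entire velocity stencil is Dirichlet-prescribed
        # have (exactly) zero rows: their divergence is boundary data, not a
        # controllable constraint
        self._controllable = diag > 1e-12 * diag.max()
        shift = 1e-8 * float(np.median(diag[self._controllable]))
        A = (A + shift * sp.identity(self.nd)).tocsc()
        self._schur = splu(A)

        # cancellation-free divergence scale for the relative norm
        self.B_abs = [abs(Bj) for Bj in self.B]

        # stiffness-matrix pressure Poisson operator for the *reported*
        # pressure: the Schur operator projects exactly but, as with any
        # unstabilised equal-order pair, admits element-scale spurious
        # pressure modes; the P1 stiffness form is the classical
        # fractional-step stabilisation and yields a smooth field
        gg = np.einsum("c,cid,ckd->cik", self.vols, self.grads, self.grads)
        rowsK = np.repeat(self.cdofs, d + 1, axis=1).ravel()
        colsK = np.tile(self.cdofs, (1, d + 1)).ravel()
        K = sp.csr_matrix((gg.ravel(), (rowsK, colsK)),
                          shape=(self.nd, self.nd))
        out_dofs = np.unique(self.mesh.node_dof[
            self.mesh.boundary_faces[self.mesh.boundary_tags == OUTLET]]) \
            if len(self.mesh.boundary_faces) else np.array([], dtype=np.int64)
        self._p_fixed = np.zeros(self.nd, dtype=bool)
        if len(out_dofs):
            self._p_fixed[out_dofs] = True
        else:
            self._p_fixed[0] = True
        keep = sp.diags((~self._p_fixed).astype(float))
        K = keep @ K @ keep + sp.diags(self._p_fixed.astype(float))
        self._pressure_poisson = splu(K.tocsc())
        self._p_enclosed = not len(out_dofs)

    def _build_outlet(self):
        mask = self.mesh.boundary_tags == OUTLET
        self.outlet_faces = self.mesh.boundary_faces[mask]
        if len(self.outlet_faces):
            areas, normals = self.mesh.boundary_face_areas_normals()
            self.outlet_areas = areas[mask]
            self.outlet_normals = normals[mask]
            self.outlet_fdofs = self.mesh.node_dof[self.outlet_faces]
        inlet = self.mesh.boundary_tags == INLET
        self.inlet_faces = self.mesh.boundary_faces[inlet]
        if len(self.inlet_faces):
            areas, normals = self.mesh.boundary_face_areas_normals()
            self.inlet_areas = areas[inlet]
            self.inlet_normals = normals[inlet]
            self.inlet_fdofs = self.mesh.node_dof[self.inlet_faces]

    def _build_porous(self):
        porous = self.mesh.cell_region == POROUS
        self.porous_volume = np.zeros(self.nd)
        if porous.any():
            d = self.dim
            np.add.at(self.porous_volume,
                      self.cdofs[porous].ravel(),
                      np.repeat(self.vols[porous] / (d + 1), d + 1))
        self.permeability = None  # set via set_permeability

    def set_permeability(self, k: float):
        """Intrinsic permeability (m^2) of the porous-tagged region."""
        if k is not None and k <= 0:
            raise SolverError(f"permeability must be > 0, got {k}")
        self.permeability = k

    # -- fields ------------------------------------------------------------

    def zero_state(self) -> FlowState:
        return FlowState(0.0, np.zeros((self.nd, self.dim)),
                         np.zeros(self.nd))

    def interpolate(self, fn) -> np.ndarray:
        """Nodal DOF values of ``fn(points) -> (n, dim)``."""
        vals = np.asarray(fn(self.mesh.vertices), dtype=float)
        out = np.zeros((self.nd, vals.shape[1]) if vals.ndim > 1 else self.nd)
        out[self.mesh.node_dof] = vals
        return out

    def kinetic_energy(self, u: np.ndarray) -> float:
        return 0.5 * float(np.einsum("i,ij,ij->", self.mass, u, u))

    def cell_gradients(self, u: np.ndarray) -> np.ndarray:
        """Per-cell velocity gradient tensors, (m, dim, dim): G[c,i,j] = du_i/dx_j."""
        uc = u[self.cdofs]                               # (m, d+1, dim)
        return np.matmul(np.swapaxes(uc, 1, 2), self.grads)

    # -- force terms -------------------------------------------------------

    def _scatter(self, cell_forces: np.ndarray) -> np.ndarray:
        """Accumulate (m, d+1, dim) per-cell nodal forces into DOFs."""
        out = np.empty((self.nd, self.dim))
        flat = self.cdofs.ravel()
        for i in range(self.dim):
            out[:, i] = np.bincount(flat, weights=cell_forces[:, :, i].ravel(),
                                    minlength=self.nd)
        return out

    def _convective_cell_forces(self, uc, gradu, form):
        """(m, d+1, dim) weak convective nodal forces (batched matmuls)."""
        uq = np.matmul(self.bary, uc)                    # (m, nq, dim)
        if form == CONV:
            nl = np.matmul(uq, np.swapaxes(gradu, 1, 2))  # (u . grad) u
        else:
            S = 0.5 * (gradu + np.swapaxes(gradu, 1, 2))
            divu = gradu[:, 0, 0].copy()
            for a in range(1, self.dim):
                divu += gradu[:, a, a]
            nl = 2.0 * np.matmul(uq, S) + divu[:, None, None] * uq
        # integrate against each basis function: phi_k(x_q) = bary[q, k]
        nl *= self.qw[None, :, None]
        cell_f = np.matmul(self.bary.T, nl)
        cell_f *= -self.vols[:, None, None]
        return cell_f

    def nonlinear_force(self, u: np.ndarray, form: str | None = None
                        ) -> np.ndarray:
        """Weak-form convective force  -integral( NL(u) . phi_i )."""
        form = form or self.config.nonlinear_form
        if form not in (CONV, EMAC):
            raise SolverError(f"unknown nonlinear form {form!r}")
        uc = u[self.cdofs]
        gradu = np.matmul(np.swapaxes(uc, 1, 2), self.grads)
        return self._scatter(self._convective_cell_forces(uc, gradu, form))

    def viscous_force(self, u: np.ndarray) -> np.ndarray:
        """Weak symmetric-gradient viscous force  -2 nu (S(u), S(phi))."""
        gradu = self.cell_gradients(u)
        S2 = gradu + np.swapaxes(gradu, 1, 2)            # 2 S(u)
        cell_f = np.matmul(self.grads, np.swapaxes(S2, 1, 2))
        cell_f *= -self.nu * self.vols[:, None, None]
        return self._scatter(cell_f)

    def darcy_force(self, u: np.ndarray) -> np.ndarray:
        """Weak Darcy drag -(nu/k) u on porous-tagged cells (lumped)."""
        if self.permeability is None or not self.porous_volume.any():
            return np.zeros_like(u)
        return -(self.nu / self.permeability) * self.porous_volume[:, None] * u

    def _boundary_forces(self, u: np.ndarray) -> np.ndarray:
        """Backflow stabilisation on the outlet (weak, nodal).

        The EMAC discrete energy identity carries the boundary flux
        (u.n)|u|^2 -- twice the kinetic-energy flux -- so the penalty
        coefficient defaults to 1.0 rather than the 1/2 used with
        skew-symmetric forms; beta = 1 exactly cancels the worst-case
        energy import through re-entering outlet flow.
        """
        F = np.zeros_like(u)
        beta = self.config.backflow_beta
        if beta <= 0 or not len(getattr(self, "outlet_faces", ())):
            return F
        nn = self.outlet_faces.shape[1]
        ubar = u[self.outlet_fdofs].mean(axis=1)          # (k, dim)
        un = np.einsum("ki,ki->k", ubar, self.outlet_normals)
        w = beta * np.minimum(un, 0.0) * self.outlet_areas / nn
        contrib = w[:, None, None] * u[self.outlet_fdofs]
        for j in range(nn):
            for i in range(self.dim):
                np.add.at(F[:, i], self.outlet_fdofs[:, j], contrib[:, j, i])
        return F

    def outlet_flow_rate(self, u: np.ndarray) -> float:
        if not len(getattr(self, "outlet_faces", ())):
            return 0.0
        ubar = u[self.outlet_fdofs].mean(axis=1)
        return float(np.einsum("ki,ki,k->", ubar, self.outlet_normals,
                               self.outlet_areas))

    def inlet_flow_rate(self, u: np.ndarray) -> float:
        if not len(getattr(self, "inlet_faces", ())):
            return 0.0
        ubar = u[self.inlet_fdofs].mean(axis=1)
        return -float(np.einsum("ki,ki,k->", ubar, self.inlet_normals,
                                self.inlet_areas))

    def acceleration(self, u: np.ndarray) -> np.ndarray:
        """M^-1 of all explicit forces except the Darcy drag."""
        uc = u[self.cdofs]
        gradu = np.matmul(np.swapaxes(uc, 1, 2), self.grads)
        cell_f = self._convective_cell_forces(uc, gradu,
                                              self.config.nonlinear_form)
        S2 = gradu + np.swapaxes(gradu, 1, 2)            # 2 S(u)
        visc = np.matmul(self.grads, S2)
        visc *= self.nu * self.vols[:, None, None]
        cell_f -= visc
        F = self._scatter(cell_f)
        F += self._boundary_forces(u)
        if self.body_force is not None:
            F += self.mass[:, None] * self.body_force[None, :]
        return F / self.mass[:, None]

    # -- constraints and projection ----------------------------------------

    def apply_dirichlet(self, u: np.ndarray, t: float) -> np.ndarray:
        for ds in self.bcs.dirichlet:
            vals = ds.values_at(t, self.dim)
            comp = np.asarray(ds.components, dtype=bool)
            dofs = np.asarray(ds.dofs, dtype=np.int64)
            u[np.ix_(dofs, np.nonzero(comp)[0])] = vals[:, comp]
        return u

    def divergence(self, u: np.ndarray) -> np.ndarray:
        return sum(self.B[j] @ u[:, j] for j in range(self.dim))

    def divergence_rel(self, u: np.ndarray) -> float:
        """Relative weak-divergence norm over the controllable pressure rows.

        Rows whose whole velocity stencil is Dirichlet-prescribed are fixed
        by the boundary data and excluded: they measure how compatible the
        prescribed inflow/no-slip data are at corners, not the projection.
        """
        div = self.divergence(u)[self._controllable]
        scale = np.linalg.norm(
            sum(self.B_abs[j] @ np.abs(u[:, j])
                for j in range(self.dim))[self._controllable])
        return float(np.linalg.norm(div) / (scale + 1e-300))

    def project(self, u: np.ndarray):
        """Exact discrete projection onto the weakly divergence-free space."""
        rhs = self.divergence(u)
        self._last_div_rhs = rhs.copy()
        rhs = np.where(self._controllable, rhs, 0.0)
        phi = self._schur.solve(rhs)
        for j in range(self.dim):
            u[:, j] -= (self.B_hat_T[j] @ phi) / self.mass
        return u, phi

    def smooth_pressure(self, div_rhs: np.ndarray, tau: float) -> np.ndarray:
        """Kinematic pressure from the stabilised (stiffness) Poisson solve."""
        rhs = -div_rhs / tau
        if self._p_enclosed:
            rhs = rhs - rhs.mean()
        rhs[self._p_fixed] = 0.0
        return self._pressure_poisson.solve(rhs)

    # -- time stepping ------------------------------------------------------

    def estimate_timestep(self, u: np.ndarray) -> float:
        """dt = cfl / max nodal rate, rate built from |u|/h + C_d nu/h^2.

        Per-cell rates (h = smallest altitude = 1/max|grad phi|) are
        mass-weighted and summed onto nodes, a Gershgorin-style bound on the
        explicit operator: on a uniform mesh this reduces exactly to
        cfl / max_cells(|u|/h + C_d nu/h^2), while slivers, whose volume is
        negligible in the lumped mass, no longer collapse the step.
        """
        umax = np.abs(u[self.cdofs]).max(axis=(1, 2)) if len(u) else 0.0
        rate_cell = (umax / self.h_cell
                     + self.config.diffusive_constant * self.nu
                     / self.h_cell ** 2)
        w = self.vols / (self.dim + 1)
        nodal = np.zeros(self.nd)
        np.add.at(nodal, self.cdofs.ravel(),
                  np.repeat(rate_cell * w, self.dim + 1))
        rmax = float((nodal / self.mass).max())
        if not np.isfinite(rmax) or rmax <= 0:
            raise SolverError("degenerate cell in time-step estimate")
        return self.config.cfl_safety / rmax

    def _darcy_implicit(self, u: np.ndarray, dt_eff: float) -> np.ndarray:
        if self.permeability is None or not self.porous_volume.any():
            return u
        lam = (self.nu / self.permeability) * self.porous_volume / self.mass
        return u / (1.0 + dt_eff * lam)[:, None]

    def _stage(self, u: np.ndarray, t_stage: float, dt: float):
        w = u + dt * self.acceleration(u)
        w = self._darcy_implicit(w, dt)
        self.apply_dirichlet(w, t_stage)
        return w

    def step(self, state: FlowState, dt: float,
             compute_pressure: bool = True,
             check_divergence: bool = True) -> FlowState:
        """One SSP-RK3 step with stage-wise non-incremental projection."""
        u, t = state.velocity, state.time
        w1 = self._stage(u, t + dt, dt)
        w1, _ = self.project(w1)
        w2 = 0.75 * u + 0.25 * self._stage(w1, t + dt, dt)
        self.apply_dirichlet(w2, t + 0.5 * dt)
        w2, _ = self.project(w2)
        w3 = (u + 2.0 * self._stage(w2, t + 0.5 * dt, dt)) / 3.0
        self.apply_dirichlet(w3, t + dt)
        w3, phi = self.project(w3)
        if not np.isfinite(w3).all():
            raise SolverError(
                f"solution blew up (NaN/Inf) stepping from t = {t:.6g} s "
                f"with dt = {dt:.3g} s")
        p = (self.smooth_pressure(self._last_div_rhs, (2.0 / 3.0) * dt)
             if compute_pressure else state.pressure)
        new = FlowState(t + dt, w3, p)
        if check_divergence:
            div_rel = self.divergence_rel(w3)
            if div_rel > self.config.projection_tolerance:
                raise SolverError(
                    f"projection failed: relative divergence {div_rel:.3e} "
                    f"exceeds {self.config.projection_tolerance:.1e}")
            new._div_rel = div_rel
        return new


def assemble_nonlinear(solver: NavierStokesSolver, u: np.ndarray,
                       form: str) -> np.ndarray:
    """Weak convective force of ``u`` under CONV or EMAC (module-level API)."""
    return solver.nonlinear_force(u, form)


def darcy_drag(solver: NavierStokesSolver, u: np.ndarray,
               permeability: float) -> np.ndarray:
    """Weak Darcy drag force for a given intrinsic permeability."""
    old = solver.permeability
    solver.set_permeability(permeability)
    try:
        return solver.darcy_force(u)
    finally:
        solver.permeability = old


def solve_transient(mesh: VolumeMesh, props: FluidProperties,
                    config: SolverConfig, bcs: BoundaryConditions,
                    probes: dict | None = None,
                    permeability: float | None = None,
                    initial: FlowState | None = None) -> RunRecord:
    """Run from rest to ``config.max_time``, recording frames and probes.

    ``probes`` maps probe names to DOF index arrays; their physical pressures
    (rho * p + outlet offset, Pa) are sampled at every output frame.
    """
    solver = NavierStokesSolver(mesh, props, config, bcs)
    if permeability is not None:
        solver.set_permeability(permeability)
    state = initial.copy() if initial is not None else solver.zero_state()
    solver.apply_dirichlet(state.velocity, state.time)
    state.velocity, _ = solver.project(state.velocity)

    record = RunRecord(mesh=mesh, props=props, config=config,
                       probe_nodes=dict(probes or {}))
    for name in record.probe_nodes:
        record.probe_pressures[name] = []

    def p_offset(u):
        if bcs.outlet_model is None:
            return 0.0
        return outlet_pressure(solver.outlet_flow_rate(u), bcs.outlet_model)

    def snapshot(st):
        record.frame_times.append(st.time)
        record.frames.append(st.copy())
        off = p_offset(st.velocity)
        record.pressure_offset.append(off)
        for name, dofs in record.probe_nodes.items():
            record.probe_pressures[name].append(
                props.density * st.pressure[dofs] + off)

    snapshot(state)
    t_end = config.max_time
    next_out = config.output_interval
    guard = 0
    dt_est = None
    while state.time < t_end - 1e-12:
        if config.fixed_dt:
            dt = config.fixed_dt
        else:
            # re-estimate every few steps; 0.95 margin covers the growth of
            # |u| between estimates
            if dt_est is None or guard % 5 == 0:
                dt_est = 0.95 * solver.estimate_timestep(state.velocity)
            dt = dt_est
        dt = min(dt, t_end - state.time, next_out - state.time)
        if dt <= 0:
            dt = 1e-12
        at_frame = state.time + dt >= next_out - 1e-12
        state = solver.step(state, dt, compute_pressure=at_frame,
                            check_divergence=(guard % 5 == 0 or at_frame))
        record.max_divergence = max(record.max_divergence,
                                    getattr(state, "_div_rel", 0.0))
        record.step_times.append(state.time)
        record.outlet_flow.append(solver.outlet_flow_rate(state.velocity))
        record.inlet_flow.append(solver.inlet_flow_rate(state.velocity))
        if state.time >= next_out - 1e-12:
            snapshot(state)
            next_out = min(next_out + config.output_interval, t_end)
        guard += 1
        if guard > 2_000_000:
            raise SolverError("step budget exceeded; dt collapsed?")
    if record.frame_times[-1] < state.time - 1e-12:
        snapshot(state)
    return record
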