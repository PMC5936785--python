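"""Canonical solver validation cases with analytic references.

Each function builds its own small mesh, runs the solver, and returns a dict
of measured errors against closed-form solutions: plane Poiseuille flow,
viscous and inviscid Taylor-Green vortices (kinetic-energy decay and the
discrete energy-conservation contrast between the EMAC and convective
forms), the steady Darcy-channel momentum balance, and the spherical
Q-criterion isosurface.  Problem sizes are chosen so every case runs in
seconds to a couple of minutes on one core while staying in the asymptotic
regime of its analytic reference.
"""

from __future__ import annotations

import numpy as np

from . import _geom, meshes, solver
from .anatomy import FluidProperties
from .hemodynamics import vortex_surface


def _run_to(s: solver.NavierStokesSolver, state, t_end, fixed_dt=None):
    div_max = 0.0
    while state.time < t_end - 1e-12:
        dt = fixed_dt or s.estimate_timestep(state.velocity)
        state = s.step(state, min(dt, t_end - state.time))
        div_max = max(div_max, getattr(state, "_div_rel", 0.0))
    return state, div_max


def poiseuille_case(n_across: int = 16, n_along: int = 24,
                    nu: float = 0.1, force: float = 1.0,
                    t_end: float = 5.0, form: str = "EMAC") -> dict:
    """Body-force-driven periodic channel vs the parabolic profile.

    Returns the maximum nodal deviation from u(y) = f y (H - y) / (2 nu),
    relative to the exact centreline velocity.
    """
    H = 1.0
    mesh = meshes.rectangle_grid(n_along, n_across, 1.5, H, periodic_x=True)
    props = FluidProperties(density=1.0, dynamic_viscosity=nu)
    cfg = solver.SolverConfig(nonlinear_form=form, max_time=t_end)
    wall_dofs = np.unique(mesh.node_dof[mesh.boundary_faces])
    bcs = solver.BoundaryConditions(
        dirichlet=[solver.DirichletSet(wall_dofs, np.array([True, True]), 0.0)],
        body_force=np.array([force, 0.0]))
    s = solver.NavierStokesSolver(mesh, props, cfg, bcs)
    state, div_max = _run_to(s, s.zero_state(), t_end)
    y = mesh.vertices[:, 1]
    u_exact = force * y * (H - y) / (2 * nu)
    ux = state.velocity[mesh.node_dof, 0]
    err = np.abs(ux - u_exact).max() / u_exact.max()
    return {"profile_rel_err": float(err), "div_rel_max": div_max,
            "centreline": float(ux[np.isclose(y, 0.5)].mean()),
            "centreline_exact": force * H * H / (8 * nu)}


def _taylor_green(pts):
    x, y = pts[:, 0], pts[:, 1]
    return np.stack([np.sin(x) * np.cos(y), -np.cos(x) * np.sin(y)], axis=1)


def _two_mode_field(pts):
    # stream function cos x cos y + 0.35 cos(2x+0.9) cos(y+0.4): divergence
    # free but without the symmetries that make single-mode dynamics trivial
    x, y = pts[:, 0], pts[:, 1]
    u = -np.cos(x) * np.sin(y) - 0.35 * np.cos(2 * x + 0.9) * np.sin(y + 0.4)
    v = np.sin(x) * np.cos(y) + 0.70 * np.sin(2 * x + 0.9) * np.cos(y + 0.4)
    return np.stack([u, v], axis=1)


def taylor_green_decay_case(n: int = 48, nu: float = 0.01,
                            t_end: float = 1.0) -> dict:
    """Viscous Taylor-Green: KE(t) = KE(0) exp(-4 nu t).

    Runs both nonlinear forms; also reports their L2 field difference.
    """
    L = 2 * np.pi
    mesh = meshes.rectangle_grid(n, n, L, L, periodic_x=True, periodic_y=True)
    props = FluidProperties(density=1.0, dynamic_viscosity=nu)
    out = {}
    fields = {}
    for form in (solver.EMAC, solver.CONV):
        cfg = solver.SolverConfig(nonlinear_form=form, max_time=t_end)
        s = solver.NavierStokesSolver(mesh, props, cfg,
                                      solver.BoundaryConditions())
        state = solver.FlowState(0.0, s.interpolate(_taylor_green),
                                 np.zeros(s.nd))
        state.velocity, _ = s.project(state.velocity)
        e0 = s.kinetic_energy(state.velocity)
        state, div_max = _run_to(s, state, t_end)
        e1 = s.kinetic_energy(state.velocity)
        expected = e0 * np.exp(-4 * nu * t_end)
        out[f"decay_rel_err_{form.lower()}"] = abs(e1 - expected) / expected
        out[f"div_rel_max_{form.lower()}"] = div_max
        fields[form] = state.velocity.copy()
    num = np.linalg.norm(fields[solver.EMAC] - fields[solver.CONV])
    out["emac_conv_l2_rel_diff"] = float(
        num / np.linalg.norm(fields[solver.EMAC]))
    return out


def inviscid_energy_case(n: int = 32, dt: float = 0.002,
                         n_steps: int = 200) -> dict:
    """Inviscid periodic run: EMAC conserves discrete KE, CONV drifts."""
    L = 2 * np.pi
    mesh = meshes.rectangle_grid(n, n, L, L, periodic_x=True, periodic_y=True)
    props = FluidProperties(density=1.0, dynamic_viscosity=1e-30)
    out = {}
    for form in (solver.EMAC, solver.CONV):
        cfg = solver.SolverConfig(nonlinear_form=form, fixed_dt=dt,
                                  max_time=dt * n_steps)
        s = solver.NavierStokesSolver(mesh, props, cfg,
                                      solver.BoundaryConditions())
        state = solver.FlowState(0.0, s.interpolate(_two_mode_field),
                                 np.zeros(s.nd))
        state.velocity, _ = s.project(state.velocity)
        e0 = s.kinetic_energy(state.velocity)
        drift = 0.0
        for _ in range(n_steps):
            state = s.step(state, dt)
            drift = max(drift,
                        abs(s.kinetic_energy(state.velocity) - e0) / e0)
        out[f"energy_drift_{form.lower()}"] = float(drift)
    return out


def darcy_channel_case(drag_rate: float = 2.0, dt: float = 0.01,
                       t_end: float = 3.0) -> dict:
    """Fully porous plug-flow channel: |grad p| = (mu/k) |u| at steady state.

    ``drag_rate`` is nu/k in 1/s; slip walls keep the profile flat so the
    Darcy balance is exact up to the semi-implicit splitting error ~ dt*rate.
    """
    rho, mu = 1.0, 0.01
    nu = mu / rho
    k = nu / drag_rate
    U = 1.0
    mesh = meshes.rectangle_grid(24, 8, 1.0, 0.4, tag_left=meshes.INLET,
                                 tag_right=meshes.OUTLET)
    mesh.cell_region[:] = meshes.POROUS
    props = FluidProperties(density=rho, dynamic_viscosity=mu)
    cfg = solver.SolverConfig(max_time=t_end, fixed_dt=dt)
    wall = np.unique(mesh.node_dof[
        mesh.boundary_faces[mesh.boundary_tags == meshes.WALL]])
    inlet = np.unique(mesh.node_dof[
        mesh.boundary_faces[mesh.boundary_tags == meshes.INLET]])
    bcs = solver.BoundaryConditions(dirichlet=[
        solver.DirichletSet(wall, np.array([False, True]), 0.0),
        solver.DirichletSet(inlet, np.array([True, True]), np.array([U, 0.0])),
    ])
    s = solver.NavierStokesSolver(mesh, props, cfg, bcs)
    s.set_permeability(k)
    state, div_max = _run_to(s, s.zero_state(), t_end, fixed_dt=dt)
    gp = np.einsum("cki,ck->ci", s.grads, state.pressure[s.cdofs])
    cent = mesh.cell_centroids()
    sel = (cent[:, 0] > 0.15) & (cent[:, 0] < 0.85)
    grad_measured = float(np.abs(gp[sel, 0]).mean()) * rho   # physical Pa/m
    grad_expected = mu / k * U
    return {"balance_rel_err": abs(grad_measured - grad_expected)
            / grad_expected,
            "grad_measured": grad_measured, "grad_expected": grad_expected,
            "div_rel_max": div_max}


def mass_conservation_case(edge_length: float = 0.0026,
                           t_end: float = 0.06) -> dict:
    """Constant-inflow cavity run: outlet flux matches inlet flux.

    For an incompressible flow in a rigid cavity the balance holds at every
    instant once the inflow ramp has finished, so a short horizon suffices;
    the geometry needs several cells across each tube for the discrete
    divergence constraint to be well posed (see the methods note).
    """
    from . import anatomy, boundary, study
    params = study.desk_cavity_params()
    # shorter tubes than the full study: the balance is a surface integral
    params = anatomy.CavityParams(
        **{**params.__dict__, "inlet_tube_length": 0.03,
           "outlet_tube_length": 0.03})
    surf = anatomy.build_smoothed_cavity(params)
    mesh = anatomy.tetrahedralize(surf, edge_length=edge_length)
    props = FluidProperties()
    cfg = solver.SolverConfig(max_time=t_end, output_interval=0.01,
                              projection_tolerance=1e-2)
    bcs = solver.build_cavity_bcs(mesh, boundary.ConstantInflow(0.55, 0.02))
    record = solver.solve_transient(mesh, props, cfg, bcs)
    n_avg = max(1, len(record.outlet_flow) // 5)
    q_out = float(np.mean(record.outlet_flow[-n_avg:]))
    q_in = float(np.mean(record.inlet_flow[-n_avg:]))
    return {"flux_rel_err": abs(q_out - q_in) / abs(q_in),
            "q_in": q_in, "q_out": q_out,
            "div_rel_max": record.max_divergence}


def q_sphere_case(n: int = 26) -> dict:
    """Radial Q field Q(r) = Q0 (1 - r/R): isosurface at Q0/2 is a sphere.

    The marching-tetrahedra area is compared with 4 pi (R/2)^2.
    """
    R = 1.0
    mesh = meshes.box_tets((n, n, n), (2.2 * R,) * 3,
                           origin=(-1.1 * R,) * 3)
    r = np.linalg.norm(mesh.vertices, axis=1)
    q0 = 1000.0
    q_nodes = q0 * (1 - r / R)
    area = _geom.marching_tets_area(mesh.vertices, mesh.cells, q_nodes,
                                    q0 / 2)
    exact = 4 * np.pi * (R / 2) ** 2
    return {"area_rel_err": abs(area - exact) / exact,
            "area": float(area), "area_exact": float(exact)}
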