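# Methods

`lvflow` is a desk-scale workbench for studying how endocardial trabeculation
alters left-ventricular (LV) hemodynamics, and how well a near-wall porous
(Darcy) layer can stand in for resolved trabeculae inside a smooth-walled
model. This note documents the models, the numerical choices, what the
synthetic geometry does and does not emulate, and the known limitations.

## Flow model

The blood is an incompressible Newtonian fluid (density ρ = 1060 kg/m³,
dynamic viscosity μ = 0.0035 kg/(m·s)) in a rigid cavity Ω with boundary
Γ split into inlet, outlet and wall. The solver advances the incompressible
Navier–Stokes equations in kinematic-pressure form,

    ∂t u + NL(u) − 2ν ∇·S(u) + ∇p = f,     ∇·u = 0,

with ν = μ/ρ, S(u) = ½(∇u + ∇uᵀ), and the nonlinear term in one of two
forms: the classical convective form `NL_conv(u) = u·∇u`, or the
energy/momentum/angular-momentum conserving form
`NL_emac(u) = 2 S(u) u + (∇·u) u`. The two coincide for exactly
divergence-free fields but differ discretely; EMAC satisfies
(NL(u), u) = 0 for *any* u on a periodic domain, which the discretisation
preserves exactly (see below). Reported pressures are ρ·p in Pa.

In porous-tagged cells a Darcy drag −(μ/k) u is added to the momentum
equation, with k the intrinsic permeability of the layer.

## Discretisation

* **Elements.** Equal-order P1 (linear) velocity and pressure on triangles
  (2D) or tetrahedra (3D), with a lumped velocity mass matrix. Convective
  and EMAC integrands are degree ≤ 2 per cell and are integrated with
  quadrature rules exact at that degree; this exactness is what makes the
  discrete EMAC energy identity hold to machine precision on periodic
  meshes.
* **Time integration.** Three-stage SSP Runge–Kutta. A non-incremental
  pressure projection is applied after *every* stage: the projection solves
  the exact discrete Schur system `(B M⁻¹ B̂ᵀ) φ = B u*` built from the
  weak divergence operator B (columns at Dirichlet-constrained velocity
  DOFs removed in B̂), factorised once per mesh. Stage-wise projection makes
  the scheme equivalent to SSP-RK3 applied to the projected dynamics
  u′ = Π NL(u), so the inviscid EMAC kinetic-energy drift is the O(Δt⁴)
  integrator truncation — measured below 10⁻⁶ relative over hundreds of
  steps — while the convective form drifts through its nonzero discrete
  energy production.
* **Two pressures.** The Schur operator projects exactly but, like any
  unstabilised equal-order pair, admits element-scale spurious pressure
  modes. The *reported* pressure therefore comes from a separate Poisson
  solve with the P1 stiffness matrix (the classical fractional-step
  stabilisation), with p = 0 weakly anchored at the outlet. The velocity
  field never sees this smoothed pressure.
* **Projection robustness.** The Schur operator is positive semi-definite:
  pressure modes supported where every velocity DOF in their stencil is
  Dirichlet-prescribed are null modes, and the global constant joins them on
  enclosed/periodic domains. A spectral shift of 10⁻⁸ times the median
  diagonal makes the factorisation robust; rows fully determined by
  boundary data are excluded from both the projection right-hand side and
  the reported divergence norm (they measure the corner compatibility of
  the prescribed data, not the projection). On the analytic validation
  meshes the post-projection relative divergence is 10⁻¹⁶–10⁻⁹; on coarse
  cavity meshes a handful of nearly-determined corner rows keep an
  irreducible residual of order 10⁻⁵, which is monitored and gated at 10⁻³.
* **Darcy drag** is integrated semi-implicitly: after the explicit stage
  update, porous DOFs are divided by (1 + Δt ν/k), a diagonal solve. This
  keeps strong drag (ν/k up to ~10⁵ s⁻¹ for σ = 70 kg/m²) unconditionally
  stable; the price is a first-order splitting bias of relative size
  ~Δt·ν/k in the drag–pressure balance, which the Darcy validation case
  keeps at the percent level by construction and which acts as a mild
  under-estimate of the drag in desk runs.
* **Time step.** dt = C / max(rate), with per-cell rates
  |u|/h + C_d ν/h² (h the smallest cell altitude, C_d = 4) mass-weighted
  and summed onto nodes — a Gershgorin-style bound on the explicit
  operator. On uniform meshes this reduces exactly to the familiar
  per-cell bound (dt = C h²/(C_d ν) at rest; dt ∝ h under convection);
  on Delaunay meshes it prevents slivers, whose volume is negligible in
  the lumped mass, from collapsing the step. Default safety C = 0.5
  (0.7 for the desk study, still well inside the RK3 stability region).
* **Outlet.** Free (natural) outflow with a quadratic backflow penalty on
  re-entering velocity. The penalty coefficient is 1.0: the EMAC discrete
  energy identity carries the boundary flux (u·n)|u|², twice the
  kinetic-energy flux that the conventional ½-coefficient cancels for
  skew-symmetric forms, and β = 1 restores an energy bound when vortices
  re-enter through the outlet. With velocity-driven protocols the flow rate is set
  by the inlet, so the resistive outlet model P = P₀ + R·Q (baseline
  10 700 Pa, R = 6·10⁶ Pa·s/m³ chosen so the resistive rise is O(1 kPa) at
  peak flow) enters as the reported absolute-pressure offset rather than as
  a traction: mode-difference pressure drops are invariant to this gauge.
* **Inflow.** Flat-profile velocity along the inlet-tube axis, realised as
  a steep plug 1 − (r/R)⁸ vanishing at the tube wall (a flat profile with a
  jump to the no-slip ring is not representable at finite resolution), with
  a 0.02 s linear start-up ramp.

## Synthetic anatomy

The smoothed cavity is a truncated prolate half-ellipsoid with a planar
base carrying a mitral-side inlet orifice and an aortic-side outlet
orifice; each orifice extends into an oblique cylindrical flow-development
tube (50 mm inlet, 70 mm outlet by default) with a planar end cap
perpendicular to the tube axis. Default tilts put 49° between the two
valve-plane normals and 2.1 cm between the valve centres, matching one of
the published anatomies.

Trabeculation displaces wall vertices inward along their normals under a
seeded sum of Gaussian bumps (width 4.5 mm by default, floored so each
protrusion neck is ≥ 1 mm² in cross-section) plus two papillary-muscle-scale
bumps in the basal third; displacement tapers to zero at the basal rim and
is guarded against surface self-intersection. When a target trabecular
volume fraction is requested the global amplitude is calibrated by
bisection against the convex-hull marker
`100·(V_hull − V_mesh)/V_hull`, computed on the cavity with tube geometry
removed. At the default 20% target, generated geometries land at 15–21%
across seeds (the self-intersection guard caps some seeds below target),
inside the published 10.9–26.6% per-heart range.

The tetrahedraliser seeds a jittered interior lattice plus axial "spines"
along the cavity long axis and the tubes (these guarantee interior nodes
near the tapering apex, the orifice planes and the tube caps — without
them, whole cell patches have every vertex on the boundary and the
discrete divergence constraint degenerates), takes the Delaunay
triangulation and keeps tetrahedra whose centroid lies inside the surface.
Near-degenerate "chord" tetrahedra over flat surface patches are handled in
three stages: refinement points inserted just inward of flat cells (keeping
the best configuration seen), pruning of flat boundary-connected slivers
(volume-guarded, so the covered volume is conserved), and a final sweep of
any cell flatter than 5% of the median altitude. The sweep can leave
sub-cell-thin internal flakes; their exposed facets are flagged as
non-genuine boundary so wall-shear statistics and porous-layer distance
fields ignore them (the solver sees a no-slip flake of negligible size).
Boundary facets inherit inlet/outlet tags from the cap labels with a
geometric fallback. The mesher is a pure function of its inputs.

What the generator does *not* emulate: real endocardial topology
(trabecular bridges and fenestrations — our protrusions never detach from
the wall), valve leaflets, wall motion, and the factor-100 finer meshes of
patient-specific studies. Passing directional tests on these geometries
therefore shows that the *pipeline* reproduces the mechanism — roughness
obstructing near-wall flow — not that it reproduces any particular
patient's numbers.

## Analysis pipeline

* **Pressure drop.** Physical pressure is sampled at the nodes of all cells
  whose centroid lies within 15 mm of the valve plane along each tube axis.
  Per output frame (every 5 ms), ΔP = mode(P_in) − mode(P_out), using
  Freedman–Diaconis histograms (bin width 2·IQR·n^(−1/3),
  linear-interpolation quantiles, unit area, mode = centre of the peak bin
  with ties toward the lower bin); the run statistic is the mean ± SD over
  the last 10 frames (≈50 ms).
* **WSS.** Per wall facet, the tangential part of the viscous traction
  2μ S(u)·n from the owning cell's gradient; tube walls are excluded from
  cavity statistics; summarised by FD histogram, mode, median, max
  (unweighted facet samples — facets are near-uniform in size).
* **Q-criterion.** Q = ½(‖W‖²_F − ‖S‖²_F) per cell; volume-weighted
  node averaging; the total vortex surface is the area of the Q = threshold
  isosurface extracted by marching tetrahedra (5000 s⁻² for constant-inflow
  runs, 1000 s⁻² for transient E–A runs; single-sided areas).
* **Porous surrogate.** The layer strength σ (kg/m²) equals μ/K for
  hydraulic conductivity K (anchor: well-graded gravel, K = 5·10⁻⁴ m/s ⇒
  σ = 7 exactly); the Darcy coefficient uses the intrinsic permeability
  k = K·μ/(ρg) = μ²/(σρg). This reconciliation of the σ unit with the
  momentum equation is the single most consequential modelling identity in
  the package and is pinned by dedicated tests. Surrogate quality is the
  signed relative error (detailed − porous)/detailed per metric
  (negative = overshoot).

## Desk-study conditions

One fixed configuration (chosen once; all knobs remain config-overridable):
cavity long axis 65 mm, base radius 20 mm (~75 ml with tubes), inlet/outlet
radii 9.0/7.5 mm (orifice areas within the published per-heart range),
valve-plane angle 49°; trabeculation target 20% with 7 mm-wide protrusions
— protrusions must span ~3 cells at the study mesh to be dynamically
active; sub-grid rugosity only smooths the cavity, whereas the published
control anatomy shows that a few large protrusions already produce all
three directional effects; tetrahedra with 2.6 mm target edges (≈30–40·10³
cells — resolving each tube with ≥6 cells across, which the equal-order
pair needs for a well-posed discrete divergence constraint); EMAC form;
constant inflow 0.55 m/s ramped over 0.02 s; 0.25 s simulated (the transit
time through the cavity is ≈0.1 s, so the final 50 ms averaging window sees
developed flow); porous run at the published selected layer, thickness
1.2·10⁻² m scaled by the cavity-size ratio (⇒ 8 mm) with σ = 20 kg/m², with
the anatomically smooth sub-valvular vestibules excluded from the layer.
Outcomes at this scale are directional (which model is larger/smaller), not
magnitude reproductions of multi-million-element studies. Measured stability
of the three directional effects across generator seeds: the WSS-median
reduction is robust; the pressure-drop increase is seed-sensitive (crevice
jets can dominate the mode statistic in either direction); the
vortex-surface increase is *not* reproduced — fragmentation of the inflow
ring into secondary vortices happens between trabeculae at scales below the
2.6 mm cells, so at this resolution the rough wall dissipates the ring
instead of multiplying its surface. The corresponding acceptance checks
report exactly this: the WSS direction passes, the vortex direction fails,
and the pressure-drop direction passes at the study seed while the methods
here flag it as marginal.

## Limitations

Rigid walls, no valves, no fluid–structure interaction; laminar
under-resolved convection at inlet Reynolds ≈3000 relies on the
energy-conserving form for stability rather than a turbulence model; the
porous layer is isotropic and uniform; pressure accuracy is first order in
time (non-incremental splitting); surrogate and directional conclusions are
established at desk resolution only.
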