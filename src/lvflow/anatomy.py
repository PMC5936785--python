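"""Synthetic ventricle-like anatomy factory.

Builds paired smoothed/trabeculated left-ventricle-like cavities: a truncated
prolate half-ellipsoid with a planar base carrying a mitral-side inlet orifice
and an aortic-side outlet orifice, each extended by a flow-development tube
(50 mm inlet, 70 mm outlet by default).  A seeded displacement field adds
trabecula-like wall protrusions and two papillary-muscle-scale bumps; the
smoothed counterpart is simply the undisplaced surface.  Also provides the
geometric markers used to characterise each anatomy (trabecular volume
percentage by convex hull, valve-plane angle, valve-centre distance, orifice
areas, inlet Reynolds number), a Delaunay-based tetrahedralizer and porous
near-wall layer tagging.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
import trimesh.repair
from scipy.spatial import ConvexHull, Delaunay, cKDTree

from . import _geom
from .meshes import (FLUID, INLET, LBL_INLET_CAP, LBL_INLET_TUBE,
                     LBL_OUTLET_CAP, LBL_OUTLET_TUBE, LBL_WALL, MeshError,
                     OUTLET, POROUS, SurfaceMesh, VolumeMesh, WALL,
                     orient_cells_positive)


class GeometryError(ValueError):
    """Raised when geometry parameters cannot produce a valid surface."""


@dataclass
class CavityParams:
    """Parameters of the smoothed ventricle-like cavity (SI meters).

    The cavity is a half-ellipsoid of depth ``long_axis_length`` below the
    basal plane z = 0 with in-plane radius ``base_radius``.  Orifice centres
    sit on the basal plane at the given 2D offsets; tubes are oblique
    cylinders along axes tilted in the x-z plane by the given angles, with
    planar end caps perpendicular to the tube axes.
    """

    long_axis_length: float = 0.08
    base_radius: float = 0.025
    inlet_offset: tuple = (-0.012, 0.0)
    outlet_offset: tuple = (0.009, 0.0)
    inlet_radius: float = 0.011
    outlet_radius: float = 0.007
    inlet_tube_length: float = 0.050
    outlet_tube_length: float = 0.070
    inlet_tilt_deg: float = -20.0
    outlet_tilt_deg: float = 29.0
    n_phi: int = 64               # circumferential resolution of the rim
    n_theta: int = 24             # meridional resolution of the bowl

    def validate(self) -> None:
        if self.long_axis_length <= 0 or self.base_radius <= 0:
            raise GeometryError("long_axis_length and base_radius must be > 0")
        for name in ("inlet", "outlet"):
            r = getattr(self, f"{name}_radius")
            lt = getattr(self, f"{name}_tube_length")
            if r > 0 and lt <= 0:
                raise GeometryError(f"{name}_tube_length must be > 0")
            off = np.asarray(getattr(self, f"{name}_offset"))
            if r > 0 and np.hypot(*off) + r >= 0.98 * self.base_radius:
                raise GeometryError(
                    f"{name} orifice (offset {tuple(off)}, radius {r}) does not "
                    f"fit inside base_radius {self.base_radius}")
        if self.inlet_radius > 0 and self.outlet_radius > 0:
            gap = np.linalg.norm(np.asarray(self.inlet_offset)
                                 - np.asarray(self.outlet_offset))
            if gap <= 1.05 * (self.inlet_radius + self.outlet_radius):
                raise GeometryError(
                    f"orifices overlap: centre distance {gap:.4g} m <= "
                    f"inlet_radius + outlet_radius = "
                    f"{self.inlet_radius + self.outlet_radius:.4g} m "
                    f"(inlet_offset={self.inlet_offset}, "
                    f"outlet_offset={self.outlet_offset})")
            # the tubes themselves must not collide above the base
            a_in = _tilt_axis(self.inlet_tilt_deg)
            a_out = _tilt_axis(self.outlet_tilt_deg)
            p_in = np.array([*self.inlet_offset, 0.0])
            p_out = np.array([*self.outlet_offset, 0.0])
            ts = np.linspace(0.0, 1.0, 64)
            seg_in = p_in + ts[:, None] * self.inlet_tube_length * a_in
            seg_out = p_out + ts[:, None] * self.outlet_tube_length * a_out
            dmin = np.linalg.norm(seg_in[:, None, :] - seg_out[None, :, :],
                                  axis=2).min()
            if dmin <= 1.02 * (self.inlet_radius + self.outlet_radius):
                raise GeometryError(
                    f"inlet and outlet tubes intersect (axis clearance "
                    f"{dmin:.4g} m); adjust inlet_tilt_deg/outlet_tilt_deg "
                    f"or the orifice offsets")


@dataclass
class TrabeculationParams:
    """Seeded wall-protrusion synthesis parameters.

    ``min_cross_section`` floors the neck area of individual protrusions
    (1 mm^2 by default, the smallest anatomical structure class emulated);
    ``target_volume_fraction`` is the fraction of the smoothed cavity volume
    the protrusions should occupy, calibrated by bisection on the generated
    mesh when positive, otherwise ``amplitude`` is used directly.
    """

    amplitude: float = 0.004
    min_cross_section: float = 1e-6
    density: float = 15000.0           # protrusions per m^2 of wall
    target_volume_fraction: float = 0.0
    papillary_count: int = 2
    papillary_scale: float = 2.5
    seed: int = 0
    bump_width: float = 0.0045         # lateral scale of one protrusion

    def validate(self) -> None:
        if self.amplitude < 0:
            raise GeometryError("amplitude must be >= 0")
        if not (0 <= self.target_volume_fraction < 0.5):
            raise GeometryError("target_volume_fraction must be in [0, 0.5)")
        if self.min_cross_section <= 0:
            raise GeometryError("min_cross_section must be > 0")


@dataclass
class FluidProperties:
    """Blood-like fluid constants (defaults: whole blood)."""

    density: float = 1060.0            # kg/m^3
    dynamic_viscosity: float = 0.0035  # kg/(m s)
    body_force: tuple = (0.0, 0.0, 0.0)
    gravity: float = 9.81              # used only in the porosity conversion

    @property
    def kinematic_viscosity(self) -> float:
        return self.dynamic_viscosity / self.density

    def validate(self) -> None:
        if self.density <= 0:
            raise GeometryError("density must be > 0")
        if self.dynamic_viscosity <= 0:
            raise GeometryError("dynamic_viscosity must be > 0")


@dataclass
class GeometryMarkers:
    trabecular_volume_pct: float
    alpha: float                       # degrees between valve-plane normals
    d: float                           # m between valve centres
    inlet_area: float
    outlet_area: float
    inlet_reynolds: float


# ---------------------------------------------------------------------------
# Smoothed cavity construction
# ---------------------------------------------------------------------------

def _tilt_axis(tilt_deg: float) -> np.ndarray:
    t = np.deg2rad(tilt_deg)
    return np.array([np.sin(t), 0.0, np.cos(t)])


def build_smoothed_cavity(params: CavityParams) -> SurfaceMesh:
    """Construct the labelled, watertight smoothed cavity surface.

    Vertex bookkeeping keeps rim and orifice rings shared exactly between the
    bowl, the basal plate and the tubes, so the assembled surface is
    watertight by construction.
    """
    params.validate()
    L, b = params.long_axis_length, params.base_radius
    n_phi, n_theta = params.n_phi, params.n_theta
    ds = 2 * np.pi * b / n_phi                     # target edge length

    verts: list = []
    faces: list = []
    labels: list = []

    def add_vertex(p):
        verts.append(np.asarray(p, dtype=float))
        return len(verts) - 1

    # --- bowl: apex + meridional rings, ring n_theta is the basal rim ------
    apex = add_vertex([0.0, 0.0, -L])
    phis = 2 * np.pi * np.arange(n_phi) / n_phi
    ring_ids = []
    for j in range(1, n_theta + 1):
        th = 0.5 * np.pi * j / n_theta
        r, z = b * np.sin(th), -L * np.cos(th)
        ring_ids.append([add_vertex([r * np.cos(p), r * np.sin(p), z])
                         for p in phis])
    first = ring_ids[0]
    for i in range(n_phi):
        faces.append([apex, first[i], first[(i + 1) % n_phi]])
        labels.append(LBL_WALL)
    for j in range(len(ring_ids) - 1):
        lo, hi = ring_ids[j], ring_ids[j + 1]
        for i in range(n_phi):
            i2 = (i + 1) % n_phi
            faces.append([lo[i], hi[i], hi[i2]])
            faces.append([lo[i], hi[i2], lo[i2]])
            labels.extend([LBL_WALL, LBL_WALL])
    rim = ring_ids[-1]

    # --- orifice rings on the basal plane ---------------------------------
    sides = []
    for name, lbl_tube, lbl_cap in (
            ("inlet", LBL_INLET_TUBE, LBL_INLET_CAP),
            ("outlet", LBL_OUTLET_TUBE, LBL_OUTLET_CAP)):
        radius = getattr(params, f"{name}_radius")
        if radius <= 0:
            continue
        centre = np.array([*getattr(params, f"{name}_offset"), 0.0])
        n_c = max(12, int(round(2 * np.pi * radius / ds)))
        ang = 2 * np.pi * np.arange(n_c) / n_c
        ring = [add_vertex(centre + radius * np.array([np.cos(a), np.sin(a), 0.0]))
                for a in ang]
        sides.append(dict(name=name, centre=centre, radius=radius, ring=ring,
                          axis=_tilt_axis(getattr(params, f"{name}_tilt_deg")),
                          length=getattr(params, f"{name}_tube_length"),
                          lbl_tube=lbl_tube, lbl_cap=lbl_cap))

    # --- basal plate filler points -----------------------------------------
    filler = []
    n_grid = int(np.ceil(2 * b / (ds * np.sqrt(3) / 2)))
    for gy in range(n_grid + 1):
        y = -b + gy * ds * np.sqrt(3) / 2
        xoff = (gy % 2) * ds / 2
        for gx in range(n_grid + 1):
            x = -b + xoff + gx * ds
            p = np.array([x, y, 0.0])
            if np.hypot(x, y) > b - 0.55 * ds:
                continue
            clear = all(np.linalg.norm(p[:2] - s["centre"][:2])
                        > s["radius"] + 0.55 * ds for s in sides)
            if clear:
                filler.append(add_vertex(p))

    base_ids = np.array(rim + filler + [v for s in sides for v in s["ring"]],
                        dtype=np.int64)
    pts2 = np.asarray([verts[i][:2] for i in base_ids])
    tri2 = Delaunay(pts2)
    vol2 = _geom.simplex_volumes(pts2, tri2.simplices)
    for simplex, a in zip(tri2.simplices, vol2):
        if abs(a) < 1e-16:
            continue
        cent = pts2[simplex].mean(axis=0)
        if any(np.linalg.norm(cent - s["centre"][:2]) < s["radius"]
               for s in sides):
            continue
        tri = base_ids[simplex].tolist()
        if a < 0:
            tri[0], tri[1] = tri[1], tri[0]
        # basal plate outward normal is +z; flip to make winding give +z
        faces.append([tri[0], tri[2], tri[1]])
        labels.append(LBL_WALL)

    # sanity: every orifice circle edge must be conforming in the plate mesh
    plate_edges = set()
    for f, lb in zip(faces, labels):
        if lb == LBL_WALL:
            for e in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                plate_edges.add(tuple(sorted(e)))
    for s in sides:
        ring = s["ring"]
        for i in range(len(ring)):
            e = tuple(sorted((ring[i], ring[(i + 1) % len(ring)])))
            if e not in plate_edges:
                raise GeometryError(
                    f"basal plate triangulation does not conform to the "
                    f"{s['name']} orifice; increase n_phi or enlarge the gap "
                    f"between orifices")

    # --- tubes (oblique prisms) with perpendicular planar caps -------------
    for s in sides:
        axis, length, centre = s["axis"], s["length"], s["centre"]
        n_ax = max(4, int(round(length / ds)))
        prev = list(s["ring"])
        cap_centre_pt = centre + length * axis
        for k in range(1, n_ax + 1):
            frac = k / n_ax
            new_ring = []
            for vi in s["ring"]:
                p = verts[vi] + frac * length * axis
                if k == n_ax:  # project last ring onto the perpendicular cap plane
                    p = p - np.dot(p - cap_centre_pt, axis) * axis
                new_ring.append(add_vertex(p))
            for i in range(len(prev)):
                i2 = (i + 1) % len(prev)
                faces.append([prev[i], new_ring[i2], new_ring[i]])
                faces.append([prev[i], prev[i2], new_ring[i2]])
                labels.extend([s["lbl_tube"], s["lbl_tube"]])
            prev = new_ring
        # cap: concentric-ring disk triangulation in the cap plane, so the
        # inflow profile is resolved over the whole cross-section
        e1 = np.array([axis[2], 0.0, -axis[0]])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(axis, e1)
        ring2d = np.array([[np.dot(verts[v] - cap_centre_pt, e1),
                            np.dot(verts[v] - cap_centre_pt, e2)]
                           for v in prev])
        r_out = np.linalg.norm(ring2d, axis=1).mean()
        n_rings = max(1, int(round(r_out / ds)))
        inner_ids, inner_2d = [], []
        for kr in range(n_rings):
            rad = r_out * kr / n_rings
            n_k = 1 if kr == 0 else max(6, int(round(len(prev) * kr / n_rings)))
            for ia in range(n_k):
                aa = 2 * np.pi * ia / n_k + 0.5 * kr
                p2 = rad * np.array([np.cos(aa), np.sin(aa)])
                inner_ids.append(add_vertex(cap_centre_pt + p2[0] * e1
                                            + p2[1] * e2))
                inner_2d.append(p2)
        cap_ids = np.array(prev + inner_ids, dtype=np.int64)
        cap_2d = np.vstack([ring2d, np.asarray(inner_2d)])
        tri_cap = Delaunay(cap_2d)
        a2 = _geom.simplex_volumes(cap_2d, tri_cap.simplices)
        for simplex, asign in zip(tri_cap.simplices, a2):
            if abs(asign) < 1e-16:
                continue
            tri = cap_ids[simplex].tolist()
            if asign < 0:
                tri[0], tri[1] = tri[1], tri[0]
            faces.append(tri)
            labels.append(s["lbl_cap"])

    mesh = SurfaceMesh(np.asarray(verts), np.asarray(faces, dtype=np.int64),
                       np.asarray(labels))
    # fix global orientation for outward normals
    tm = mesh.to_trimesh()
    trimesh.repair.fix_normals(tm)
    if tm.volume < 0:
        tm.invert()
    mesh = SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces),
                       mesh.face_labels, mesh.metadata)
    mesh.metadata["valve_planes"] = {
        s["name"]: {"centre": s["centre"].tolist(), "axis": s["axis"].tolist(),
                    "radius": s["radius"], "tube_length": s["length"]}
        for s in sides}
    mesh.metadata["cavity_params"] = params
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# Trabeculation
# ---------------------------------------------------------------------------

def _vertex_normals(surface: SurfaceMesh) -> np.ndarray:
    areas, normals = _geom.triangle_areas_normals(surface.vertices,
                                                  surface.faces)
    vn = np.zeros_like(surface.vertices)
    w = (areas[:, None] * normals)
    for k in range(3):
        np.add.at(vn, surface.faces[:, k], w)
    nn = np.linalg.norm(vn, axis=1)
    vn[nn > 0] /= nn[nn > 0, None]
    return vn


def _bump_displacement(surface: SurfaceMesh, trab: TrabeculationParams):
    """Unit-amplitude inward displacement magnitudes for each vertex.

    Returns ``(magnitude, movable_mask)``; magnitude is 1 at the deepest bump
    apex for amplitude 1.
    """
    params: CavityParams = surface.metadata.get("cavity_params")
    L = params.long_axis_length if params else float(
        -surface.vertices[:, 2].min())
    rng = np.random.default_rng(trab.seed)

    wall_faces = surface.faces[surface.face_labels == LBL_WALL]
    wall_vids = np.unique(wall_faces)
    v = surface.vertices
    # movable: wall-only vertices strictly below the basal plate
    other_vids = np.unique(surface.faces[surface.face_labels != LBL_WALL])
    movable = np.zeros(len(v), dtype=bool)
    movable[wall_vids] = True
    movable[other_vids] = False
    movable &= v[:, 2] < -0.02 * L

    areas, _ = _geom.triangle_areas_normals(v, wall_faces)
    wall_area = float(areas.sum())
    n_bumps = max(1, int(round(trab.density * wall_area)))
    width_floor = np.sqrt(trab.min_cross_section / np.pi)
    s0 = max(trab.bump_width, 1.6 * width_floor)

    # bump centres: sample wall vertices weighted by incident area, below rim
    vw = np.zeros(len(v))
    fa = areas / 3.0
    for k in range(3):
        np.add.at(vw, wall_faces[:, k], fa)
    cand = np.nonzero(movable & (v[:, 2] < -0.08 * L))[0]
    p_sel = vw[cand] / vw[cand].sum()
    centres = v[rng.choice(cand, size=n_bumps, p=p_sel)]
    widths = np.maximum(s0 * rng.lognormal(0.0, 0.25, n_bumps), width_floor)
    amps = rng.uniform(0.5, 1.0, n_bumps)

    # papillary-muscle-scale protrusions in the basal third
    if trab.papillary_count > 0:
        zlo, zhi = -0.45 * L, -0.15 * L
        pm_cand = cand[(v[cand, 2] > zlo) & (v[cand, 2] < zhi)]
        if len(pm_cand) < trab.papillary_count:
            pm_cand = cand
        pm_ids = rng.choice(pm_cand, size=trab.papillary_count, replace=False)
        centres = np.vstack([centres, v[pm_ids]])
        widths = np.concatenate([widths,
                                 np.full(trab.papillary_count,
                                         trab.papillary_scale * s0)])
        amps = np.concatenate([amps, np.full(trab.papillary_count,
                                             1.6)])

    mag = np.zeros(len(v))
    idx = np.nonzero(movable)[0]
    tree = cKDTree(v[idx])
    for c, s, a in zip(centres, widths, amps):
        near = tree.query_ball_point(c, 3.0 * s)
        if not near:
            continue
        near = np.asarray(near)
        d2 = np.einsum("ij,ij->i", v[idx[near]] - c, v[idx[near]] - c)
        mag[idx[near]] += a * np.exp(-0.5 * d2 / s ** 2)
    # taper toward the basal rim so the plate/rim stays fixed
    taper = np.clip(-v[:, 2] / (0.15 * L), 0.0, 1.0)
    mag *= taper
    mmax = mag.max()
    if mmax > 0:
        mag /= mmax
    return mag, movable


def _apply_displacement(surface: SurfaceMesh, mag: np.ndarray,
                        amplitude: float) -> SurfaceMesh:
    vn = _vertex_normals(surface)
    out = surface.copy()
    out.vertices = surface.vertices - amplitude * mag[:, None] * vn
    return out


def _trabecular_pct(surface: SurfaceMesh) -> float:
    cavity = _closed_cavity(surface)
    v_mesh = cavity.volume()
    hull = ConvexHull(cavity.vertices[np.unique(cavity.faces)])
    return 100.0 * max(hull.volume - v_mesh, 0.0) / hull.volume


def add_trabeculation(surface: SurfaceMesh,
                      trab: TrabeculationParams) -> SurfaceMesh:
    """Displace wall vertices inward along seeded bump/ridge fields.

    Tube and cap faces are untouched; output is watertight (topology is
    preserved) and deterministic for a fixed seed.  When
    ``target_volume_fraction`` > 0 the global amplitude is calibrated by
    bisection so the convex-hull trabecular volume marker hits the target.
    """
    trab.validate()
    if trab.amplitude == 0 and trab.target_volume_fraction == 0:
        return surface.copy()

    mag, movable = _bump_displacement(surface, trab)
    v = surface.vertices
    params: CavityParams | None = surface.metadata.get("cavity_params")
    L = params.long_axis_length if params else float(-v[:, 2].min())
    # self-intersection guard: radially moving vertices must not cross the
    # long axis; axially moving vertices (apex region) have depth to spare
    vn = _vertex_normals(surface)
    radial_frac = np.hypot(vn[:, 0], vn[:, 1])
    r_axis = np.hypot(v[:, 0], v[:, 1])
    limit = np.where(mag > 1e-6,
                     0.6 * r_axis + 0.4 * L * (1.0 - radial_frac), np.inf)
    areas0, normals0 = _geom.triangle_areas_normals(v, surface.faces)

    def build(amp):
        if (amp * mag > limit).any():
            raise GeometryError(
                f"amplitude {amp:.4g} m risks self-intersection "
                f"(protrusions would cross the cavity axis); reduce amplitude "
                f"or density")
        out = _apply_displacement(surface, mag, amp)
        areas, normals = _geom.triangle_areas_normals(out.vertices, out.faces)
        flipped = np.einsum("ij,ij->i", normals, normals0) <= 0
        if (areas <= 1e-16).any() or flipped.any():
            raise GeometryError(
                f"amplitude {amp:.4g} m folds the surface "
                f"(self-intersection detected); reduce amplitude or density")
        return out

    if trab.target_volume_fraction <= 0:
        return build(trab.amplitude)

    target = 100.0 * trab.target_volume_fraction
    hi = trab.amplitude if trab.amplitude > 0 else 0.004
    lo, ceiling = 0.0, None       # ceiling: smallest amplitude known infeasible
    pct_hi = 0.0
    # grow hi until the marker reaches the target, backing off the guard
    for _ in range(40):
        try:
            pct_hi = _trabecular_pct(build(hi))
        except GeometryError:
            ceiling = hi
            hi = 0.5 * (lo + hi)
            if ceiling - hi < 1e-5:
                break
            continue
        if pct_hi >= target:
            break
        lo = hi
        hi = min(hi * 1.4, 0.5 * (hi + ceiling)) if ceiling else hi * 1.4
        if ceiling and ceiling - lo < 1e-5:
            break
    if pct_hi < target:           # guard-limited: return the deepest feasible
        return build(lo if lo > 0 else hi)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        pct = _trabecular_pct(build(mid))
        if abs(pct - target) < 0.02 * target:
            return build(mid)
        if pct < target:
            lo = mid
        else:
            hi = mid
    return build(0.5 * (lo + hi))


# ---------------------------------------------------------------------------
# Geometric markers
# ---------------------------------------------------------------------------

def _boundary_loops(faces: np.ndarray):
    """Closed loops of edges used by exactly one face."""
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]],
                            faces[:, [2, 0]]])
    key = np.sort(edges, axis=1)
    uniq, counts = np.unique(key, axis=0, return_counts=True)
    open_edges = uniq[counts == 1]
    nxt = {}
    for a, b in open_edges:
        nxt.setdefault(a, []).append(b)
        nxt.setdefault(b, []).append(a)
    loops, seen = [], set()
    for start in nxt:
        if start in seen:
            continue
        loop, prev, cur = [start], None, start
        seen.add(start)
        while True:
            nbrs = [x for x in nxt[cur] if x != prev]
            if not nbrs:
                break
            prev, cur = cur, nbrs[0]
            if cur == start:
                break
            loop.append(cur)
            seen.add(cur)
        if len(loop) >= 3:
            loops.append(loop)
    return loops


def _closed_cavity(surface: SurfaceMesh) -> SurfaceMesh:
    """Cavity-only surface (tube geometry removed, orifices fan-capped)."""
    wall = surface.subset([LBL_WALL])
    faces = wall.faces.tolist()
    labels = wall.face_labels.tolist()
    verts = surface.vertices.copy()
    extra = []
    for loop in _boundary_loops(wall.faces):
        c = verts[loop].mean(axis=0)
        extra.append(c)
        ci = len(verts) + len(extra) - 1
        for i in range(len(loop)):
            faces.append([ci, loop[i], loop[(i + 1) % len(loop)]])
            labels.append(LBL_WALL)
    if extra:
        verts = np.vstack([verts, np.asarray(extra)])
    out = SurfaceMesh(verts, np.asarray(faces, dtype=np.int64),
                      np.asarray(labels))
    tm = out.to_trimesh()
    import trimesh.repair as _rep
    _rep.fix_normals(tm)
    if tm.volume < 0:
        tm.invert()
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces),
                       out.face_labels)


def _cap_info(surface: SurfaceMesh, cap_label: str, tube_label: str):
    cap = surface.face_labels == cap_label
    if not cap.any():
        raise GeometryError(
            f"surface has no '{cap_label}' faces; expected labels "
            f"{LBL_INLET_CAP!r} and {LBL_OUTLET_CAP!r}")
    areas, normals = _geom.triangle_areas_normals(surface.vertices,
                                                  surface.faces[cap])
    area = float(areas.sum())
    n = (areas[:, None] * normals).sum(axis=0)
    n /= np.linalg.norm(n)
    cap_centroid = (areas[:, None]
                    * surface.vertices[surface.faces[cap]].mean(axis=1)
                    ).sum(axis=0) / area
    # valve centre: ring shared between tube lateral faces and wall faces;
    # falls back to the cap centroid when the tube is absent
    tube_vids = set(np.unique(surface.faces[surface.face_labels == tube_label]))
    wall_vids = set(np.unique(surface.faces[surface.face_labels == LBL_WALL]))
    ring = np.array(sorted(tube_vids & wall_vids), dtype=np.int64)
    centre = (surface.vertices[ring].mean(axis=0) if len(ring) >= 3
              else cap_centroid)
    return area, n, centre


def inlet_reynolds(area: float, speed: float, props: FluidProperties) -> float:
    """Re = rho * V * D / mu with equivalent circular diameter D = sqrt(4A/pi)."""
    if area <= 0:
        raise GeometryError(f"inlet area must be > 0, got {area}")
    if speed < 0:
        raise GeometryError("speed must be >= 0")
    diameter = np.sqrt(4.0 * area / np.pi)
    return props.density * speed * diameter / props.dynamic_viscosity


def compute_markers(surface: SurfaceMesh, fluid_speed: float = 0.55,
                    props: FluidProperties | None = None) -> GeometryMarkers:
    """Geometric markers of a labelled cavity surface.

    The trabecular volume percentage is 100 (V_hull - V_mesh) / V_hull on the
    cavity with tube geometry removed (tubes are artificial flow developers,
    not anatomy); the valve-plane angle comes from the cap normals and the
    distance from the valve-ring centres.
    """
    props = props or FluidProperties()
    a_in, n_in, c_in = _cap_info(surface, LBL_INLET_CAP, LBL_INLET_TUBE)
    a_out, n_out, c_out = _cap_info(surface, LBL_OUTLET_CAP, LBL_OUTLET_TUBE)
    cosang = np.clip(np.dot(n_in, n_out), -1.0, 1.0)
    alpha = float(np.degrees(np.arccos(cosang)))
    d = float(np.linalg.norm(c_in - c_out))
    pct = _trabecular_pct(surface)
    return GeometryMarkers(
        trabecular_volume_pct=pct, alpha=alpha, d=d,
        inlet_area=a_in, outlet_area=a_out,
        inlet_reynolds=inlet_reynolds(a_in, fluid_speed, props))


# ---------------------------------------------------------------------------
# Tetrahedralization
# ---------------------------------------------------------------------------

def _tet_quality(vertices, cells):
    vols = _geom.simplex_volumes(vertices, cells)
    x = vertices[cells]
    e = np.stack([x[:, i] - x[:, j] for i, j in
                  ((1, 0), (2, 0), (3, 0), (2, 1), (3, 1), (3, 2))], axis=1)
    lmax = np.linalg.norm(e, axis=2).max(axis=1)
    return np.cbrt(6 * np.sqrt(2) * np.abs(vols)) / np.maximum(lmax, 1e-300)


def tetrahedralize(surface: SurfaceMesh, edge_length: float | None = None,
                   volume_band: tuple | None = None,
                   near_wall_refinement: float = 1.0,
                   quality_floor: float = 0.18) -> VolumeMesh:
    """Delaunay mesh of the cavity interior, conforming to the surface points.

    Interior seed points sit on a jittered lattice; tetrahedra whose centroid
    falls outside the closed surface are discarded, and low-quality slivers
    that touch the boundary are pruned (this only recedes the boundary by a
    fraction of one cell).  Boundary facets inherit inlet/outlet tags from the
    cap labels; everything else is wall.
    """
    if not surface.is_watertight:
        raise MeshError("tetrahedralize requires a watertight surface")
    if edge_length is None:
        if volume_band is not None:
            target = float(np.sqrt(volume_band[0] * volume_band[1]))
            edge_length = np.cbrt(6.0 * target)
        else:
            edge_length = float(np.sqrt(surface.face_areas().mean() * 2))
    a = float(edge_length)

    rng = np.random.default_rng(987654321)  # fixed: mesher is deterministic
    lo = surface.vertices.min(axis=0)
    hi = surface.vertices.max(axis=0)
    nxyz = np.maximum(((hi - lo) / a).astype(int) + 1, 1)
    axes = [lo[k] + a * (0.5 + np.arange(nxyz[k])) for k in range(3)]
    G = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    G = G + rng.uniform(-0.15 * a, 0.15 * a, G.shape)

    inside = _geom.points_in_surface(surface.vertices, surface.faces, G)
    G = G[inside]
    dist = _geom.distance_to_facets(G, surface.vertices, surface.faces)
    G = G[dist > 0.55 * a]

    # spine seeding keeps the thin inlet/outlet tubes well filled and, along
    # the cavity long axis, guarantees interior nodes near the tapering apex
    # (otherwise whole cell patches have every vertex on the wall, which
    # leaves the discrete divergence constraint locally infeasible)
    spines = []
    cav: CavityParams | None = (surface.metadata or {}).get("cavity_params")
    if cav is not None:
        zs = np.arange(-cav.long_axis_length + 0.35 * a, -0.3 * a, 0.6 * a)
        for z in zs:
            spines.append(np.array([0.0, 0.0, z]))
    for side in ((surface.metadata or {}).get("valve_planes") or {}).values():
        c = np.asarray(side["centre"])
        ax = np.asarray(side["axis"])
        r, lt = side["radius"], side["tube_length"]
        # start below the orifice plane (breaks the exactly cocircular,
        # coplanar ring configurations that otherwise produce flat tets
        # spanning the orifice disk) and end just under the cap so the cap
        # cells keep free interior nodes
        ts = np.arange(-0.3 * a, lt - 0.45 * a, 0.5 * a)
        ts = np.append(ts, lt - 0.45 * a)
        level = [np.zeros(3)]
        for frac in (0.4, 0.75):
            rad = frac * r
            if rad < r - 0.35 * a and rad > 0.3 * a:
                ang = 2 * np.pi * np.arange(8) / 8 + frac
                level += [np.array([rad * np.cos(t), rad * np.sin(t), 0.0])
                          for t in ang]
        for t in ts:
            for off in level:
                spines.append(c + t * ax + off)
    if spines:
        S = np.asarray(spines)
        S += rng.uniform(-0.05 * a, 0.05 * a, S.shape)
        ok = _geom.points_in_surface(surface.vertices, surface.faces, S)
        S = S[ok]
        dS = _geom.distance_to_facets(S, surface.vertices, surface.faces)
        S = S[dS > 0.3 * a]
        if len(S):
            # spine seeds take precedence; drop lattice seeds too close to
            # them (near-coincident seeds degrade the Delaunay badly)
            if len(G):
                near = cKDTree(S).query_ball_point(G, 0.45 * a)
                G = G[[len(n) == 0 for n in near]]
            G = np.vstack([G, S]) if len(G) else S

    pts = [surface.vertices, G]
    if near_wall_refinement > 1.0:
        areas, normals = _geom.triangle_areas_normals(surface.vertices,
                                                      surface.faces)
        delta = a / (2.0 * near_wall_refinement)
        off = surface.vertices[surface.faces].mean(axis=1) - delta * normals
        ok = _geom.points_in_surface(surface.vertices, surface.faces, off)
        off = off[ok]
        if len(off):
            d2 = _geom.distance_to_facets(off, surface.vertices, surface.faces)
            off = off[(d2 > 0.3 * delta)]
            pts.insert(1, off)
    points = np.vstack(pts)

    def _triangulate(pts_arr):
        tri = Delaunay(pts_arr)
        cc = orient_cells_positive(pts_arr, tri.simplices.astype(np.int64))
        cent = pts_arr[cc].mean(axis=1)
        keep = _geom.points_in_surface(surface.vertices, surface.faces, cent)
        if keep.any():
            vv = _geom.simplex_volumes(pts_arr, cc)
            keep &= vv > 1e-9 * np.median(vv[keep])
        return cc[keep]

    cells = _triangulate(points)

    # Delaunay refinement against chord slivers: tets whose vertices all lie
    # on nearly-flat surface patches can be almost degenerate; inserting a
    # point slightly inward of each flat cell breaks its (enormous)
    # circumsphere.  Insertion can create fresh degeneracies elsewhere, so
    # the best configuration seen (by worst-cell flatness) is kept.
    def _flatness(pp, cc):
        hh = _geom.cell_min_heights(pp, cc)
        return hh.min() / np.median(hh)

    best = (points, cells, _flatness(points, cells))
    for _ in range(3):
        hh = _geom.cell_min_heights(points, cells)
        flat = hh < 0.08 * np.median(hh)
        if not flat.any():
            break
        fc = points[cells[flat]]
        nrm = np.cross(fc[:, 1] - fc[:, 0], fc[:, 2] - fc[:, 0])
        nrm /= np.maximum(np.linalg.norm(nrm, axis=1), 1e-300)[:, None]
        centres = fc.mean(axis=1)
        cand = np.concatenate([centres + 0.35 * a * nrm,
                               centres - 0.35 * a * nrm])
        ok = _geom.points_in_surface(surface.vertices, surface.faces, cand)
        cand = cand[ok]
        if len(cand):
            dC = _geom.distance_to_facets(cand, surface.vertices,
                                          surface.faces)
            cand = cand[dC > 0.25 * a]
        if len(cand) == 0:
            break
        near = cKDTree(points).query_ball_point(cand, 0.3 * a)
        cand = cand[[len(nn) == 0 for nn in near]]
        if len(cand) == 0:
            break
        points = np.vstack([points, cand])
        cells = _triangulate(points)
        score = _flatness(points, cells)
        if score > best[2]:
            best = (points, cells, score)
    points, cells, _ = best

    # last resort: remove any cell still flatter than 5% of the median
    # altitude (such cells would throttle the explicit diffusive step bound).
    # This can leave sub-cell-thin internal voids; their exposed facets are
    # flagged below so wall statistics and layer distances ignore them, while
    # the solver simply sees a no-slip flake of negligible size.
    h_all = _geom.cell_min_heights(points, cells)
    cells = cells[h_all > 0.05 * np.median(h_all)]

    # prune flat boundary slivers (they control the explicit stable step);
    # the volume guard restricts pruning to genuinely degenerate cells so
    # the covered volume is preserved, and only boundary-connected cells are
    # ever removed (no interior voids)
    for _ in range(12):
        if quality_floor <= 0 or not len(cells):
            break
        q = _tet_quality(points, cells)
        vols_now = _geom.simplex_volumes(points, cells)
        vmed = np.median(vols_now)
        bfaces, owners = _geom.boundary_facets(cells)
        bad = np.zeros(len(cells), dtype=bool)
        bad[owners] = True
        bad &= (q < quality_floor) & (vols_now < 0.1 * vmed)
        if not bad.any():
            break
        cells = cells[~bad]

    # drop unused points and renumber
    used = np.unique(cells)
    remap = -np.ones(len(points), dtype=np.int64)
    remap[used] = np.arange(len(used))
    points = points[used]
    cells = remap[cells]

    bfaces, _ = _geom.boundary_facets(cells)
    n_surf = len(surface.vertices)
    cat = np.zeros(n_surf, dtype=np.int64)  # 0 wall, 1 inlet, 2 outlet
    cat[np.unique(surface.faces[surface.face_labels == LBL_INLET_CAP])] = INLET
    cat[np.unique(surface.faces[surface.face_labels == LBL_OUTLET_CAP])] = OUTLET
    old_of_new = used                        # new point index -> original index
    tags = np.full(len(bfaces), WALL, dtype=np.int64)
    bv_old = old_of_new[bfaces]              # (k, 3) original point indices
    on_surface = (bv_old < n_surf).all(axis=1)
    bv_cat = cat[np.clip(bv_old, 0, n_surf - 1)]
    for tag in (INLET, OUTLET):
        tags[on_surface & (bv_cat == tag).all(axis=1)] = tag
    # geometric fallback: faces on a cap plane whose normal aligns with the
    # tube axis (covers facets re-exposed by sliver pruning)
    planes = (surface.metadata or {}).get("valve_planes") or {}
    if planes:
        fareas, fnormals = _geom.triangle_areas_normals(points, bfaces)
        fc = points[bfaces].mean(axis=1)
        for name, tag in (("inlet", INLET), ("outlet", OUTLET)):
            side = planes.get(name)
            if side is None:
                continue
            c = np.asarray(side["centre"]) + side["tube_length"] * \
                np.asarray(side["axis"])
            ax = np.asarray(side["axis"])
            plane_d = np.abs((fc - c) @ ax)
            lateral = np.linalg.norm(fc - c - ((fc - c) @ ax)[:, None] * ax,
                                     axis=1)
            aligned = np.abs(fnormals @ ax) > 0.7
            tags[(plane_d < 0.9 * a) & (lateral < 1.1 * side["radius"])
                 & aligned] = tag

    # facets on the true domain boundary vs facets exposed by removing
    # degenerate cells (the latter are excluded from wall statistics and
    # layer-distance fields)
    fc_b = points[bfaces].mean(axis=1)
    d_b = _geom.distance_to_facets(fc_b, surface.vertices, surface.faces)
    genuine = d_b < 0.35 * a

    mesh = VolumeMesh(points, cells, bfaces, tags,
                      metadata=dict(surface.metadata),
                      boundary_genuine=genuine)
    mesh.validate(volume_band=volume_band)
    return mesh


# ---------------------------------------------------------------------------
# Porous layer tagging
# ---------------------------------------------------------------------------

def tag_porous_layer(mesh: VolumeMesh, thickness: float,
                     vestibule_factor: float = 1.3) -> VolumeMesh:
    """Tag cells whose centroid lies within ``thickness`` of a wall facet.

    Inlet/outlet tube cells (centroids beyond a valve plane) are never
    tagged, and neither are cells within ``vestibule_factor`` times the
    orifice radius of either valve axis: the sub-valvular vestibules and
    the outflow tract are anatomically smooth, and a porous collar across
    an orifice would throttle the through-flow instead of emulating wall
    trabeculation.  Requires valve-plane metadata for these exclusions.
    Returns a new mesh; the input is untouched.
    """
    if thickness < 0:
        raise GeometryError("thickness must be >= 0")
    region = np.full(len(mesh.cells), FLUID, dtype=np.int64)
    out = VolumeMesh(mesh.vertices, mesh.cells, mesh.boundary_faces,
                     mesh.boundary_tags, region, dict(mesh.metadata),
                     mesh.node_dof)
    if thickness == 0:
        return out
    wall_faces = mesh.boundary_faces[(mesh.boundary_tags == WALL)
                                     & mesh.boundary_genuine]
    if len(wall_faces) == 0:
        return out
    cent = mesh.cell_centroids()
    dist = _geom.distance_to_facets(cent, mesh.vertices, wall_faces)
    porous = dist <= thickness
    planes = (mesh.metadata or {}).get("valve_planes") or {}
    for side in planes.values():
        c = np.asarray(side["centre"])
        ax = np.asarray(side["axis"])
        s = (cent - c) @ ax
        lateral = np.linalg.norm(cent - c - s[:, None] * ax, axis=1)
        in_tube = (s > 1e-12) & (lateral <= 1.2 * side["radius"])
        vestibule = (s > -2.0 * thickness) \
            & (lateral <= vestibule_factor * side["radius"])
        porous &= ~(in_tube | vestibule)
    region[porous] = POROUS
    out.cell_region = region
    return out
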