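"""Mesh containers and structured generators.

Two containers cover the pipeline: :class:`SurfaceMesh` for closed, labelled
triangulated endocardial surfaces and :class:`VolumeMesh` for the simplex
fluid domain (triangles in 2D, tetrahedra in 3D) with tagged boundary facets
and an optional porous cell region.  Structured generators for rectangles
(with periodic pairing) and boxes back the solver validation cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from . import _geom

# Boundary facet tags
WALL, INLET, OUTLET = 0, 1, 2
TAG_NAMES = {WALL: "wall", INLET: "inlet", OUTLET: "outlet"}

# Cell regions
FLUID, POROUS = 0, 1

# Surface face labels
LBL_WALL = "wall"
LBL_INLET_CAP = "inlet_cap"
LBL_OUTLET_CAP = "outlet_cap"
LBL_INLET_TUBE = "inlet_tube"
LBL_OUTLET_TUBE = "outlet_tube"
SURFACE_LABELS = (LBL_WALL, LBL_INLET_CAP, LBL_OUTLET_CAP,
                  LBL_INLET_TUBE, LBL_OUTLET_TUBE)


class MeshError(ValueError):
    """Raised when a mesh violates its structural invariants."""


@dataclass
class SurfaceMesh:
    """Closed triangulated surface with per-face labels (SI meters)."""

    vertices: np.ndarray          # (n, 3) float
    faces: np.ndarray             # (m, 3) int
    face_labels: np.ndarray       # (m,) unicode, values in SURFACE_LABELS
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.face_labels = np.asarray(self.face_labels)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               process=False)

    @property
    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    @property
    def euler_characteristic(self) -> int:
        return int(self.to_trimesh().euler_number)

    def volume(self) -> float:
        """Enclosed volume by the divergence theorem (outward orientation)."""
        return float(self.to_trimesh().volume)

    def face_areas(self) -> np.ndarray:
        areas, _ = _geom.triangle_areas_normals(self.vertices, self.faces)
        return areas

    def subset(self, labels) -> "SurfaceMesh":
        """Faces whose label is in ``labels``; vertex array is shared."""
        keep = np.isin(self.face_labels, list(labels))
        return SurfaceMesh(self.vertices, self.faces[keep],
                           self.face_labels[keep], dict(self.metadata))

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.faces.copy(),
                           self.face_labels.copy(), dict(self.metadata))

    def validate(self) -> None:
        bad = ~np.isin(self.face_labels, SURFACE_LABELS)
        if bad.any():
            raise MeshError(f"unknown face labels: {set(self.face_labels[bad])}")
        if len(self.faces) != len(self.face_labels):
            raise MeshError("face_labels length does not match faces")
        areas = self.face_areas()
        if (areas <= 0).any() or not np.isfinite(areas).all():
            raise MeshError("degenerate (zero-area) faces present")
        tm = self.to_trimesh()
        if not tm.is_watertight:
            raise MeshError("surface is not watertight")
        if tm.volume <= 0:
            raise MeshError("surface orientation is inward (negative volume)")


@dataclass
class VolumeMesh:
    """Simplex fluid domain with tagged boundary facets.

    ``node_dof`` maps mesh nodes to solver degrees of freedom; it differs from
    the identity only for periodic meshes, where paired nodes share a DOF.
    """

    vertices: np.ndarray          # (n, dim)
    cells: np.ndarray             # (m, dim+1)
    boundary_faces: np.ndarray    # (k, dim) vertex indices
    boundary_tags: np.ndarray     # (k,) int in {WALL, INLET, OUTLET}
    cell_region: np.ndarray = None  # (m,) int in {FLUID, POROUS}
    metadata: dict = field(default_factory=dict)
    node_dof: np.ndarray = None   # (n,) int -> dof index
    boundary_genuine: np.ndarray = None  # (k,) bool: facet lies on the true
    # domain boundary (False marks facets exposed by degenerate-cell removal)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.cells = np.asarray(self.cells, dtype=np.int64)
        self.boundary_faces = np.asarray(self.boundary_faces, dtype=np.int64)
        self.boundary_tags = np.asarray(self.boundary_tags, dtype=np.int64)
        if self.cell_region is None:
            self.cell_region = np.zeros(len(self.cells), dtype=np.int64)
        if self.node_dof is None:
            self.node_dof = np.arange(len(self.vertices), dtype=np.int64)
        if self.boundary_genuine is None:
            self.boundary_genuine = np.ones(len(self.boundary_faces),
                                            dtype=bool)
        else:
            self.boundary_genuine = np.asarray(self.boundary_genuine,
                                               dtype=bool)

    @property
    def dim(self) -> int:
        return self.vertices.shape[1]

    @property
    def n_dofs(self) -> int:
        return int(self.node_dof.max()) + 1 if len(self.node_dof) else 0

    def cell_volumes(self) -> np.ndarray:
        return _geom.simplex_volumes(self.vertices, self.cells)

    def cell_centroids(self) -> np.ndarray:
        return self.vertices[self.cells].mean(axis=1)

    def boundary_face_areas_normals(self):
        """Measures and outward unit normals of the boundary facets."""
        if self.dim == 3:
            areas, normals = _geom.triangle_areas_normals(
                self.vertices, self.boundary_faces)
        else:
            p = self.vertices[self.boundary_faces]
            t = p[:, 1] - p[:, 0]
            areas = np.linalg.norm(t, axis=1)
            normals = np.stack([t[:, 1], -t[:, 0]], axis=1)
            normals /= np.maximum(areas, 1e-300)[:, None]
        # orient outward using the owning cells
        _, owners = _geom.boundary_facets(self.cells)
        cent = self.cell_centroids()
        fc = self.vertices[self.boundary_faces].mean(axis=1)
        owner_of = self._match_owners(owners)
        out = fc - cent[owner_of]
        flip = np.einsum("ij,ij->i", out, normals) < 0
        normals[flip] *= -1
        return areas, normals

    def _match_owners(self, owners=None) -> np.ndarray:
        """Owning cell index for each boundary facet, by sorted-vertex key."""
        facets, own = _geom.boundary_facets(self.cells)
        key = {tuple(f): o for f, o in zip(np.sort(facets, axis=1).tolist(),
                                           own.tolist())}
        try:
            return np.array(
                [key[tuple(f)] for f in np.sort(self.boundary_faces, axis=1).tolist()],
                dtype=np.int64)
        except KeyError as exc:
            raise MeshError("boundary_faces do not match the cell boundary") from exc

    def boundary_owner_cells(self) -> np.ndarray:
        return self._match_owners()

    def validate(self, volume_band=None) -> None:
        vols = self.cell_volumes()
        if (vols <= 0).any():
            raise MeshError(f"{int((vols <= 0).sum())} non-positive cell volumes")
        periodic = self.n_dofs < len(self.vertices)
        facets, _ = _geom.boundary_facets(self.cells)
        if not periodic and len(facets) != len(self.boundary_faces):
            # periodic meshes keep geometric facets on the identified sides,
            # which are interior as far as the DOF topology is concerned
            raise MeshError(
                f"boundary tags do not partition the boundary: "
                f"{len(self.boundary_faces)} tagged vs {len(facets)} geometric facets")
        self._match_owners()
        if volume_band is not None:
            lo, hi = volume_band
            if vols.min() < lo or vols.max() > hi:
                raise MeshError(
                    f"cell volumes [{vols.min():.3e}, {vols.max():.3e}] outside "
                    f"the configured band [{lo:.3e}, {hi:.3e}]")


def orient_cells_positive(vertices, cells):
    """Swap two vertices of negatively oriented simplices in place."""
    vols = _geom.simplex_volumes(vertices, cells)
    neg = vols < 0
    cells[neg, 0], cells[neg, 1] = cells[neg, 1].copy(), cells[neg, 0].copy()
    return cells


# ---------------------------------------------------------------------------
# Structured generators (solver validation fixtures)
# ---------------------------------------------------------------------------

def rectangle_grid(nx: int, ny: int, lx: float, ly: float,
                   periodic_x: bool = False, periodic_y: bool = False,
                   origin=(0.0, 0.0),
                   tag_left=INLET, tag_right=OUTLET,
                   tag_bottom=WALL, tag_top=WALL) -> VolumeMesh:
    """Structured crossed-triangle rectangle mesh with optional periodicity."""
    xs = np.linspace(origin[0], origin[0] + lx, nx + 1)
    ys = np.linspace(origin[1], origin[1] + ly, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    verts = np.stack([X.ravel(), Y.ravel()], axis=1)

    def vid(i, j):
        return i * (ny + 1) + j

    cells = []
    for i in range(nx):
        for j in range(ny):
            a, b = vid(i, j), vid(i + 1, j)
            c, d = vid(i + 1, j + 1), vid(i, j + 1)
            if (i + j) % 2 == 0:
                cells += [[a, b, c], [a, c, d]]
            else:
                cells += [[a, b, d], [b, c, d]]
    cells = np.array(cells, dtype=np.int64)

    bfaces, btags = [], []
    if not periodic_x:
        for j in range(ny):
            bfaces.append([vid(0, j), vid(0, j + 1)]); btags.append(tag_left)
            bfaces.append([vid(nx, j), vid(nx, j + 1)]); btags.append(tag_right)
    if not periodic_y:
        for i in range(nx):
            bfaces.append([vid(i, 0), vid(i + 1, 0)]); btags.append(tag_bottom)
            bfaces.append([vid(i, ny), vid(i + 1, ny)]); btags.append(tag_top)

    node_dof = np.arange(len(verts), dtype=np.int64)
    if periodic_x:
        for j in range(ny + 1):
            node_dof[vid(nx, j)] = node_dof[vid(0, j)]
    if periodic_y:
        for i in range(nx + 1):
            node_dof[vid(i, ny)] = node_dof[vid(i, 0)]
    # compress dof numbering
    uniq, node_dof = np.unique(node_dof, return_inverse=True)

    mesh = VolumeMesh(verts, cells,
                      np.array(bfaces, dtype=np.int64).reshape(-1, 2),
                      np.array(btags, dtype=np.int64),
                      node_dof=node_dof.astype(np.int64))
    if bfaces:
        mesh.validate()
    return mesh


def box_tets(n: tuple, lengths: tuple, origin=(0.0, 0.0, 0.0)) -> VolumeMesh:
    """Structured Kuhn (6 tets per cube) box mesh; all boundary tagged wall."""
    nx, ny, nz = n
    lx, ly, lz = lengths
    xs = np.linspace(origin[0], origin[0] + lx, nx + 1)
    ys = np.linspace(origin[1], origin[1] + ly, ny + 1)
    zs = np.linspace(origin[2], origin[2] + lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    verts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def vid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    I, J, K = I.ravel(), J.ravel(), K.ravel()
    c000 = vid(I, J, K)
    c100 = vid(I + 1, J, K)
    c010 = vid(I, J + 1, K)
    c001 = vid(I, J, K + 1)
    c110 = vid(I + 1, J + 1, K)
    c101 = vid(I + 1, J, K + 1)
    c011 = vid(I, J + 1, K + 1)
    c111 = vid(I + 1, J + 1, K + 1)
    # Kuhn triangulation along the 6 monotone paths 000 -> 111
    paths = [
        (c000, c100, c110, c111),
        (c000, c100, c101, c111),
        (c000, c010, c110, c111),
        (c000, c010, c011, c111),
        (c000, c001, c101, c111),
        (c000, c001, c011, c111),
    ]
    cells = np.concatenate([np.stack(p, axis=1) for p in paths], axis=0)
    cells = orient_cells_positive(verts, cells.astype(np.int64))
    bfaces, _ = _geom.boundary_facets(cells)
    mesh = VolumeMesh(verts, cells, bfaces,
                      np.full(len(bfaces), WALL, dtype=np.int64))
    return mesh
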