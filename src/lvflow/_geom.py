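"""Low-level simplex geometry kernels shared by the meshing, solver and analysis layers.

Everything here operates on raw numpy arrays (vertices, connectivity) so the
higher-level containers stay thin.  All routines are vectorised over cells.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

# Quadrature rules on the reference simplex, exact for polynomials of degree 2.
# Rows are barycentric coordinates, weights sum to 1.
_TRI_Q2_BARY = np.array(
    [[0.5, 0.5, 0.0], [0.0, 0.5, 0.5], [0.5, 0.0, 0.5]]
)
_TRI_Q2_W = np.full(3, 1.0 / 3.0)

_TET_A = 0.5854101966249685
_TET_B = 0.1381966011250105
_TET_Q2_BARY = np.array(
    [
        [_TET_A, _TET_B, _TET_B, _TET_B],
        [_TET_B, _TET_A, _TET_B, _TET_B],
        [_TET_B, _TET_B, _TET_A, _TET_B],
        [_TET_B, _TET_B, _TET_B, _TET_A],
    ]
)
_TET_Q2_W = np.full(4, 0.25)


def quadrature_degree2(dim: int):
    """Barycentric points and weights integrating degree-2 polynomials exactly."""
    if dim == 2:
        return _TRI_Q2_BARY, _TRI_Q2_W
    if dim == 3:
        return _TET_Q2_BARY, _TET_Q2_W
    raise ValueError(f"unsupported dimension {dim}")


def simplex_volumes(vertices: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """Signed volumes (areas in 2D) of simplices."""
    x = vertices[cells]
    edges = x[:, 1:, :] - x[:, :1, :]
    dim = vertices.shape[1]
    det = np.linalg.det(edges)
    return det / (2.0 if dim == 2 else 6.0)


def shape_gradients(vertices: np.ndarray, cells: np.ndarray):
    """P1 shape-function gradients and cell volumes.

    Returns ``(grads, vols)`` with ``grads`` of shape ``(n_cells, dim+1, dim)``:
    the constant gradient of each barycentric basis function on each cell.
    """
    dim = vertices.shape[1]
    x = vertices[cells]
    edges = x[:, 1:, :] - x[:, :1, :]          # (m, dim, dim), row k = x_k - x_0
    det = np.linalg.det(edges)
    vols = det / (2.0 if dim == 2 else 6.0)
    inv = np.linalg.inv(edges)                 # columns of inv are grad(lambda_k)
    g = np.swapaxes(inv, 1, 2)                 # (m, dim, dim): row k = grad lambda_{k+1}
    g0 = -g.sum(axis=1, keepdims=True)
    return np.concatenate([g0, g], axis=1), vols


def cell_min_heights(vertices: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """Smallest altitude of each simplex: dim * V / max facet measure.

    Equivalently 1/max|grad lambda_k|, which is what the explicit time-step
    bound actually sees through the P1 gradients.
    """
    grads, _ = shape_gradients(vertices, cells)
    gmax = np.linalg.norm(grads, axis=2).max(axis=1)
    return 1.0 / gmax


def triangle_areas_normals(vertices: np.ndarray, faces: np.ndarray):
    """Areas and unit normals of 3D triangles (normal by right-hand winding)."""
    p = vertices[faces]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    nn = np.linalg.norm(n, axis=1)
    areas = 0.5 * nn
    unit = np.zeros_like(n)
    ok = nn > 0
    unit[ok] = n[ok] / nn[ok, None]
    return areas, unit


def boundary_facets(cells: np.ndarray):
    """Facets of a simplex mesh that belong to exactly one cell.

    Returns ``(facets, owner_cells)`` where ``facets`` is ``(k, dim)`` of
    vertex indices (original local orientation) and ``owner_cells`` the index
    of the unique cell owning each facet.
    """
    m, npc = cells.shape
    local = [np.delete(np.arange(npc), i) for i in range(npc)]
    all_faces = np.concatenate([cells[:, li] for li in local], axis=0)
    owners = np.tile(np.arange(m), npc)
    key = np.sort(all_faces, axis=1)
    order = np.lexsort(key.T[::-1])
    key_s = key[order]
    uniq = np.ones(len(key_s), dtype=bool)
    dup = (key_s[1:] == key_s[:-1]).all(axis=1)
    uniq[1:] &= ~dup
    uniq[:-1] &= ~dup
    sel = order[uniq]
    return all_faces[sel], owners[sel]


# ---------------------------------------------------------------------------
# Point-in-surface parity test (3D closed triangulated surface)
# ---------------------------------------------------------------------------

def points_in_surface(vertices: np.ndarray, faces: np.ndarray,
                      points: np.ndarray) -> np.ndarray:
    """Parity ray test: which ``points`` lie inside the closed surface.

    Casts rays along +z and counts crossings; a 2D grid over (x, y) keeps the
    candidate triangle lists short.  Ray origins are shifted by a tiny fixed
    irrational offset so rays generically miss triangle edges.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return np.zeros(0, dtype=bool)
    tri = vertices[faces]                                    # (f, 3, 3)
    scale = max(float(np.ptp(vertices, axis=0).max()), 1e-300)
    eps = np.array([1e-9 * (0.5 + 1 / np.pi), 1e-9 * (0.5 + 1 / np.e)]) * scale
    q = pts[:, :2] + eps

    lo = tri[:, :, :2].min(axis=1)
    hi = tri[:, :, :2].max(axis=1)
    gmin = np.minimum(lo.min(axis=0), q.min(axis=0)) - 1e-9 * scale
    gmax = np.maximum(hi.max(axis=0), q.max(axis=0)) + 1e-9 * scale
    ncell = int(np.clip(np.sqrt(len(faces)), 8, 96))
    width = np.maximum(gmax - gmin, 1e-300)

    def cell_of(xy):
        c = np.floor((xy - gmin) / width * ncell).astype(int)
        return np.clip(c, 0, ncell - 1)

    clo, chi = cell_of(lo), cell_of(hi)
    buckets: dict[tuple, list] = {}
    for fi in range(len(faces)):
        for cx in range(clo[fi, 0], chi[fi, 0] + 1):
            for cy in range(clo[fi, 1], chi[fi, 1] + 1):
                buckets.setdefault((cx, cy), []).append(fi)

    pc = cell_of(q)
    keys, inverse = np.unique(pc, axis=0, return_inverse=True)
    inside = np.zeros(len(pts), dtype=bool)
    for ki, key in enumerate(map(tuple, keys)):
        fidx = buckets.get(key)
        sel = np.nonzero(inverse == ki)[0]
        if not fidx:
            continue
        t = tri[fidx]                                        # (F, 3, 3)
        a2, b2, c2 = t[:, 0, :2], t[:, 1, :2], t[:, 2, :2]
        p2 = q[sel]                                          # (P, 2)
        v0 = b2 - a2
        v1 = c2 - a2
        den = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]      # (F,)
        good = np.abs(den) > 1e-300
        d = np.where(good, den, 1.0)
        w = p2[:, None, :] - a2[None, :, :]                  # (P, F, 2)
        u = (w[:, :, 0] * v1[None, :, 1] - w[:, :, 1] * v1[None, :, 0]) / d
        v = (v0[None, :, 0] * w[:, :, 1] - v0[None, :, 1] * w[:, :, 0]) / d
        hit = good[None, :] & (u >= 0) & (v >= 0) & (u + v <= 1)
        z = (t[None, :, 0, 2]
             + u * (t[None, :, 1, 2] - t[None, :, 0, 2])
             + v * (t[None, :, 2, 2] - t[None, :, 0, 2]))
        above = hit & (z > pts[sel, None, 2])
        inside[sel] = (above.sum(axis=1) % 2).astype(bool)
    return inside


# ---------------------------------------------------------------------------
# Point-to-facet distances (KD-tree prefiltered, exact on the candidates)
# ---------------------------------------------------------------------------

def _point_triangle_dist(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact distances between paired points ``p (n,3)`` and triangles ``tri (n,3,3)``."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    closest = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def assign(mask, pts):
        m = mask & ~done
        closest[m] = pts[m] if pts.shape == p.shape else pts
        done[m] = True

    assign((d1 <= 0) & (d2 <= 0), a)
    assign((d3 >= 0) & (d4 <= d3), b)
    assign((d6 >= 0) & (d5 <= d6), c)

    vc = d1 * d4 - d3 * d2
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0) & ~done
    t = np.where(np.abs(d1 - d3) > 0, d1 / np.where(d1 - d3 == 0, 1.0, d1 - d3), 0.0)
    closest[m] = a[m] + t[m, None] * ab[m]
    done |= m

    vb = d5 * d2 - d1 * d6
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0) & ~done
    t = np.where(np.abs(d2 - d6) > 0, d2 / np.where(d2 - d6 == 0, 1.0, d2 - d6), 0.0)
    closest[m] = a[m] + t[m, None] * ac[m]
    done |= m

    va = d3 * d6 - d5 * d4
    m = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0) & ~done
    den = (d4 - d3) + (d5 - d6)
    t = np.where(den != 0, (d4 - d3) / np.where(den == 0, 1.0, den), 0.0)
    closest[m] = b[m] + t[m, None] * (c - b)[m]
    done |= m

    m = ~done
    den = np.where(va + vb + vc == 0, 1.0, va + vb + vc)
    v = vb / den
    w = vc / den
    closest[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return np.linalg.norm(p - closest, axis=1)


def _point_segment_dist(p: np.ndarray, seg: np.ndarray) -> np.ndarray:
    a, b = seg[:, 0], seg[:, 1]
    ab = b - a
    t = np.einsum("ij,ij->i", p - a, ab) / np.maximum(
        np.einsum("ij,ij->i", ab, ab), 1e-300)
    t = np.clip(t, 0.0, 1.0)
    return np.linalg.norm(p - (a + t[:, None] * ab), axis=1)


def distance_to_facets(points: np.ndarray, vertices: np.ndarray,
                       facets: np.ndarray, k: int = 12) -> np.ndarray:
    """Distance from each point to the nearest facet (triangle or segment).

    The ``k`` nearest facets by centroid are examined exactly; with roughly
    uniform facet sizes this matches the true distance.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) == 0:
        return np.zeros(0)
    fac = vertices[facets]
    cent = fac.mean(axis=1)
    k = min(k, len(facets))
    _, idx = cKDTree(cent).query(pts, k=k)
    if k == 1:
        idx = idx[:, None]
    best = np.full(len(pts), np.inf)
    for j in range(idx.shape[1]):
        cand = fac[idx[:, j]]
        if facets.shape[1] == 3:
            d = _point_triangle_dist(pts, cand)
        else:
            d = _point_segment_dist(pts, cand)
        best = np.minimum(best, d)
    return best


# ---------------------------------------------------------------------------
# Marching tetrahedra isosurface area
# ---------------------------------------------------------------------------

def marching_tets_area(vertices: np.ndarray, cells: np.ndarray,
                       node_values: np.ndarray, threshold: float) -> float:
    """Area of the ``node_values == threshold`` isosurface over a tet mesh.

    Linear interpolation per tetrahedron; open sheets clipped by the domain
    boundary are counted single-sided.
    """
    vals = node_values[cells]                                # (m, 4)
    mask = vals >= threshold
    cnt = mask.sum(axis=1)
    area = 0.0

    def edge_cross(pa, va, pb, vb):
        t = (threshold - va) / (vb - va)
        return pa + t[:, None] * (pb - pa)

    def tri_area(p0, p1, p2):
        return 0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1)

    x = vertices[cells]                                      # (m, 4, 3)
    for lone_inside in (True, False):
        sel = np.nonzero(cnt == (1 if lone_inside else 3))[0]
        if len(sel) == 0:
            continue
        m_sel = mask[sel] if lone_inside else ~mask[sel]
        lone = np.argmax(m_sel, axis=1)
        others = np.array([np.delete(np.arange(4), i) for i in lone])
        r = np.arange(len(sel))
        pl = x[sel, lone]
        vl = vals[sel, lone]
        crossings = [
            edge_cross(pl, vl, x[sel][r, others[:, j]], vals[sel][r, others[:, j]])
            for j in range(3)
        ]
        area += tri_area(*crossings).sum()

    sel = np.nonzero(cnt == 2)[0]
    if len(sel):
        order = np.argsort(~mask[sel], axis=1, kind="stable")
        r = np.arange(len(sel))
        ia, ib = order[:, 0], order[:, 1]
        oc, od = order[:, 2], order[:, 3]
        pa, pb = x[sel][r, ia], x[sel][r, ib]
        pc, pd = x[sel][r, oc], x[sel][r, od]
        va, vb = vals[sel][r, ia], vals[sel][r, ib]
        vc, vd = vals[sel][r, oc], vals[sel][r, od]
        q_ac = edge_cross(pa, va, pc, vc)
        q_ad = edge_cross(pa, va, pd, vd)
        q_bd = edge_cross(pb, vb, pd, vd)
        q_bc = edge_cross(pb, vb, pc, vc)
        area += tri_area(q_ac, q_ad, q_bd).sum()
        area += tri_area(q_ac, q_bd, q_bc).sum()
    return float(area)
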