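"""Hemodynamic outcome metrics computed from transient run records.

Implements the analysis pipeline applied to each simulated ventricle:

* Freedman-Diaconis histograms (unit area; mode = centre of the peak bin);
* the intra-ventricular pressure drop as the difference between the inlet and
  outlet pressure histogram modes, sampled in 15 mm tube sub-volumes and
  averaged over the last frames of the run;
* wall shear stress (tangential viscous traction magnitude, 2 mu S(u) n) per
  wall boundary face, summarised by FD histogram, mode, median and maximum
  with tube walls excluded from the cavity statistics;
* the Q-criterion Q = (||W||_F^2 - ||S||_F^2) / 2 per cell and the total
  vortex surface, the area of the Q = threshold isosurface extracted by
  marching tetrahedra on the node-averaged field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _geom
from .anatomy import FluidProperties
from .meshes import VolumeMesh, WALL
from .solver import FlowState, NavierStokesSolver, RunRecord


class AnalysisError(ValueError):
    """Raised for inconsistent analysis inputs."""


@dataclass
class Histogram:
    bin_edges: np.ndarray
    density: np.ndarray
    n_samples: int
    bin_width: float
    mode_value: float
    median_value: float


def fd_histogram(samples) -> Histogram:
    """Unit-area histogram with the Freedman-Diaconis bin width.

    ``bin_width = 2 IQR n^(-1/3)`` with linear-interpolation quantiles; the
    mode is the centre of the highest-density bin, ties broken toward the
    lower bin.  A zero IQR degenerates to a single bin.
    """
    x = np.asarray(samples, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise AnalysisError(f"need at least 2 samples, got {n}")
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    median = float(np.median(x))
    span = float(x.max() - x.min())
    scale = max(float(np.abs(x).max()), 1.0)
    if iqr <= 0 or span < 1e-12 * scale:
        # (near-)identical samples: a delta-like single bin whose nominal
        # width stays representable (a subnormal span would overflow 1/width)
        width = max(span, 1e-12 * scale)
        edges = np.array([x.min(), x.min() + width])
        width = float(edges[1] - edges[0])       # realised width after rounding
        density = np.array([1.0 / width])
        return Histogram(edges, density, n, width, float(x.mean()), median)
    width = 2.0 * iqr * n ** (-1.0 / 3.0)
    nbins = max(1, int(np.ceil((x.max() - x.min()) / width)))
    if nbins > 100_000:
        # pathologically heavy-tailed samples: cap the bin count and widen
        nbins = 100_000
        width = (x.max() - x.min()) / nbins
    edges = x.min() + width * np.arange(nbins + 1)
    edges[-1] = max(edges[-1], x.max())          # guard float rounding
    density, edges = np.histogram(x, bins=edges, density=True)
    # ties (to within rounding) break toward the lower bin
    mode_bin = int(np.argmax(density >= density.max() * (1 - 1e-12)))
    mode = 0.5 * (edges[mode_bin] + edges[mode_bin + 1])
    return Histogram(edges, density, n, width, float(mode), median)


def pressure_drop(record: RunRecord, window_frames: int = 10,
                  inlet_probe: str = "inlet", outlet_probe: str = "outlet"):
    """Mean and SD of the per-frame mode pressure difference, in kPa.

    Per frame, dP = mode(P_in) - mode(P_out) from the FD histograms of the
    tube sub-volume samples; the returned statistics are over the last
    ``window_frames`` frames.
    """
    for name in (inlet_probe, outlet_probe):
        if name not in record.probe_pressures:
            raise AnalysisError(
                f"run record has no probe {name!r}; available: "
                f"{sorted(record.probe_pressures)}")
    n = len(record.probe_pressures[inlet_probe])
    if n < window_frames:
        raise AnalysisError(
            f"need at least {window_frames} frames for the averaging window, "
            f"run record has {n}")
    dps = []
    for i in range(n - window_frames, n):
        m_in = fd_histogram(record.probe_pressures[inlet_probe][i]).mode_value
        m_out = fd_histogram(record.probe_pressures[outlet_probe][i]).mode_value
        dps.append(m_in - m_out)
    dps = np.asarray(dps) / 1000.0               # Pa -> kPa
    return float(dps.mean()), float(dps.std())


def _tube_face_mask(mesh: VolumeMesh, face_centroids: np.ndarray) -> np.ndarray:
    """True for faces in the tube regions (beyond a valve plane, within the
    tube's lateral footprint)."""
    mask = np.zeros(len(face_centroids), dtype=bool)
    for side in ((mesh.metadata or {}).get("valve_planes") or {}).values():
        c = np.asarray(side["centre"])
        ax = np.asarray(side["axis"])
        s = (face_centroids - c) @ ax
        lat = np.linalg.norm(face_centroids - c - s[:, None] * ax, axis=1)
        mask |= (s > 1e-9) & (lat <= 1.3 * side["radius"])
    return mask


def wall_shear_stress(state: FlowState, mesh: VolumeMesh,
                      props: FluidProperties, exclude_tubes: bool = True):
    """Per-wall-face WSS magnitudes (Pa) and their FD histogram summary.

    WSS is the tangential part of the viscous traction 2 mu S(u) n evaluated
    from the owning cell's velocity gradient.  Returns ``(values, areas,
    histogram)``.
    """
    wall = (mesh.boundary_tags == WALL) & mesh.boundary_genuine
    if not wall.any():
        raise AnalysisError("mesh has no wall-tagged boundary faces")
    areas, normals = mesh.boundary_face_areas_normals()
    owners = mesh.boundary_owner_cells()
    grads, _ = _geom.shape_gradients(mesh.vertices, mesh.cells)
    u = state.velocity[mesh.node_dof[mesh.cells]]
    gradu = np.einsum("cki,ckj->cij", u, grads)      # du_i/dx_j per cell
    S = 0.5 * (gradu + np.swapaxes(gradu, 1, 2))

    sel = np.nonzero(wall)[0]
    if exclude_tubes:
        fc = mesh.vertices[mesh.boundary_faces[sel]].mean(axis=1)
        sel = sel[~_tube_face_mask(mesh, fc)]
    n = normals[sel]
    traction = 2.0 * props.dynamic_viscosity * np.einsum(
        "fij,fj->fi", S[owners[sel]], n)
    tangential = traction - np.einsum("fi,fi->f", traction, n)[:, None] * n
    wss = np.linalg.norm(tangential, axis=1)
    hist = fd_histogram(wss) if len(wss) >= 2 else None
    return wss, areas[sel], hist


def q_criterion(state: FlowState, mesh: VolumeMesh) -> np.ndarray:
    """Per-cell Q = (||W||_F^2 - ||S||_F^2)/2 in 1/s^2."""
    grads, _ = _geom.shape_gradients(mesh.vertices, mesh.cells)
    u = state.velocity[mesh.node_dof[mesh.cells]]
    gradu = np.einsum("cki,ckj->cij", u, grads)
    S = 0.5 * (gradu + np.swapaxes(gradu, 1, 2))
    W = 0.5 * (gradu - np.swapaxes(gradu, 1, 2))
    return 0.5 * (np.einsum("cij,cij->c", W, W)
                  - np.einsum("cij,cij->c", S, S))


def q_to_nodes(q_cells: np.ndarray, mesh: VolumeMesh) -> np.ndarray:
    """Volume-weighted average of the cell Q field onto mesh nodes."""
    vols = np.abs(mesh.cell_volumes())
    nd = mesh.n_dofs
    num = np.zeros(nd)
    den = np.zeros(nd)
    cdofs = mesh.node_dof[mesh.cells]
    npc = mesh.cells.shape[1]
    np.add.at(num, cdofs.ravel(), np.repeat(q_cells * vols, npc))
    np.add.at(den, cdofs.ravel(), np.repeat(vols, npc))
    return num / np.maximum(den, 1e-300)


def vortex_surface(q_cells: np.ndarray, mesh: VolumeMesh,
                   threshold: float) -> float:
    """Area (m^2) of the Q = threshold isosurface (marching tetrahedra)."""
    if mesh.dim != 3:
        raise AnalysisError("vortex_surface requires a tetrahedral mesh")
    if not np.isfinite(threshold):
        raise AnalysisError("threshold must be finite")
    q_nodes = q_to_nodes(q_cells, mesh)
    node_vals = q_nodes[mesh.node_dof]
    return _geom.marching_tets_area(mesh.vertices, mesh.cells, node_vals,
                                    threshold)


@dataclass
class HemodynamicSummary:
    """One column of the per-ventricle outcome table."""

    delta_p: float                # kPa
    delta_p_sd: float             # kPa
    wss_mode: float               # Pa
    wss_median: float             # Pa
    wss_max: float                # Pa
    total_vortex_surface: float   # m^2
    q_threshold: float            # 1/s^2

    def metrics(self) -> dict:
        return {"delta_p": self.delta_p, "wss_median": self.wss_median,
                "total_vortex_surface": self.total_vortex_surface}


def summarize_run(record: RunRecord, q_threshold: float = 5000.0,
                  window_frames: int = 10) -> HemodynamicSummary:
    """Combine the three metric families for one run (final-frame fields)."""
    state = record.frames[-1]
    if not np.any(state.velocity):
        return HemodynamicSummary(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, q_threshold)
    dp, dp_sd = pressure_drop(record, window_frames=window_frames)
    wss, _, hist = wall_shear_stress(state, record.mesh, record.props)
    q = q_criterion(state, record.mesh)
    area = vortex_surface(q, record.mesh, q_threshold) \
        if record.mesh.dim == 3 else 0.0
    return HemodynamicSummary(
        delta_p=dp, delta_p_sd=dp_sd,
        wss_mode=hist.mode_value if hist else 0.0,
        wss_median=hist.median_value if hist else 0.0,
        wss_max=float(wss.max()) if len(wss) else 0.0,
        total_vortex_surface=area, q_threshold=q_threshold)
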