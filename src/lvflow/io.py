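"""Mesh and run-record file I/O.

Surface meshes round-trip through STL/PLY (trimesh backend); face labels and
geometry metadata, which those formats cannot carry, live in a JSON sidecar
``<file>.labels.json``.  Volume meshes round-trip through ASCII VTU
(unstructured grid) with cell data ``region`` (0 fluid, 1 porous) and the
boundary facets embedded as extra triangle/line cells carrying a ``tag``
cell-data field; mesh metadata goes to ``<file>.meta.json``.
"""

from __future__ import annotations

import dataclasses
import json
import os
import xml.etree.ElementTree as ET

import numpy as np
import pandas as pd
import trimesh

from .anatomy import CavityParams
from .meshes import SurfaceMesh, VolumeMesh

_SURFACE_EXT = {".stl", ".ply"}
_VOLUME_EXT = {".vtu"}

# VTK cell type codes
_VTK_TET, _VTK_TRI, _VTK_LINE = 10, 5, 3
_CELL_TYPE = {4: _VTK_TET, 3: _VTK_TRI, 2: _VTK_LINE}


class FormatError(ValueError):
    """Raised for unsupported or corrupt mesh files."""


def _meta_to_json(metadata: dict) -> dict:
    out = {}
    for key, val in (metadata or {}).items():
        if dataclasses.is_dataclass(val):
            out[key] = {"__dataclass__": type(val).__name__,
                        **dataclasses.asdict(val)}
        else:
            out[key] = val
    return out


def _meta_from_json(raw: dict) -> dict:
    out = {}
    for key, val in (raw or {}).items():
        if isinstance(val, dict) and val.get("__dataclass__") == "CavityParams":
            kw = {k: v for k, v in val.items() if k != "__dataclass__"}
            kw["inlet_offset"] = tuple(kw["inlet_offset"])
            kw["outlet_offset"] = tuple(kw["outlet_offset"])
            out[key] = CavityParams(**kw)
        else:
            out[key] = val
    return out


def write_mesh(mesh, path) -> None:
    """Write a SurfaceMesh (.stl/.ply) or VolumeMesh (.vtu)."""
    ext = os.path.splitext(str(path))[1].lower()
    if isinstance(mesh, SurfaceMesh):
        if ext not in _SURFACE_EXT:
            raise FormatError(
                f"unsupported surface format {ext!r}; supported: "
                f"{sorted(_SURFACE_EXT)}")
        mesh.to_trimesh().export(str(path))
        sidecar = {"face_labels": mesh.face_labels.tolist(),
                   "metadata": _meta_to_json(mesh.metadata)}
        with open(f"{path}.labels.json", "w") as fh:
            json.dump(sidecar, fh)
        return
    if isinstance(mesh, VolumeMesh):
        if ext not in _VOLUME_EXT:
            raise FormatError(
                f"unsupported volume format {ext!r}; supported: "
                f"{sorted(_VOLUME_EXT)}")
        _write_vtu_mesh(mesh, path)
        with open(f"{path}.meta.json", "w") as fh:
            json.dump(_meta_to_json(mesh.metadata), fh)
        return
    raise FormatError(f"cannot write object of type {type(mesh).__name__}")


def read_mesh(path):
    """Read a mesh written by :func:`write_mesh` (format from extension)."""
    ext = os.path.splitext(str(path))[1].lower()
    if not os.path.exists(path):
        raise FormatError(f"mesh file not found: {path}")
    if ext in _SURFACE_EXT:
        tm = trimesh.load(str(path), process=False, force="mesh")
        sidecar_path = f"{path}.labels.json"
        if os.path.exists(sidecar_path):
            with open(sidecar_path) as fh:
                sidecar = json.load(fh)
            labels = np.asarray(sidecar["face_labels"])
            metadata = _meta_from_json(sidecar.get("metadata"))
        else:
            labels = np.full(len(tm.faces), "wall")
            metadata = {}
        return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces),
                           labels, metadata)
    if ext in _VOLUME_EXT:
        mesh = _read_vtu_mesh(path)
        meta_path = f"{path}.meta.json"
        if os.path.exists(meta_path):
            with open(meta_path) as fh:
                mesh.metadata = _meta_from_json(json.load(fh))
        return mesh
    raise FormatError(
        f"unsupported mesh extension {ext!r}; supported: "
        f"{sorted(_SURFACE_EXT | _VOLUME_EXT)}")


# ---------------------------------------------------------------------------
# ASCII VTU
# ---------------------------------------------------------------------------

def _ascii(arr) -> str:
    return " ".join(np.asarray(arr).ravel().astype(str))


def _data_array(parent, name, data, n_comp=1, dtype="Float64"):
    el = ET.SubElement(parent, "DataArray", Name=name, type=dtype,
                       NumberOfComponents=str(n_comp), format="ascii")
    if dtype.startswith("Float"):
        flat = np.asarray(data, dtype=float).ravel()
        el.text = " ".join(f"{v:.17g}" for v in flat)
    else:
        el.text = _ascii(np.asarray(data).astype(np.int64))
    return el


def write_vtu(path, vertices, cell_blocks, point_data=None, cell_data=None):
    """Minimal ASCII VTU writer.

    ``cell_blocks`` is a list of (connectivity, vtk_type) arrays (they are
    concatenated); ``point_data``/``cell_data`` map names to arrays (cell
    data over all blocks concatenated, same order).
    """
    vertices = np.asarray(vertices, dtype=float)
    if vertices.shape[1] == 2:
        vertices = np.column_stack([vertices, np.zeros(len(vertices))])
    conn, offs, types = [], [], []
    off = 0
    for block, vtk_type in cell_blocks:
        block = np.asarray(block, dtype=np.int64)
        for row in block:
            conn.extend(row.tolist())
            off += len(row)
            offs.append(off)
            types.append(vtk_type)
    root = ET.Element("VTKFile", type="UnstructuredGrid", version="0.1",
                      byte_order="LittleEndian")
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(grid, "Piece", NumberOfPoints=str(len(vertices)),
                          NumberOfCells=str(len(types)))
    pts = ET.SubElement(piece, "Points")
    _data_array(pts, "Points", vertices, n_comp=3)
    cells_el = ET.SubElement(piece, "Cells")
    _data_array(cells_el, "connectivity", conn, dtype="Int64")
    _data_array(cells_el, "offsets", offs, dtype="Int64")
    _data_array(cells_el, "types", types, dtype="UInt8")
    if point_data:
        pd_el = ET.SubElement(piece, "PointData")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            _data_array(pd_el, name, arr,
                        n_comp=arr.shape[1] if arr.ndim > 1 else 1)
    if cell_data:
        cd_el = ET.SubElement(piece, "CellData")
        for name, arr in cell_data.items():
            arr = np.asarray(arr)
            dtype = "Int64" if np.issubdtype(arr.dtype, np.integer) \
                else "Float64"
            _data_array(cd_el, name, arr, dtype=dtype)
    ET.indent(root)
    ET.ElementTree(root).write(str(path), xml_declaration=True,
                               encoding="unicode")


def read_vtu(path):
    """Read an ASCII VTU written by :func:`write_vtu`.

    Returns ``(vertices, cell_blocks, point_data, cell_data)`` with
    ``cell_blocks`` a list of (connectivity, vtk_type) grouped by type order
    of appearance.
    """
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:
        raise FormatError(
            f"corrupt VTU file {path}: parse error at {exc.position}") from exc
    piece = tree.getroot().find(".//Piece")
    if piece is None:
        raise FormatError(f"corrupt VTU file {path}: no <Piece> element")

    def grab(parent, name):
        for el in parent.iter("DataArray"):
            if el.get("Name") == name:
                kind = float if el.get("type", "").startswith("Float") else int
                return np.array((el.text or "").split(), dtype=kind)
        raise FormatError(f"corrupt VTU file {path}: missing array {name!r}")

    pts = grab(piece.find("Points"), "Points").astype(float).reshape(-1, 3)
    cells_el = piece.find("Cells")
    conn = grab(cells_el, "connectivity").astype(np.int64)
    offs = grab(cells_el, "offsets").astype(np.int64)
    types = grab(cells_el, "types").astype(np.int64)
    blocks = []
    start = 0
    i = 0
    while i < len(types):
        j = i
        while j < len(types) and types[j] == types[i]:
            j += 1
        width = (offs[i] - start) if i == 0 else offs[i] - offs[i - 1]
        seg = conn[(offs[i] - width):offs[j - 1]].reshape(j - i, width)
        blocks.append((seg, int(types[i])))
        i = j

    def collect(tag):
        out = {}
        el = piece.find(tag)
        if el is not None:
            for arr in el.iter("DataArray"):
                ncomp = int(arr.get("NumberOfComponents", "1"))
                kind = float if arr.get("type", "").startswith("Float") else np.int64
                data = np.array((arr.text or "").split(), dtype=kind)
                out[arr.get("Name")] = data.reshape(-1, ncomp) if ncomp > 1 \
                    else data
        return out

    return pts, blocks, collect("PointData"), collect("CellData")


def _write_vtu_mesh(mesh: VolumeMesh, path) -> None:
    npc = mesh.cells.shape[1]
    nbf = mesh.boundary_faces.shape[1] if len(mesh.boundary_faces) else 0
    blocks = [(mesh.cells, _CELL_TYPE[npc])]
    region = mesh.cell_region.astype(np.int64)
    tag = np.full(len(mesh.cells), -1, dtype=np.int64)
    genuine = np.full(len(mesh.cells), -1, dtype=np.int64)
    if len(mesh.boundary_faces):
        blocks.append((mesh.boundary_faces, _CELL_TYPE[nbf]))
        region = np.concatenate(
            [region, np.full(len(mesh.boundary_faces), -1, dtype=np.int64)])
        tag = np.concatenate([tag, mesh.boundary_tags.astype(np.int64)])
        genuine = np.concatenate(
            [genuine, mesh.boundary_genuine.astype(np.int64)])
    write_vtu(path, mesh.vertices, blocks,
              cell_data={"region": region, "tag": tag, "genuine": genuine})


def _read_vtu_mesh(path) -> VolumeMesh:
    pts, blocks, _, cell_data = read_vtu(path)
    vol_block = next((b for b, t in blocks if t == _VTK_TET), None)
    dim = 3
    if vol_block is None:
        vol_block = next((b for b, t in blocks if t == _VTK_TRI), None)
        dim = 2
    if vol_block is None:
        raise FormatError(f"{path}: no volume cells found")
    verts = pts[:, :dim]
    n_vol = len(vol_block)
    bnd = [(b, t) for b, t in blocks
           if (dim == 3 and t == _VTK_TRI) or (dim == 2 and t == _VTK_LINE)]
    genuine = None
    if bnd:
        bfaces = np.concatenate([b for b, _ in bnd], axis=0)
        tags = cell_data["tag"][n_vol:]
        if "genuine" in cell_data:
            genuine = cell_data["genuine"][n_vol:].astype(bool)
    else:
        from . import _geom
        bfaces, _ = _geom.boundary_facets(vol_block)
        tags = np.zeros(len(bfaces), dtype=np.int64)
    region = cell_data.get("region")
    region = region[:n_vol] if region is not None else None
    return VolumeMesh(verts, vol_block, bfaces, tags.astype(np.int64),
                      boundary_genuine=genuine,
                      cell_region=region)


# ---------------------------------------------------------------------------
# Run records
# ---------------------------------------------------------------------------

def write_run_record(record, out_dir, write_frames: bool = False) -> None:
    """Persist a run record: mesh, probe CSVs, flow series, optional frames."""
    os.makedirs(out_dir, exist_ok=True)
    write_mesh(record.mesh, os.path.join(out_dir, "mesh.vtu"))
    pd.DataFrame({"time": record.step_times,
                  "q_out": record.outlet_flow,
                  "q_in": record.inlet_flow}).to_csv(
        os.path.join(out_dir, "flows.csv"), index=False)
    for name, series in record.probe_pressures.items():
        arr = np.asarray(series)
        cols = {"time": record.frame_times}
        cols.update({f"p_{i}": arr[:, i] for i in range(arr.shape[1])})
        pd.DataFrame(cols).to_csv(
            os.path.join(out_dir, f"probe_{name}_pa.csv"), index=False)
    if write_frames:
        rho = record.props.density
        for i, (t, st) in enumerate(zip(record.frame_times, record.frames)):
            u = st.velocity[record.mesh.node_dof]
            p = rho * st.pressure[record.mesh.node_dof]
            write_vtu(os.path.join(out_dir, f"frame_{i:04d}.vtu"),
                      record.mesh.vertices,
                      [(record.mesh.cells,
                        _CELL_TYPE[record.mesh.cells.shape[1]])],
                      point_data={"velocity": u, "pressure": p})


def write_histogram_csv(hist, path) -> None:
    pd.DataFrame({"edge_low": hist.bin_edges[:-1],
                  "edge_high": hist.bin_edges[1:],
                  "density": hist.density}).to_csv(path, index=False)
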