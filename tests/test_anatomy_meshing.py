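"""Tetrahedralisation and porous-layer tagging."""

import numpy as np
import pytest
from scipy import ndimage

from lvflow import _geom, anatomy
from lvflow.meshes import (INLET, MeshError, OUTLET, POROUS, SurfaceMesh,
                           WALL)


def _cube_surface(side=1.0):
    v = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                  [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], float) * side
    f = np.array([[0, 2, 1], [0, 3, 2], [4, 5, 6], [4, 6, 7],
                  [0, 1, 5], [0, 5, 4], [1, 2, 6], [1, 6, 5],
                  [2, 3, 7], [2, 7, 6], [3, 0, 4], [3, 4, 7]])
    return SurfaceMesh(v, f, np.full(len(f), "wall"))


class TestTetrahedralize:
    def test_unit_cube_volume_conserved(self):
        mesh = anatomy.tetrahedralize(_cube_surface(), edge_length=0.21)
        assert mesh.cell_volumes().sum() == pytest.approx(1.0, rel=1e-6)

    def test_no_inverted_elements(self, cavity_mesh):
        assert (cavity_mesh.cell_volumes() > 0).all()

    def test_boundary_tags_partition(self, cavity_mesh):
        cavity_mesh.validate()
        for tag in (WALL, INLET, OUTLET):
            assert (cavity_mesh.boundary_tags == tag).any()

    def test_cavity_volume_close_to_surface_volume(self, cavity_surface,
                                                   cavity_mesh):
        assert cavity_mesh.cell_volumes().sum() == pytest.approx(
            cavity_surface.volume(), rel=0.02)

    def test_cap_areas_recovered(self, cavity_surface, cavity_mesh):
        areas, _ = cavity_mesh.boundary_face_areas_normals()
        cap = cavity_surface.subset(["inlet_cap"]).face_areas().sum()
        assert areas[cavity_mesh.boundary_tags == INLET].sum() \
            == pytest.approx(cap, rel=0.05)

    def test_near_wall_refinement(self, cavity_surface):
        coarse = anatomy.tetrahedralize(cavity_surface, edge_length=0.005)
        fine = anatomy.tetrahedralize(cavity_surface, edge_length=0.005,
                                      near_wall_refinement=2.0)
        wall_faces = fine.boundary_faces[fine.boundary_tags == WALL]
        dist = _geom.distance_to_facets(fine.cell_centroids(),
                                        fine.vertices, wall_faces)
        vols = fine.cell_volumes()
        near = dist < 0.0025
        assert np.median(vols[near]) <= 0.5 * np.median(vols[~near])
        assert len(fine.cells) > len(coarse.cells)

    def test_non_watertight_input_rejected(self):
        cube = _cube_surface()
        open_cube = SurfaceMesh(cube.vertices, cube.faces[:-1],
                                cube.face_labels[:-1])
        with pytest.raises(MeshError, match="watertight"):
            anatomy.tetrahedralize(open_cube, edge_length=0.3)

    def test_deterministic(self, cavity_surface):
        a = anatomy.tetrahedralize(cavity_surface, edge_length=0.005)
        b = anatomy.tetrahedralize(cavity_surface, edge_length=0.005)
        assert np.array_equal(a.vertices, b.vertices)
        assert np.array_equal(a.cells, b.cells)


class TestPorousLayer:
    def test_zero_thickness_tags_nothing(self, cavity_mesh):
        out = anatomy.tag_porous_layer(cavity_mesh, 0.0)
        assert not (out.cell_region == POROUS).any()

    def test_huge_thickness_tags_all_cavity_cells(self, cavity_mesh):
        """Everything in the cavity proper is within reach of a huge layer
        (tubes and the smooth sub-valvular vestibules stay fluid)."""
        out = anatomy.tag_porous_layer(cavity_mesh, 1.0)
        cent = out.cell_centroids()
        sel = cent[:, 2] < 0                    # below the basal plane
        for side in out.metadata["valve_planes"].values():
            c, ax = np.asarray(side["centre"]), np.asarray(side["axis"])
            s = (cent - c) @ ax
            lat = np.linalg.norm(cent - c - s[:, None] * ax, axis=1)
            sel &= lat > 1.3 * side["radius"]   # outside the vestibules
        assert (out.cell_region[sel] == POROUS).all()

    def test_tubes_never_tagged(self, cavity_mesh):
        out = anatomy.tag_porous_layer(cavity_mesh, 1.0)
        planes = out.metadata["valve_planes"]
        cent = out.cell_centroids()
        for side in planes.values():
            c, ax = np.asarray(side["centre"]), np.asarray(side["axis"])
            s = (cent - c) @ ax
            lat = np.linalg.norm(cent - c - s[:, None] * ax, axis=1)
            in_tube = (s > 1e-6) & (lat <= side["radius"])
            assert not (out.cell_region[in_tube] == POROUS).any()

    def test_volume_fraction_matches_voxel_distance_oracle(self):
        """Porous fraction vs an independent voxel distance-transform oracle."""
        p = anatomy.CavityParams(long_axis_length=0.06, base_radius=0.03,
                                 inlet_radius=0.0, outlet_radius=0.0)
        surf = anatomy.build_smoothed_cavity(p)
        mesh = anatomy.tetrahedralize(surf, edge_length=0.005)
        thickness = 1.2e-2
        out = anatomy.tag_porous_layer(mesh, thickness)
        vols = out.cell_volumes()
        frac = vols[out.cell_region == POROUS].sum() / vols.sum()

        # oracle: voxelize, distance transform from the outside
        h = 1.2e-3
        lo = surf.vertices.min(axis=0) - 2 * h
        hi = surf.vertices.max(axis=0) + 2 * h
        axes = [np.arange(lo[k] + h / 2, hi[k], h) for k in range(3)]
        P = np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, 3)
        inside = _geom.points_in_surface(surf.vertices, surf.faces, P)
        grid = inside.reshape(len(axes[0]), len(axes[1]), len(axes[2]))
        dist = ndimage.distance_transform_edt(grid, sampling=h)
        frac_oracle = (grid & (dist <= thickness)).sum() / grid.sum()
        assert frac == pytest.approx(frac_oracle, abs=0.02)
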