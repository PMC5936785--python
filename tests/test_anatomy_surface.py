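"""Surface generation: watertightness, tube lengths, volumes, trabeculation."""

import numpy as np
import pytest

from lvflow import anatomy
from lvflow.meshes import (LBL_INLET_CAP, LBL_OUTLET_CAP, LBL_WALL,
                           SURFACE_LABELS)


class TestSmoothedCavity:
    def test_watertight_genus_zero(self, cavity_surface):
        assert cavity_surface.is_watertight
        assert cavity_surface.euler_characteristic == 2

    def test_labels_cover_known_set(self, cavity_surface):
        assert set(cavity_surface.face_labels) <= set(SURFACE_LABELS)
        for lbl in (LBL_WALL, LBL_INLET_CAP, LBL_OUTLET_CAP):
            assert (cavity_surface.face_labels == lbl).any()

    @pytest.mark.parametrize("side, expected", [("inlet", 0.050),
                                                ("outlet", 0.070)])
    def test_tube_axial_lengths(self, cavity_surface, side, expected):
        """Distance from the tip cap plane to the valve plane along the axis."""
        planes = cavity_surface.metadata["valve_planes"]
        centre = np.asarray(planes[side]["centre"])
        axis = np.asarray(planes[side]["axis"])
        lbl = LBL_INLET_CAP if side == "inlet" else LBL_OUTLET_CAP
        cap_faces = cavity_surface.faces[cavity_surface.face_labels == lbl]
        cap_pts = cavity_surface.vertices[np.unique(cap_faces)]
        axial = (cap_pts - centre) @ axis
        assert axial == pytest.approx(expected, abs=1e-9)

    def test_half_ellipsoid_volume_closed_form(self):
        """Tubes disabled: enclosed volume matches (2/3) pi a b^2 within 1%."""
        p = anatomy.CavityParams(inlet_radius=0.0, outlet_radius=0.0)
        surf = anatomy.build_smoothed_cavity(p)
        exact = (2.0 / 3.0) * np.pi * p.long_axis_length * p.base_radius ** 2
        assert surf.volume() == pytest.approx(exact, rel=0.01)
        assert surf.euler_characteristic == 2

    def test_overlapping_orifices_rejected(self):
        p = anatomy.CavityParams(inlet_offset=(-0.004, 0.0),
                                 outlet_offset=(0.004, 0.0))
        with pytest.raises(anatomy.GeometryError, match="overlap"):
            anatomy.build_smoothed_cavity(p)

    def test_intersecting_tubes_rejected(self):
        p = anatomy.CavityParams(inlet_tilt_deg=25.0, outlet_tilt_deg=-25.0)
        with pytest.raises(anatomy.GeometryError, match="intersect"):
            anatomy.build_smoothed_cavity(p)


class TestTrabeculation:
    def test_zero_amplitude_is_identity(self, cavity_surface):
        out = anatomy.add_trabeculation(
            cavity_surface, anatomy.TrabeculationParams(amplitude=0.0))
        assert np.array_equal(out.vertices, cavity_surface.vertices)
        assert np.array_equal(out.faces, cavity_surface.faces)

    def test_same_seed_is_byte_identical(self, cavity_surface):
        trab = anatomy.TrabeculationParams(target_volume_fraction=0.15,
                                           seed=11)
        a = anatomy.add_trabeculation(cavity_surface, trab)
        b = anatomy.add_trabeculation(cavity_surface, trab)
        assert a.vertices.tobytes() == b.vertices.tobytes()

    def test_tubes_and_caps_untouched(self, cavity_surface,
                                      trabeculated_surface):
        moved = ~np.isclose(trabeculated_surface.vertices,
                            cavity_surface.vertices).all(axis=1)
        wall_only = np.ones(len(cavity_surface.vertices), dtype=bool)
        non_wall = np.unique(cavity_surface.faces[
            cavity_surface.face_labels != LBL_WALL])
        wall_only[non_wall] = False
        assert not moved[~wall_only].any()

    def test_target_fraction_reached(self, trabeculated_surface):
        """Target 20% lands in the published per-heart band 10.9-26.6%."""
        pct = anatomy.compute_markers(
            trabeculated_surface).trabecular_volume_pct
        assert 15.0 <= pct <= 27.0

    def test_output_watertight(self, trabeculated_surface):
        assert trabeculated_surface.is_watertight

    def test_excessive_amplitude_rejected(self, cavity_surface):
        trab = anatomy.TrabeculationParams(amplitude=0.05, seed=0)
        with pytest.raises(anatomy.GeometryError,
                           match="amplitude|self-intersection"):
            anatomy.add_trabeculation(cavity_surface, trab)

    def test_invalid_params_rejected(self):
        with pytest.raises(anatomy.GeometryError):
            anatomy.TrabeculationParams(amplitude=-1e-3).validate()
        with pytest.raises(anatomy.GeometryError):
            anatomy.TrabeculationParams(target_volume_fraction=0.7).validate()
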