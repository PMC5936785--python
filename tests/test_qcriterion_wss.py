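"""Q-criterion fields, vortex-surface extraction, wall shear stress,
and the mode-based pressure drop on synthetic run records."""

import numpy as np
import pytest

from lvflow import hemodynamics as hd
from lvflow import meshes
from lvflow.anatomy import FluidProperties
from lvflow.solver import FlowState, RunRecord


@pytest.fixture(scope="module")
def box():
    return meshes.box_tets((8, 8, 8), (1.0, 1.0, 1.0), origin=(-.5, -.5, -.5))


def _state(mesh, fn):
    return FlowState(0.0, np.asarray(fn(mesh.vertices), dtype=float),
                     np.zeros(len(mesh.vertices)))


class TestQCriterion:
    def test_rigid_rotation(self, box):
        """u = (-w y, w x, 0): W has entries +-w, S = 0, so Q = w^2."""
        w = 3.0
        st = _state(box, lambda p: np.stack(
            [-w * p[:, 1], w * p[:, 0], np.zeros(len(p))], axis=1))
        q = hd.q_criterion(st, box)
        assert np.allclose(q, w ** 2, rtol=1e-12)

    def test_simple_shear(self, box):
        """u = (g y, 0, 0): ||W||^2 = ||S||^2, so Q = 0."""
        g = 2.5
        st = _state(box, lambda p: np.stack(
            [g * p[:, 1], np.zeros(len(p)), np.zeros(len(p))], axis=1))
        assert np.allclose(hd.q_criterion(st, box), 0.0, atol=1e-12)

    def test_pure_strain(self, box):
        """u = (g x, -g y, 0): W = 0, ||S||^2 = 2 g^2, so Q = -g^2."""
        g = 1.7
        st = _state(box, lambda p: np.stack(
            [g * p[:, 0], -g * p[:, 1], np.zeros(len(p))], axis=1))
        assert np.allclose(hd.q_criterion(st, box), -g ** 2, rtol=1e-12)

    def test_galilean_invariance(self, box, rng):
        st = _state(box, lambda p: rng.normal(size=(len(p), 3)))
        q0 = hd.q_criterion(st, box)
        st.velocity = st.velocity + np.array([2.0, -1.0, 0.5])
        assert np.allclose(hd.q_criterion(st, box), q0, atol=1e-10)


class TestVortexSurface:
    def test_sphere_closed_form(self, qsphere_result):
        assert qsphere_result["area_rel_err"] < 0.03

    def test_threshold_above_max_gives_zero(self, box):
        st = _state(box, lambda p: np.stack(
            [-p[:, 1], p[:, 0], np.zeros(len(p))], axis=1))
        q = hd.q_criterion(st, box)
        assert hd.vortex_surface(q, box, q.max() * 10 + 1) == 0.0

    def test_monotone_in_threshold(self, box):
        """Nested level sets of a radially decreasing field."""
        r = np.linalg.norm(box.cell_centroids(), axis=1)
        q = 1000.0 * (1 - r / 0.5)
        areas = [hd.vortex_surface(q, box, thr)
                 for thr in (100.0, 300.0, 500.0, 700.0)]
        assert all(a2 <= a1 + 1e-12 for a1, a2 in zip(areas, areas[1:]))


class TestWallShearStress:
    def test_poiseuille_wall_value(self):
        """Parabolic profile: wall WSS = 2 mu U / h (centreline U, half-gap h).

        Only top/bottom are wall-tagged; the in/outflow ends carry no WSS.
        The one-sided P1 cell gradient reads the parabola's wall slope as a
        secant biased low by h_cell/(2h), so 40 cells across keep the bias
        inside the 3% band.
        """
        mesh = meshes.rectangle_grid(20, 40, 2.0, 1.0)
        props = FluidProperties(density=1.0, dynamic_viscosity=0.05)
        U, h = 1.2, 0.5
        st = _state(mesh, lambda p: np.stack(
            [U * (1 - ((p[:, 1] - h) / h) ** 2), np.zeros(len(p))], axis=1))
        wss, areas, hist = hd.wall_shear_stress(st, mesh, props)
        expected = 2 * props.dynamic_viscosity * U / h
        assert np.median(wss) == pytest.approx(expected, rel=0.03)
        assert wss.max() == pytest.approx(expected, rel=0.03)

    def test_rigid_rotation_gives_zero(self, box):
        """S = 0 for a rigid rotation, so the viscous traction vanishes."""
        st = _state(box, lambda p: np.stack(
            [-p[:, 1], p[:, 0], np.zeros(len(p))], axis=1))
        wss, _, _ = hd.wall_shear_stress(st, box, FluidProperties())
        assert np.allclose(wss, 0.0, atol=1e-10)

    def test_rotation_invariance(self, box, rng):
        """WSS values survive a rigid rotation of mesh + field."""
        st = _state(box, lambda p: np.stack(
            [p[:, 2] ** 1 * 0 + p[:, 1] * 0.8, 0.3 * p[:, 2],
             np.zeros(len(p))], axis=1))
        wss0, _, _ = hd.wall_shear_stress(st, box, FluidProperties())
        th = 0.6
        R = np.array([[np.cos(th), 0, np.sin(th)], [0, 1, 0],
                      [-np.sin(th), 0, np.cos(th)]])
        rot = meshes.VolumeMesh(box.vertices @ R.T, box.cells,
                                box.boundary_faces, box.boundary_tags)
        st_rot = FlowState(0.0, st.velocity @ R.T, st.pressure)
        wss1, _, _ = hd.wall_shear_stress(st_rot, rot, FluidProperties())
        assert np.allclose(np.sort(wss0), np.sort(wss1), rtol=1e-8)

    def test_missing_wall_tags_rejected(self, box):
        no_wall = meshes.VolumeMesh(box.vertices, box.cells,
                                    box.boundary_faces,
                                    np.full(len(box.boundary_faces),
                                            meshes.OUTLET))
        st = _state(box, lambda p: np.zeros((len(p), 3)))
        with pytest.raises(hd.AnalysisError, match="wall"):
            hd.wall_shear_stress(st, no_wall, FluidProperties())


class TestPressureDrop:
    def _record(self, inlet_frames, outlet_frames):
        rec = RunRecord(mesh=None, props=None, config=None)
        rec.probe_pressures = {"inlet": inlet_frames, "outlet": outlet_frames}
        rec.frame_times = list(range(len(inlet_frames)))
        return rec

    def test_identical_probes_give_zero(self, rng):
        frames = [rng.normal(10000, 300, 200) for _ in range(12)]
        dp, sd = hd.pressure_drop(self._record(frames, frames))
        assert dp == 0.0 and sd == 0.0

    def test_constant_shift_recovered(self, rng):
        """Outlet = inlet - 500 Pa: mode difference is 0.5 kPa exactly."""
        frames_in = [rng.normal(10000, 300, 400) for _ in range(12)]
        frames_out = [f - 500.0 for f in frames_in]
        dp, sd = hd.pressure_drop(self._record(frames_in, frames_out))
        assert dp == pytest.approx(0.5, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_translation_equivariance(self, rng):
        """Adding a constant to every sample leaves the drop unchanged."""
        frames_in = [rng.normal(10000, 300, 400) for _ in range(12)]
        frames_out = [rng.normal(9000, 250, 400) for _ in range(12)]
        dp0, _ = hd.pressure_drop(self._record(frames_in, frames_out))
        dp1, _ = hd.pressure_drop(self._record(
            [f + 777.0 for f in frames_in], [f + 777.0 for f in frames_out]))
        assert dp1 == pytest.approx(dp0, abs=1e-9)

    def test_too_few_frames_reported(self, rng):
        frames = [rng.normal(0, 1, 50) for _ in range(4)]
        with pytest.raises(hd.AnalysisError, match="10 frames"):
            hd.pressure_drop(self._record(frames, frames))
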