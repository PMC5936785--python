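"""Porosity/permeability conversions, Darcy drag, surrogate scoring."""

import numpy as np
import pytest

from lvflow import meshes, porous, solver
from lvflow.anatomy import FluidProperties
from lvflow.hemodynamics import HemodynamicSummary
from lvflow.porous import (PorousError, PorousLayerSpec,
                           conductivity_from_sigma, permeability_from_sigma,
                           sigma_from_conductivity, sigma_from_permeability,
                           surrogate_error)


class TestConversions:
    def test_gravel_anchor_exact(self):
        """K = 5e-4 m/s (well-graded gravel) gives sigma = 7 kg/m^2 exactly."""
        assert sigma_from_conductivity(5e-4) == 7.0

    def test_sweep_value_twenty(self):
        assert sigma_from_conductivity(1.75e-4) == pytest.approx(20.0)

    def test_reciprocal_in_conductivity(self):
        assert sigma_from_conductivity(1e-3) \
            == pytest.approx(sigma_from_conductivity(2e-3) * 2)

    def test_permeability_value(self):
        # k = mu^2 / (sigma rho g) at blood constants
        assert permeability_from_sigma(7.0) \
            == pytest.approx(0.0035 ** 2 / (7.0 * 1060.0 * 9.81), rel=1e-12)
        assert permeability_from_sigma(7.0) == pytest.approx(1.68e-10,
                                                             rel=0.01)

    def test_impermeable_limit(self):
        assert permeability_from_sigma(1e12) < 1e-20

    def test_round_trips_exact(self):
        for sigma in (7.0, 20.0, 40.0, 70.0):
            k = permeability_from_sigma(sigma)
            assert sigma_from_permeability(k) == pytest.approx(sigma,
                                                               rel=1e-12)
            K = conductivity_from_sigma(sigma)
            assert sigma_from_conductivity(K) == pytest.approx(sigma,
                                                               rel=1e-12)

    @pytest.mark.parametrize("fn", [sigma_from_conductivity,
                                    permeability_from_sigma,
                                    sigma_from_permeability])
    def test_nonpositive_rejected(self, fn):
        with pytest.raises(PorousError):
            fn(0.0)

    def test_spec_derived_quantities(self):
        spec = PorousLayerSpec(thickness=0.012, sigma=20.0)
        assert spec.hydraulic_conductivity() \
            == pytest.approx(0.0035 / 20.0)
        assert spec.intrinsic_permeability() \
            == pytest.approx(permeability_from_sigma(20.0))


class TestDarcyDrag:
    def _setup(self):
        mesh = meshes.rectangle_grid(8, 4, 1.0, 0.5)
        mesh.cell_region[:] = meshes.POROUS
        s = solver.NavierStokesSolver(
            mesh, FluidProperties(density=1.0, dynamic_viscosity=0.01),
            solver.SolverConfig(max_time=1.0), solver.BoundaryConditions())
        return mesh, s

    def test_zero_velocity_zero_drag(self):
        _, s = self._setup()
        F = solver.darcy_drag(s, np.zeros((s.nd, 2)), 1e-8)
        assert np.all(F == 0.0)

    def test_infinite_permeability_limit(self, rng):
        _, s = self._setup()
        u = rng.normal(size=(s.nd, 2))
        F = solver.darcy_drag(s, u, 1e12)
        assert np.abs(F).max() < 1e-12

    def test_drag_only_on_porous_cells(self, rng):
        mesh = meshes.rectangle_grid(8, 4, 1.0, 0.5)
        mesh.cell_region[:4] = meshes.POROUS  # left corner cells only
        s = solver.NavierStokesSolver(
            mesh, FluidProperties(density=1.0, dynamic_viscosity=0.01),
            solver.SolverConfig(max_time=1.0), solver.BoundaryConditions())
        u = np.ones((s.nd, 2))
        F = solver.darcy_drag(s, u, 1e-8)
        porous_dofs = np.unique(s.cdofs[mesh.cell_region == meshes.POROUS])
        far = np.setdiff1d(np.arange(s.nd), porous_dofs)
        assert np.all(F[far] == 0.0)
        assert np.abs(F[porous_dofs]).max() > 0.0

    def test_invalid_permeability_rejected(self):
        _, s = self._setup()
        with pytest.raises(solver.SolverError, match="permeability"):
            s.set_permeability(-1.0)

    def test_steady_channel_balance(self, darcy_result):
        """|grad p| = (mu/k) |u| within 5% at steady state."""
        assert darcy_result["balance_rel_err"] < 0.05


class TestSurrogateError:
    def _summary(self, dp, wss, vortex):
        return HemodynamicSummary(dp, 0.0, 0.0, wss, 0.0, vortex, 5000.0)

    def test_identical_summaries_zero(self):
        s = self._summary(1.5, 0.39, 0.0356)
        assert all(v == 0.0 for v in surrogate_error(s, s).values())

    def test_published_wss_pairing(self):
        """0.36 Pa porous vs 0.39 Pa detailed -> 0.077."""
        err = surrogate_error(self._summary(1.5, 0.36, 0.0368),
                              self._summary(1.5, 0.39, 0.0356))
        assert err["wss_median"] == pytest.approx(0.077, abs=5e-4)

    def test_published_pressure_pairing_model_d(self):
        """2.6 kPa porous vs 4.9 kPa detailed -> 0.47."""
        err = surrogate_error(self._summary(2.6, 0.55, 0.0546),
                              self._summary(4.9, 0.66, 0.0484))
        assert err["delta_p"] == pytest.approx(0.47, abs=5e-3)

    def test_sign_negative_when_porous_overshoots(self):
        err = surrogate_error(self._summary(1.5, 0.39, 0.0546),
                              self._summary(1.5, 0.39, 0.0484))
        assert err["total_vortex_surface"] == pytest.approx(-0.128, abs=2e-3)

    def test_zero_reference_undefined_not_infinite(self):
        err = surrogate_error(self._summary(1.0, 0.5, 0.01),
                              self._summary(0.0, 0.5, 0.01))
        assert err["delta_p"] is None

    def test_empty_grid_rejected(self):
        with pytest.raises(PorousError, match="non-empty"):
            porous.run_sweep(None, [], [7.0], None, None, None)
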