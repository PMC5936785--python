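"""Inflow waveforms and the outlet pressure model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lvflow import boundary
from lvflow.boundary import (ConstantInflow, EAWaveParams, OutletModel,
                             WaveformError, ea_wave, outlet_pressure,
                             stroke_volume)


class TestEAWave:
    params = EAWaveParams()

    def test_peak_values(self):
        assert ea_wave(self.params.tp_E, self.params) \
            == pytest.approx(self.params.A_E)
        assert ea_wave(self.params.tp_A, self.params) \
            == pytest.approx(self.params.A_A)

    def test_zero_in_diastasis_and_outside(self):
        ts = [0.5 * (self.params.t1_E + self.params.t0_A),   # diastasis
              self.params.t1_A + 0.05, self.params.period - 1e-3]
        assert all(ea_wave(t, self.params) == 0.0 for t in ts)

    def test_zero_at_wave_endpoints_for_midpoint_peaks(self):
        # cos(+-pi) = -1 forces the raised cosine to zero at interval ends
        for t in (self.params.t0_E, self.params.t1_E,
                  self.params.t0_A, self.params.t1_A):
            assert ea_wave(t, self.params) == pytest.approx(0.0, abs=1e-12)

    def test_continuity(self):
        ts = np.linspace(0.0, self.params.period, 4001)
        v = ea_wave(ts, self.params)
        assert np.abs(np.diff(v)).max() < 0.02  # no jumps at this sampling

    @given(t=st.floats(0.0, 0.8))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounded_and_nonnegative(self, t):
        v = ea_wave(t, self.params)
        assert 0.0 <= v <= max(self.params.A_E, self.params.A_A) + 1e-12

    def test_time_shift_invariance(self):
        shift = 0.137
        shifted = EAWaveParams(
            t0_E=self.params.t0_E + shift, t1_E=self.params.t1_E + shift,
            tp_E=self.params.tp_E + shift, t0_A=self.params.t0_A + shift,
            t1_A=self.params.t1_A + shift, tp_A=self.params.tp_A + shift,
            period=self.params.period + shift)
        ts = np.linspace(0, self.params.period, 500)
        assert np.allclose(ea_wave(ts, self.params),
                           ea_wave(ts + shift, shifted))

    def test_invalid_ordering_rejected(self):
        with pytest.raises(WaveformError, match="t0_E"):
            EAWaveParams(t0_E=0.3, tp_E=0.2, t1_E=0.25)


class TestConstantInflow:
    def test_default_plateau(self):
        assert boundary.constant_inflow(1.0) == pytest.approx(0.55)

    @pytest.mark.parametrize("t, expected", [(0.0, 0.0), (0.025, 0.275),
                                             (0.05, 0.55), (1.0, 0.55)])
    def test_linear_ramp(self, t, expected):
        assert ConstantInflow(0.55, 0.05)(t) == pytest.approx(expected)


class TestOutletModel:
    def test_baseline_at_zero_flow(self):
        assert outlet_pressure(0.0, OutletModel()) == pytest.approx(10700.0)

    def test_zero_resistance_flow_independent(self):
        m = OutletModel(resistance=0.0)
        assert outlet_pressure(1e-3, m) == outlet_pressure(5e-3, m)

    def test_affine_in_flow(self):
        m = OutletModel(baseline_pressure=10700.0, resistance=2.0e6)
        inc1 = outlet_pressure(1e-4, m) - outlet_pressure(0.0, m)
        inc2 = outlet_pressure(2e-4, m) - outlet_pressure(0.0, m)
        assert inc2 == pytest.approx(2 * inc1)


class TestStrokeVolume:
    def test_single_raised_cosine_closed_form(self):
        # integral of (A/2)(1 + cos) over its support is A * width / 2
        p = EAWaveParams(A_E=0.6, A_A=0.0, t0_E=0.0, t1_E=0.3, tp_E=0.15,
                        t0_A=0.45, tp_A=0.5, t1_A=0.55)
        area = 3.8e-4
        assert stroke_volume(p, area) \
            == pytest.approx(0.5 * 0.6 * 0.3 * area, rel=1e-8)

    def test_zero_amplitudes(self):
        p = EAWaveParams(A_E=0.0, A_A=0.0)
        assert stroke_volume(p, 1e-3) == pytest.approx(0.0, abs=1e-15)

    def test_healthy_defaults_give_plausible_volume(self):
        # default waveform through a 7 cm^2 mitral orifice: tens of ml
        sv = stroke_volume(EAWaveParams(), 7e-4)
        assert 20e-6 < sv < 120e-6

    def test_quadrature_richardson(self):
        """Adaptive result vs dense trapezoid at 10x resolution."""
        p = EAWaveParams()
        area = 1.0
        ts = np.linspace(0, p.period, 200001)
        dense = np.trapezoid(ea_wave(ts, p), ts) * area
        assert stroke_volume(p, area) == pytest.approx(dense, rel=1e-6)
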