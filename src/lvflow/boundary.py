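"""Inflow waveforms and the outlet pressure boundary model.

Two inflow protocols are provided: a constant flat-profile transmitral
velocity (0.55 m/s by default, a normal peak transmitral value) with an
optional linear start-up ramp, and a synthetic biphasic E-A diastolic wave
built from two raised cosines separated by diastasis.  The outlet model is a
resistive Windkessel-style condition: baseline arterial pressure plus an
outflow resistance times the instantaneous volumetric flow rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad


class WaveformError(ValueError):
    """Raised for inconsistent waveform parameters."""


@dataclass
class EAWaveParams:
    """Raised-cosine E and A wave timing/amplitude parameters (s, m/s).

    The default pattern is a healthy transmitral profile: a 0.55 m/s E wave
    over the first 0.25 s, diastasis, then a 0.35 m/s A wave of 0.15 s within
    a 0.8 s beat, with each peak at its interval midpoint.
    """

    A_E: float = 0.55
    A_A: float = 0.35
    t0_E: float = 0.0
    t1_E: float = 0.25
    tp_E: float = 0.125
    t0_A: float = 0.45
    t1_A: float = 0.60
    tp_A: float = 0.525
    period: float = 0.8

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.A_E < 0 or self.A_A < 0:
            raise WaveformError("wave amplitudes must be >= 0")
        ok = (self.t0_E < self.tp_E < self.t1_E <= self.t0_A
              < self.tp_A < self.t1_A)
        if not ok:
            raise WaveformError(
                "wave times must satisfy t0_E < tp_E < t1_E <= t0_A < tp_A "
                f"< t1_A, got ({self.t0_E}, {self.tp_E}, {self.t1_E}, "
                f"{self.t0_A}, {self.tp_A}, {self.t1_A})")
        if self.period < self.t1_A:
            raise WaveformError("period must cover the A wave")


def ea_wave(t, params: EAWaveParams):
    """Biphasic transmitral velocity at time ``t`` (scalar or array).

    Each wave is (A/2)(1 + cos(2 pi (t - tp) / (t1 - t0))) on its interval;
    the value is exactly zero in diastasis and outside both waves, and the
    profile is continuous when each peak is its interval midpoint.
    """
    t = np.asarray(t, dtype=float)
    v = np.zeros_like(t)
    for a, t0, t1, tp in ((params.A_E, params.t0_E, params.t1_E, params.tp_E),
                          (params.A_A, params.t0_A, params.t1_A, params.tp_A)):
        m = (t >= t0) & (t <= t1)
        v = np.where(m, 0.5 * a * (1 + np.cos(2 * np.pi * (t - tp) / (t1 - t0))),
                     v)
    return v if v.ndim else float(v)


@dataclass
class ConstantInflow:
    """Flat-profile constant inflow with a linear start-up ramp."""

    speed: float = 0.55
    ramp: float = 0.02

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.ramp > 0:
            v = self.speed * np.clip(t / self.ramp, 0.0, 1.0)
        else:
            v = np.full_like(t, self.speed)
        return v if v.ndim else float(v)


def constant_inflow(t, speed: float = 0.55, ramp: float = 0.0):
    return ConstantInflow(speed, ramp)(t)


@dataclass
class OutletModel:
    """Outlet pressure: baseline plus resistance times flow rate."""

    baseline_pressure: float = 10700.0   # Pa (80 mmHg)
    resistance: float = 6.0e6           # Pa s / m^3

    def validate(self) -> None:
        if self.baseline_pressure < 0 or self.resistance < 0:
            raise WaveformError("baseline_pressure and resistance must be >= 0")


def outlet_pressure(flow_rate: float, model: OutletModel) -> float:
    """P = baseline_pressure + resistance * flow_rate (Pa)."""
    return model.baseline_pressure + model.resistance * flow_rate


def stroke_volume(params: EAWaveParams, inlet_area: float) -> float:
    """Volume through the inlet over one beat, by adaptive quadrature (m^3)."""
    total = 0.0
    for t0, t1 in ((params.t0_E, params.t1_E), (params.t0_A, params.t1_A)):
        val, _ = quad(lambda s: ea_wave(s, params), t0, t1, limit=200)
        total += val
    return total * inlet_area
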