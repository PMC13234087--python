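"""Heart chamber models: time-varying elastance and prescribed volume.

Elastance chambers follow P = [E_min + (E_max - E_min) * a(t)] * (V - V0)
with a smooth raised-cosine activation a(t) in [0, 1], periodic with the
cycle length T.  Prescribed-volume chambers interpolate an imaging-derived
volume waveform with a periodic cubic spline; their pressure is left to the
network flow balance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "raised_cosine_activation",
    "ElastanceChamber",
    "PrescribedVolumeChamber",
    "elastance_pressure",
    "prescribed_volume",
]


def raised_cosine_activation(t, period: float, onset: float, tau_rise: float,
                             tau_fall: float):
    """Smooth periodic activation: 0 -> 1 over tau_rise, 1 -> 0 over tau_fall.

    C1-smooth (zero slope at the joints), which keeps the implicit Newton
    solve well conditioned.  All times in seconds.
    """
    s = np.mod(np.asarray(t, dtype=float) - onset, period)
    rise = 0.5 * (1.0 - np.cos(np.pi * np.clip(s / tau_rise, 0.0, 1.0)))
    fall = 0.5 * (1.0 + np.cos(
        np.pi * np.clip((s - tau_rise) / tau_fall, 0.0, 1.0)))
    a = np.where(s < tau_rise, rise, fall)
    return a if a.ndim else float(a)


@dataclass
class ElastanceChamber:
    """Contracting chamber with linear, time-varying elastance (Pa/mm^3)."""

    e_max: float
    e_min: float
    v0: float                 # unstressed volume, mm^3
    period: float = 1.0
    activation_onset: float = 0.6
    tau_rise: float = 0.2
    tau_fall: float = 0.18
    mode: str = "elastance"

    def __post_init__(self) -> None:
        if not (self.e_max >= self.e_min > 0):
            raise ValueError("need E_max >= E_min > 0")

    def activation(self, t):
        return raised_cosine_activation(
            t, self.period, self.activation_onset, self.tau_rise, self.tau_fall
        )

    def elastance(self, t):
        return self.e_min + (self.e_max - self.e_min) * self.activation(t)

    def pressure(self, v, t):
        return self.elastance(t) * (np.asarray(v, dtype=float) - self.v0)


@dataclass
class PrescribedVolumeChamber:
    """Chamber whose volume waveform is prescribed (imaging-derived).

    ``times`` (s) must span one period starting at 0; ``volumes`` (mm^3)
    must close periodically (first == last within ``periodic_tol`` relative).
    """

    times: np.ndarray
    volumes: np.ndarray
    period: Optional[float] = None
    periodic_tol: float = 1.0e-6
    mode: str = "prescribed_volume"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.volumes, dtype=float).copy()
        if t.ndim != 1 or t.size < 4 or np.any(np.diff(t) <= 0):
            raise ValueError("waveform times must be increasing, >= 4 samples")
        if self.period is None:
            self.period = float(t[-1])
        if abs(t[-1] - self.period) > 1e-9 * self.period or t[0] != 0.0:
            raise ValueError("waveform must cover exactly [0, period]")
        scale = max(abs(v[0]), abs(v[-1]), 1.0)
        if abs(v[-1] - v[0]) > self.periodic_tol * scale:
            raise ValueError(
                f"waveform is not periodic: V(0)={v[0]} vs V(T)={v[-1]}"
            )
        v[-1] = v[0]  # close exactly for the periodic spline
        self.times = t
        self.volumes = v
        self._spline = CubicSpline(t, v, bc_type="periodic")
        self._dspline = self._spline.derivative()

    def volume(self, t):
        return self._spline(np.mod(t, self.period))

    def dvdt(self, t):
        return self._dspline(np.mod(t, self.period))

    def increment(self, t0: float, t1: float) -> float:
        """Exact volume change V(t1) - V(t0) of the interpolant."""
        return float(self.volume(t1) - self.volume(t0))

    @classmethod
    def from_table(cls, table, period=None, volume_unit_mm3: float = 1.0):
        """Build from a 2-column array-like (t_seconds, volume)."""
        arr = np.asarray(table, dtype=float)
        return cls(arr[:, 0], arr[:, 1] * volume_unit_mm3, period=period)


def elastance_pressure(chamber, v, t):
    """Pressure of an elastance chamber (Pa); errors on prescribed chambers."""
    if getattr(chamber, "mode", None) != "elastance":
        raise TypeError("elastance_pressure requires an elastance-mode chamber")
    return chamber.pressure(v, t)


def prescribed_volume(chamber, t):
    """(volume, dV/dt) of a prescribed-volume chamber at time t."""
    if getattr(chamber, "mode", None) != "prescribed_volume":
        raise TypeError("prescribed_volume requires a prescribed-volume chamber")
    return chamber.volume(t), chamber.dvdt(t)
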