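"""Valve opening/closing dynamics, orifice geometry and transvalvular flow.

Each valve carries a dimensionless opening state ``g`` in [0, 1] governed by

    dg/dt = C1 * sgn(alpha) / 2 * [1 + alpha * (1 - 2 g)],

where the switching variable ``alpha = tanh[C2*dP + C3*(Q + tau*dQ/dt)]``
(tau = 1 s keeps the bracket in mm^3/s) encodes the forward-driving
transvalvular pressure difference and the flow/deceleration state.  For
regurgitant valves the effective opening is floored at ``g_min``, derived
from the regurgitant orifice area, so the valve never seals completely.
Valve repair is modeled by setting ``g_min = 0``.

The fully open orifice is an ellipse with semi-axes ``l_a, l_b`` (a circle
when equal); the effective open area scales as ``A(G) = pi*l_a*l_b*G^2``
(semi-axes shrink proportionally with G).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import BloodProperties

__all__ = [
    "ValveGeometry",
    "ValveState",
    "g_min_from_roa",
    "effective_area",
    "alpha",
    "valve_rhs",
    "orifice_flow",
]

#: timescale making C3*(Q + tau*dQ/dt) dimensionally consistent (s).  The
#: derivative term anticipates flow reversal; ~20 ms (the scale of the
#: isovolumic phases and of the blood column's inertia at the annulus) lets
#: it trigger closure at end-ejection/end-filling without overpowering the
#: flow term during ordinary E-wave deceleration.
FLOW_RATE_TIMESCALE = 0.02


@dataclass(frozen=True)
class ValveGeometry:
    """Fully open orifice geometry; semi-axes in mm."""

    l_a: float
    l_b: float
    shape: str = "ellipse"

    def __post_init__(self) -> None:
        if not (self.l_a >= self.l_b > 0):
            raise ValueError(f"need l_a >= l_b > 0, got ({self.l_a}, {self.l_b})")
        if self.shape not in ("ellipse", "circle"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.shape == "circle" and self.l_a != self.l_b:
            raise ValueError("circular valve requires l_a == l_b")

    @property
    def full_open_area(self) -> float:
        """pi * l_a * l_b, mm^2."""
        return np.pi * self.l_a * self.l_b

    @classmethod
    def circle(cls, radius_mm: float) -> "ValveGeometry":
        return cls(radius_mm, radius_mm, "circle")


@dataclass
class ValveState:
    """Dynamic state and switching constants of one valve.

    C1 (1/s) sets the transition speed, C2 (1/Pa) the pressure sensitivity
    and C3 (s/mm^3) the flow/deceleration sensitivity.
    """

    geometry: ValveGeometry
    g: float = 1.0
    g_min: float = 0.0
    c1: float = 800.0
    c2: float = 0.001
    c3: float = 0.0001
    tau_q: float = FLOW_RATE_TIMESCALE   # s; anticipation horizon of dQ/dt

    def __post_init__(self) -> None:
        if not (0.0 <= self.g_min <= 1.0):
            raise ValueError(f"g_min must be in [0,1], got {self.g_min}")
        self.g = float(np.clip(self.g, 0.0, 1.0))

    @property
    def effective_opening(self) -> float:
        """G = max(g, g_min)."""
        return max(self.g, self.g_min)


def g_min_from_roa(roa: float, geom: ValveGeometry) -> float:
    """Opening-state floor reproducing a regurgitant orifice area (mm^2).

    Inverse of :func:`effective_area`: the g at which the effective open
    area equals ``roa``.
    """
    full = geom.full_open_area
    if roa < 0 or roa > full:
        raise ValueError(
            f"regurgitant orifice area {roa} mm^2 outside [0, {full:.2f}] mm^2"
        )
    return float(np.sqrt(roa / full))


def effective_area(g, geom: ValveGeometry):
    """Open orifice area pi*l_a*l_b*G^2 (mm^2) at opening state g."""
    return geom.full_open_area * np.square(g)


def alpha(dp_forward, q, dqdt, c2: float = 0.001, c3: float = 0.0001,
          tau: float = FLOW_RATE_TIMESCALE):
    """Switching variable in (-1, 1); positive drives the valve open.

    dp_forward is the forward-driving pressure difference (upstream minus
    downstream, Pa), q the transvalvular flow (mm^3/s, positive forward)
    and dqdt its time derivative (mm^3/s^2).
    """
    return np.tanh(c2 * dp_forward + c3 * (q + tau * dqdt))


def valve_rhs(g, a, c1: float = 800.0, sgn_eps: float = 0.0):
    """dg/dt of the valve-state ODE.

    With ``sgn_eps == 0`` the exact sign function is used (sgn(0) = 0);
    a positive ``sgn_eps`` smooths it as tanh(a/sgn_eps) for Newton
    differentiability inside the implicit solver.
    """
    s = np.sign(a) if sgn_eps == 0.0 else np.tanh(np.asarray(a) / sgn_eps)
    return 0.5 * c1 * s * (1.0 + a * (1.0 - 2.0 * np.asarray(g)))


def orifice_flow(p_up, p_down, area, blood: BloodProperties, dp_eps: float = 0.0):
    """Bernoulli orifice flow (mm^3/s), odd in the pressure difference.

    Q = sign(dP) * area * sqrt(2|dP|/rho).  A positive ``dp_eps`` (Pa)
    regularizes the square-root slope at dP = 0 for implicit solves:
    Q = area * dP * sqrt(2/(rho*(|dP|+dp_eps))); the relative error is
    below dp_eps/|dP| away from the crossing.
    """
    if np.any(np.asarray(area) < 0):
        raise ValueError("orifice area must be non-negative")
    dp = np.asarray(p_up, dtype=float) - np.asarray(p_down, dtype=float)
    rho = blood.density
    if dp_eps > 0.0:
        return area * dp * np.sqrt(2.0 / (rho * (np.abs(dp) + dp_eps)))
    return area * np.sign(dp) * np.sqrt(2.0 * np.abs(dp) / rho)
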