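"""Continuous-flow LVAD model: cubic pressure-flow (H-Q) characteristic.

The pump head dP = A + B*Q + C*Q^2 + D*Q^3 (Pa, with Q in mm^3/s) is the
static characteristic at a fixed operating speed.  Default coefficients are
for a HeartMate 3 at 5400 RPM.  The characteristic must be strictly
monotone decreasing in Q so that the flow at a given head is unique; this
is verified at construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = ["PumpHQ", "hq_dp", "hq_invert"]


@dataclass(frozen=True)
class PumpHQ:
    a: float = 14306.0      # Pa
    b: float = -0.05        # Pa*s/mm^3
    c: float = 4.0e-7       # Pa*s^2/mm^6
    d: float = -8.0e-12     # Pa*s^3/mm^9
    speed_rpm: float = 5400.0

    def __post_init__(self) -> None:
        if not self._is_strictly_decreasing():
            raise ValueError(
                "H-Q coefficients are not strictly monotone decreasing in Q; "
                "the flow at a given head would be non-unique "
                f"(A={self.a}, B={self.b}, C={self.c}, D={self.d})"
            )

    def _is_strictly_decreasing(self) -> bool:
        # d(HQ)/dQ = B + 2C Q + 3D Q^2 must be < 0 for all real Q
        b, c, d = self.b, self.c, self.d
        if d == 0.0:
            if c == 0.0:
                return b < 0.0
            return False  # genuine quadratic derivative is a line: changes sign
        if 3.0 * d > 0.0:
            return False  # upward parabola is eventually positive
        disc = (2.0 * c) ** 2 - 4.0 * (3.0 * d) * b
        return disc < 0.0

    def dp(self, q):
        return hq_dp(self, q)

    def flow(self, dp: float) -> float:
        return hq_invert(self, dp)


def hq_dp(pump: PumpHQ, q):
    """Pressure head across the pump (Pa) at flow q (mm^3/s)."""
    q = np.asarray(q, dtype=float)
    out = pump.a + q * (pump.b + q * (pump.c + q * pump.d))
    return out if out.ndim else float(out)


def hq_invert(pump: PumpHQ, dp: float, tol_factor: float = 1.0e-8) -> float:
    """Unique flow (mm^3/s) at which the pump head equals ``dp`` (Pa).

    Root-found by bracketing + Brent's method (safeguarded), then polished
    with one Newton step; |residual| < tol_factor * A at return.
    """

    def resid(q: float) -> float:
        return hq_dp(pump, q) - dp

    # expand a bracket around 0; the characteristic is strictly decreasing
    lo, hi = -1.0e5, 1.0e5
    while resid(lo) < 0.0:
        lo *= 2.0
        if lo < -1.0e12:
            raise RuntimeError("failed to bracket H-Q inversion (low side)")
    while resid(hi) > 0.0:
        hi *= 2.0
        if hi > 1.0e12:
            raise RuntimeError("failed to bracket H-Q inversion (high side)")
    q = brentq(resid, lo, hi, xtol=1.0e-10, rtol=8.9e-16)
    # Newton polish
    slope = pump.b + 2.0 * pump.c * q + 3.0 * pump.d * q * q
    if slope != 0.0:
        q -= resid(q) / slope
    if abs(resid(q)) > tol_factor * abs(pump.a):
        raise RuntimeError(f"H-Q inversion residual {resid(q):.3e} Pa too large")
    return float(q)
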