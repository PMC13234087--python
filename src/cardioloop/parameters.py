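"""Blood properties and the 23-entry personalizable parameter vector.

The circulation is an RLC circuit analogue: resistances in Pa*s/mm^3,
compliances in mm^3/Pa, inductances in Pa*s^2/mm^3, chamber elastances in
Pa/mm^3 and regurgitant orifice areas (ROA) in mm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Dict, Iterator

import numpy as np

__all__ = ["BloodProperties", "ParameterVector", "PARAMETER_NAMES"]


@dataclass(frozen=True)
class BloodProperties:
    """Bulk blood properties used by the orifice flow law.

    density is in g/mm^3 (1.026 g/mL = 1.026e-3 g/mm^3 so that
    0.5*rho*v^2 with v in mm/s gives Pa); viscosity in Pa*s.
    """

    density: float = 1.026e-3
    viscosity: float = 0.004

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("blood density and viscosity must be positive")


# The 23 scalars exposed to the personalization layer.  Chamber activation
# timings are fixed chamber settings, not fitted parameters.
@dataclass
class ParameterVector:
    # systemic circulation
    z_sys_prox: float = 0.007     # proximal (characteristic) impedance, Pa*s/mm^3
    c_sys_ar: float = 11.0        # arterial compliance, mm^3/Pa
    r_sys_dist: float = 0.13      # distal arterial resistance, Pa*s/mm^3
    l_sys_ar: float = 5.0e-5      # arterial inductance, Pa*s^2/mm^3
    r_sys_ven: float = 0.017      # venous resistance, Pa*s/mm^3
    c_sys_ven: float = 450.0      # venous compliance, mm^3/Pa
    # pulmonary circulation
    r_pul_ar: float = 0.016
    c_pul_ar: float = 30.0
    l_pul_ar: float = 5.0e-5
    r_pul_ven: float = 0.004
    c_pul_ven: float = 60.0
    l_pul_ven: float = 5.0e-5
    # coronary circulation
    r_cor_prox: float = 1.7
    r_cor_dist: float = 3.4
    c_cor: float = 2.0
    # right-heart elastances, Pa/mm^3
    e_ra_max: float = 0.040
    e_ra_min: float = 0.020
    e_rv_max: float = 0.0667
    e_rv_min: float = 0.00667
    # regurgitant orifice areas, mm^2
    roa_tv: float = 25.0
    roa_pv: float = 5.0
    roa_mv: float = 44.0
    roa_av: float = 6.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name.startswith("roa_"):
                if v < 0:
                    raise ValueError(f"{f.name} must be >= 0, got {v}")
            elif v <= 0:
                raise ValueError(f"{f.name} must be > 0, got {v}")

    # dict-like access so the fitter can treat theta as a named map
    def __getitem__(self, name: str) -> float:
        return getattr(self, name)

    def __iter__(self) -> Iterator[str]:
        return iter(PARAMETER_NAMES)

    def as_dict(self) -> Dict[str, float]:
        return {name: getattr(self, name) for name in PARAMETER_NAMES}

    def as_array(self, names=None) -> np.ndarray:
        names = PARAMETER_NAMES if names is None else names
        return np.array([getattr(self, n) for n in names], dtype=float)

    def with_values(self, **updates: float) -> "ParameterVector":
        return replace(self, **updates)

    def with_array(self, values, names=None) -> "ParameterVector":
        names = PARAMETER_NAMES if names is None else names
        return replace(self, **dict(zip(names, (float(v) for v in values))))


PARAMETER_NAMES = tuple(f.name for f in fields(ParameterVector))
assert len(PARAMETER_NAMES) == 23
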