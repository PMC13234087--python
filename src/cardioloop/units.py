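"""Unit conversion constants.

Internal units throughout the solver are Pa (pressure), mm^3 (volume) and
mm^3/s (flow); the pump H-Q coefficients are published in these units.
User-facing interfaces use mmHg, mL and L/min.
"""

MMHG_TO_PA = 133.32239
PA_TO_MMHG = 1.0 / MMHG_TO_PA

ML_TO_MM3 = 1000.0
MM3_TO_ML = 1.0 / ML_TO_MM3

L_TO_MM3 = 1.0e6

LMIN_TO_MM3S = 1.0e6 / 60.0   # L/min -> mm^3/s
MM3S_TO_LMIN = 60.0 / 1.0e6

MMS_TO_CMS = 0.1              # mm/s -> cm/s


def mmhg(value_pa: float) -> float:
    """Pa -> mmHg."""
    return value_pa * PA_TO_MMHG


def pa(value_mmhg: float) -> float:
    """mmHg -> Pa."""
    return value_mmhg * MMHG_TO_PA
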