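"""Per-cycle clinical metrics: regurgitant volumes, forward cardiac output,
pulse pressure, pressure-volume loop indices and an E-wave velocity proxy.

Forward cardiac output is defined as the mean systemic inflow at the aortic
root: pump flow plus net aortic-valve flow (the AV contribution is negative
under pure aortic regurgitation).  All integrals are trapezoid sums on the
cycle grid, so the forward/regurgitant decomposition of any valve flow is
exactly consistent with its net integral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .units import MM3_TO_ML, MM3S_TO_LMIN, MMS_TO_CMS, PA_TO_MMHG
from .valves import ValveGeometry, effective_area

__all__ = [
    "CycleMetrics", "regurgitant_volume", "forward_volume", "forward_co",
    "pulse_pressure", "pv_loop", "e_wave_proxy", "cycle_metrics",
]


@dataclass
class CycleMetrics:
    """Derived quantities of one cardiac cycle (clinical units)."""

    regurgitant_volume_ml: Dict[str, float]   # per valve, mL/beat
    forward_co_lmin: float
    pump_flow_lmin: float
    aortic_pulse_pressure_mmhg: float
    lvedp_mmhg: float
    chamber: Dict[str, Dict[str, float]]      # EDV/ESV/SV/EF per chamber, mL
    e_wave_cm_s: Optional[float]
    extras: Dict[str, float] = field(default_factory=dict)

    def as_flat_dict(self) -> Dict[str, float]:
        out = {
            "forward_co_lmin": self.forward_co_lmin,
            "pump_flow_lmin": self.pump_flow_lmin,
            "aortic_pulse_pressure_mmhg": self.aortic_pulse_pressure_mmhg,
            "lvedp_mmhg": self.lvedp_mmhg,
            "e_wave_cm_s": math.nan if self.e_wave_cm_s is None else self.e_wave_cm_s,
        }
        for v, val in self.regurgitant_volume_ml.items():
            out[f"{v}_regurgitant_volume_ml"] = val
        for ch, d in self.chamber.items():
            for k, val in d.items():
                out[f"{ch}_{k}"] = val
        out.update(self.extras)
        return out


def regurgitant_volume(record, valve_id: str, forward_sign: float = 1.0) -> float:
    """Backward volume through a valve over one cycle, mL/beat."""
    q = forward_sign * np.asarray(record[f"q_{valve_id}"], dtype=float)
    back = np.clip(-q, 0.0, None)
    return float(np.trapezoid(back, record.t)) * MM3_TO_ML


def forward_volume(record, valve_id: str, forward_sign: float = 1.0) -> float:
    """Forward volume through a valve over one cycle, mL/beat."""
    q = forward_sign * np.asarray(record[f"q_{valve_id}"], dtype=float)
    return float(np.trapezoid(np.clip(q, 0.0, None), record.t)) * MM3_TO_ML


def forward_co(record) -> float:
    """Forward cardiac output (pump + net aortic valve flow), L/min."""
    net = np.trapezoid(record["q_vad"] + record["q_av"], record.t)
    return float(net / record.period) * MM3S_TO_LMIN


def pump_flow_mean(record) -> float:
    return float(np.trapezoid(record["q_vad"], record.t) / record.period) * MM3S_TO_LMIN


def pulse_pressure(record, node: str = "p_ao") -> float:
    """Peak-to-trough pressure excursion at a node over one cycle, mmHg."""
    p = np.asarray(record[node], dtype=float)
    return float(p.max() - p.min()) * PA_TO_MMHG


def pv_loop(record, chamber: str):
    """(V, P) loop and EDV/ESV/SV/EF with end diastole at maximum volume.

    ``chamber`` is one of lv, rv, la, ra.  Returns (loop, indices) where
    loop is an (n, 2) array of (V mL, P mmHg) pairs and indices a dict with
    edv/esv/sv/ef (mL and fraction), edp (mmHg) and a ``degenerate`` flag
    for constant-volume chambers.
    """
    v = np.asarray(record[f"v_{chamber}"], dtype=float) * MM3_TO_ML
    p = np.asarray(record[f"p_{chamber}"], dtype=float) * PA_TO_MMHG
    loop = np.column_stack([v, p])
    i_ed, i_es = int(np.argmax(v)), int(np.argmin(v))
    edv, esv = v[i_ed], v[i_es]
    sv = edv - esv
    degenerate = sv <= 1e-9 * max(edv, 1.0)
    indices = {
        "edv_ml": float(edv), "esv_ml": float(esv), "sv_ml": float(sv),
        "ef": float(sv / edv) if edv > 0 else math.nan,
        "edp_mmhg": float(p[i_ed]),
        "peak_pressure_mmhg": float(p.max()),
        "degenerate": bool(degenerate),
    }
    return loop, indices


def e_wave_proxy(record, mv_geometry: ValveGeometry,
                 open_threshold: float = 0.5,
                 early_fraction: float = 0.5) -> Optional[float]:
    """Peak early-diastolic transmitral velocity proxy, cm/s.

    Velocity = Q_MV / effective_area(g_MV) while the mitral valve is open
    with forward flow; the peak is taken over the early part (default first
    half) of the longest open span.  Returns None if the valve never opens.
    """
    g = np.asarray(record["g_mv"], dtype=float)
    q = np.asarray(record["q_mv"], dtype=float)
    is_open = g >= open_threshold
    if not np.any(is_open):
        return None
    # longest contiguous open span (wrap not needed on a one-cycle record)
    idx = np.flatnonzero(is_open)
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    span = max(splits, key=len)
    early = span[: max(1, int(math.ceil(early_fraction * len(span))))]
    vel = np.clip(q[early], 0.0, None) / effective_area(g[early], mv_geometry)
    return float(vel.max()) * MMS_TO_CMS  # mm/s -> cm/s


def valve_closure_duration(record, valve_id: str, g_floor: float,
                           open_level: float = 0.99,
                           closed_offset: float = 0.01) -> Optional[float]:
    """Duration of a valve's closing transition within one cycle (s).

    Measured from the last sample with g >= open_level before the first
    sample with g <= g_floor + closed_offset.  Returns None if the valve
    never closes (or never opens) during the record.
    """
    g = np.asarray(record[f"g_{valve_id}"], dtype=float)
    t = np.asarray(record.t, dtype=float)
    closed = np.flatnonzero(g <= g_floor + closed_offset)
    if closed.size == 0:
        return None
    i_end = int(closed[0])
    open_idx = np.flatnonzero(g[:i_end] >= open_level)
    if open_idx.size == 0:
        return None
    return float(t[i_end] - t[int(open_idx[-1])])


def cycle_metrics(record, network) -> CycleMetrics:
    """Bundle all per-cycle metrics for a simulated cycle."""
    regurg = {v: regurgitant_volume(record, v) for v in ("mv", "av", "tv", "pv")}
    chamber = {}
    for ch in ("lv", "rv"):
        _, idx = pv_loop(record, ch)
        chamber[ch] = idx
    _, lv_idx = pv_loop(record, "lv")
    extras = {
        "coronary_flow_ml_min": float(
            np.trapezoid(record["q_cor"], record.t) / record.period
        ) * MM3_TO_ML * 60.0,
        "map_mmhg": record.mean("p_sys_ar") * PA_TO_MMHG,
        "pa_mean_mmhg": record.mean("p_pul_ar") * PA_TO_MMHG,
        "pcwp_mmhg": record.mean("p_pul_ven") * PA_TO_MMHG,
        "ra_mean_mmhg": record.mean("p_ra") * PA_TO_MMHG,
    }
    return CycleMetrics(
        regurgitant_volume_ml=regurg,
        forward_co_lmin=forward_co(record),
        pump_flow_lmin=pump_flow_mean(record),
        aortic_pulse_pressure_mmhg=pulse_pressure(record, "p_ao"),
        lvedp_mmhg=lv_idx["edp_mmhg"],
        chamber=chamber,
        e_wave_cm_s=e_wave_proxy(record, network.valves["mv"].geometry),
        extras=extras,
    )
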