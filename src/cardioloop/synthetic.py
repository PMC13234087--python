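"""Synthetic-patient fixture generator.

Produces everything a download-free end-to-end run needs: smooth periodic
LA/LV volume waveforms (emulating dynamic-CT-derived chamber volumes of an
LVAD-supported failing heart with minimal wall deformation), a ground-truth
parameter vector, the assembled closed-loop network, and a noisy clinical
target table for the personalization loop.

The default patient mirrors the regime of an LVAD-supported heart with
mitral and aortic regurgitation: MV regurgitant orifice area 44 mm^2
(elliptical annulus 17 x 9 mm), AV 6 mm^2 (circular annulus radius 13 mm),
moderate tricuspid and mild pulmonary regurgitation, and a HeartMate 3 at
5400 RPM.  At baseline the aortic valve stays closed (the leaky mitral
valve absorbs ejection at low LV pressure); repairing the MV forces LV
systolic pressure above aortic pressure and opens the AV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .chambers import ElastanceChamber, PrescribedVolumeChamber
from .metrics import cycle_metrics, pv_loop
from .network import CirculationNetwork, IntegratorConfig
from .parameters import BloodProperties, ParameterVector
from .personalization import ClinicalTargets, TargetEntry, nadler_blood_volume
from .pump import PumpHQ
from .solver import run_cycles
from .units import L_TO_MM3, ML_TO_MM3, MM3_TO_ML
from .valves import ValveGeometry, ValveState, g_min_from_roa

__all__ = ["SyntheticPatientSpec", "SimSettings", "volume_waveforms",
           "build_network", "make_targets", "TARGET_UNITS"]


VALVE_GEOMETRY = {
    "mv": ValveGeometry(17.0, 9.0, "ellipse"),
    "av": ValveGeometry.circle(13.0),
    "tv": ValveGeometry.circle(15.0),
    "pv": ValveGeometry.circle(11.0),
}


@dataclass
class SimSettings:
    """Simulation settings shared by target generation and fitting."""

    cfg: IntegratorConfig = field(default_factory=IntegratorConfig)
    n_min_cycles: int = 3
    max_cycles: int = 12
    periodicity_threshold: float = 0.05

    @classmethod
    def reduced(cls) -> "SimSettings":
        """Coarse settings for optimization loops (dt = 4 ms)."""
        return cls(cfg=IntegratorConfig(dt=4.0e-3), max_cycles=8)


@dataclass
class SyntheticPatientSpec:
    period: float = 1.0             # s
    lv_edv: float = 180.0           # mL
    lv_esv: float = 155.0           # mL (small stroke: failing, unloaded LV)
    la_vmax: float = 90.0           # mL
    la_vmin: float = 60.0           # mL
    sample_dt: float = 0.01         # s (emulates 10 CT phases, upsampled)
    height_m: float = 1.75
    weight_kg: float = 80.0
    sex: str = "male"
    lv_mass_g: float = 150.0
    theta_star: ParameterVector = field(default_factory=ParameterVector)
    valve_severity: Dict[str, str] = field(default_factory=lambda: {
        "mv": "severe", "av": "mild", "tv": "moderate", "pv": "mild"})
    pump: PumpHQ = field(default_factory=PumpHQ)
    k_im: float = 0.5
    noise_level: float = 0.05
    seed: int = 0
    v_un_sys_ven: Optional[float] = None   # mm^3; balanced to Nadler if None

    def __post_init__(self) -> None:
        if not (self.lv_edv > self.lv_esv > 0):
            raise ValueError("need EDV > ESV > 0")
        if not (self.la_vmax > self.la_vmin > 0):
            raise ValueError("need LA vmax > vmin > 0")


def _eased_segments(knots_t, knots_v, t):
    """C1 piecewise raised-cosine interpolation through (t, V) knots."""
    v = np.empty_like(t)
    for (t0, v0), (t1, v1) in zip(zip(knots_t[:-1], knots_v[:-1]),
                                  zip(knots_t[1:], knots_v[1:])):
        m = (t >= t0) & (t <= t1)
        s = (t[m] - t0) / (t1 - t0)
        v[m] = v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * s))
    return v


def volume_waveforms(spec: SyntheticPatientSpec) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """LV and LA volume tables (t_seconds, volume_mL) over one period.

    t = 0 is the onset of ventricular diastole.  LV: early filling,
    diastasis, atrial kick to EDV at 0.60 T, then ejection back to ESV;
    LA: reciprocally phased reservoir.  Deterministic (no randomness).
    """
    T = spec.period
    t = np.round(np.arange(0.0, T + 0.5 * spec.sample_dt, spec.sample_dt), 12)
    sv = spec.lv_edv - spec.lv_esv
    lv_knots_t = np.array([0.0, 0.25, 0.45, 0.60, 0.63, 0.94, 1.0]) * T
    lv_knots_v = spec.lv_esv + sv * np.array([0.0, 0.70, 0.78, 1.0, 1.0, 0.0, 0.0])
    la_r = spec.la_vmax - spec.la_vmin
    la_knots_t = np.array([0.0, 0.25, 0.45, 0.60, 0.63, 0.95, 1.0]) * T
    la_knots_v = spec.la_vmin + la_r * np.array([1.0, 0.45, 0.30, 0.0, 0.0, 1.0, 1.0])
    lv = pd.DataFrame({"t_seconds": t,
                       "volume_mL": _eased_segments(lv_knots_t, lv_knots_v, t)})
    la = pd.DataFrame({"t_seconds": t,
                       "volume_mL": _eased_segments(la_knots_t, la_knots_v, t)})
    return lv, la


def resolve(spec: SyntheticPatientSpec) -> SyntheticPatientSpec:
    """Fix the venous unstressed volume so TBV(theta*) matches Nadler."""
    if spec.v_un_sys_ven is not None:
        return spec
    trial = replace(spec, v_un_sys_ven=0.0)
    net = build_network(trial)
    y0 = net.initial_state()
    tbv0 = net.total_blood_volume(y0, 0.0)
    target = nadler_blood_volume(spec.height_m, spec.weight_kg, spec.sex) * L_TO_MM3
    v_un = target - tbv0
    if v_un <= 0:
        raise ValueError("Nadler volume too small for the configured circulation")
    return replace(spec, v_un_sys_ven=float(v_un))


def build_network(spec: SyntheticPatientSpec,
                  params: Optional[ParameterVector] = None, *,
                  gmin_overrides: Optional[Dict[str, float]] = None
                  ) -> CirculationNetwork:
    """Assemble the closed-loop network of a (possibly re-parameterized)
    synthetic patient.  ``gmin_overrides`` models valve repair (g_min = 0)."""
    params = spec.theta_star if params is None else params
    T = spec.period
    lv_tab, la_tab = volume_waveforms(spec)
    lv = PrescribedVolumeChamber(lv_tab["t_seconds"].to_numpy(),
                                 lv_tab["volume_mL"].to_numpy() * ML_TO_MM3)
    la = PrescribedVolumeChamber(la_tab["t_seconds"].to_numpy(),
                                 la_tab["volume_mL"].to_numpy() * ML_TO_MM3)
    ra = ElastanceChamber(params.e_ra_max, params.e_ra_min, v0=10.0e3, period=T,
                          activation_onset=0.45 * T, tau_rise=0.08 * T,
                          tau_fall=0.10 * T)
    rv = ElastanceChamber(params.e_rv_max, params.e_rv_min, v0=20.0e3, period=T,
                          activation_onset=0.60 * T, tau_rise=0.20 * T,
                          tau_fall=0.18 * T)
    roas = {"mv": params.roa_mv, "av": params.roa_av,
            "tv": params.roa_tv, "pv": params.roa_pv}
    overrides = gmin_overrides or {}
    valves = {}
    for name, geom in VALVE_GEOMETRY.items():
        g_min = g_min_from_roa(roas[name], geom)
        if name in overrides:
            g_min = float(overrides[name])
        valves[name] = ValveState(geometry=geom, g=1.0, g_min=g_min)
    v_un = {"sys_ar": 4.0e5, "pul_ar": 5.0e4, "pul_ven": 3.5e5, "cor": 5.0e3,
            "sys_ven": spec.v_un_sys_ven if spec.v_un_sys_ven is not None else 2.8e6}
    return CirculationNetwork(params, la, lv, ra, rv, valves, spec.pump,
                              blood=BloodProperties(), k_im=spec.k_im,
                              v_unstressed=v_un, period=T)


# --- clinical targets ---------------------------------------------------------
TARGET_UNITS = {
    "sys_sbp": "mmHg", "sys_dbp": "mmHg", "sys_map": "mmHg",
    "pa_sys": "mmHg", "pa_dia": "mmHg", "pa_mean": "mmHg",
    "pcwp": "mmHg", "ra_mean": "mmHg", "rv_edp": "mmHg",
    "forward_co": "L/min", "pump_flow": "L/min",
    "rv_edv": "mL", "rv_esv": "mL", "lvedp": "mmHg",
    "aortic_pulse_pressure": "mmHg",
    "mv_regurg_vol": "mL", "av_regurg_vol": "mL", "tv_regurg_vol": "mL",
    "coronary_flow": "mL/min", "e_wave": "cm/s",
}


def targets_from_cycle(record, network) -> Dict[str, float]:
    """The canonical 20 named clinical quantities from one converged cycle."""
    from .units import PA_TO_MMHG

    m = cycle_metrics(record, network)
    _, rv_idx = pv_loop(record, "rv")
    p_sys = np.asarray(record["p_sys_ar"]) * PA_TO_MMHG
    p_pa = np.asarray(record["p_pul_ar"]) * PA_TO_MMHG
    vals = {
        "sys_sbp": float(p_sys.max()),
        "sys_dbp": float(p_sys.min()),
        "sys_map": m.extras["map_mmhg"],
        "pa_sys": float(p_pa.max()),
        "pa_dia": float(p_pa.min()),
        "pa_mean": m.extras["pa_mean_mmhg"],
        "pcwp": m.extras["pcwp_mmhg"],
        "ra_mean": m.extras["ra_mean_mmhg"],
        "rv_edp": rv_idx["edp_mmhg"],
        "forward_co": m.forward_co_lmin,
        "pump_flow": m.pump_flow_lmin,
        "rv_edv": rv_idx["edv_ml"],
        "rv_esv": rv_idx["esv_ml"],
        "lvedp": m.lvedp_mmhg,
        "aortic_pulse_pressure": m.aortic_pulse_pressure_mmhg,
        "mv_regurg_vol": m.regurgitant_volume_ml["mv"],
        "av_regurg_vol": m.regurgitant_volume_ml["av"],
        "tv_regurg_vol": m.regurgitant_volume_ml["tv"],
        "coronary_flow": m.extras["coronary_flow_ml_min"],
        "e_wave": m.e_wave_cm_s if m.e_wave_cm_s is not None else float("nan"),
    }
    assert set(vals) == set(TARGET_UNITS)
    return vals


def make_targets(spec: SyntheticPatientSpec, noise_level: Optional[float] = None,
                 sim: Optional[SimSettings] = None) -> ClinicalTargets:
    """Noisy clinical target table from a simulation at ground truth.

    Each target is multiplied by (1 + noise_level * z), z standard normal
    at the spec seed; noise_level = 0 gives exact self-consistent targets.
    """
    spec = resolve(spec)
    sim = sim or SimSettings()
    noise = spec.noise_level if noise_level is None else noise_level
    net = build_network(spec)
    cycles, periodic = run_cycles(
        net, sim.cfg, n_min_cycles=sim.n_min_cycles, max_cycles=sim.max_cycles,
        periodicity_threshold=sim.periodicity_threshold)
    if not periodic:
        raise RuntimeError("ground-truth simulation did not reach periodicity; "
                           "synthetic patient spec is invalid")
    vals = targets_from_cycle(cycles[-1], net)
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal(len(TARGET_UNITS))
    entries = []
    for (name, unit), zi in zip(TARGET_UNITS.items(), z):
        y = vals[name] * (1.0 + noise * zi)
        entries.append(TargetEntry(name=name, value=float(y), units=unit))
    return ClinicalTargets(
        entries=entries, height_m=spec.height_m, weight_kg=spec.weight_kg,
        sex=spec.sex, lv_mass_g=spec.lv_mass_g,
        valve_severity=dict(spec.valve_severity))


def config_dict(spec: SyntheticPatientSpec) -> dict:
    """The YAML-schema configuration equivalent to a synthetic patient.

    Waveform CSV paths are relative to the config file's directory
    (lv_volume.csv / la_volume.csv, written by :func:`export_patient`).
    """
    spec = resolve(spec)
    T = spec.period
    valves = {}
    for name, geom in VALVE_GEOMETRY.items():
        roas = {"mv": spec.theta_star.roa_mv, "av": spec.theta_star.roa_av,
                "tv": spec.theta_star.roa_tv, "pv": spec.theta_star.roa_pv}
        valves[name] = {
            "shape": geom.shape, "l_a_mm": geom.l_a, "l_b_mm": geom.l_b,
            "roa_mm2": float(roas[name]), "c1": 800.0, "c2_per_pa": 1.0e-3,
            "c3_s_per_mm3": 1.0e-4, "tau_q_s": 0.02,
        }
    return {
        "version": 1,
        "cycle": {"period_s": T, "n_min_cycles": 3, "max_cycles": 12,
                  "periodicity_threshold": 0.05},
        "integrator": {"dt_s": 1.0e-3, "theta": 0.5, "newton_tol": 1.0e-6,
                       "max_newton_iters": 50, "dp_eps_pa": 0.5,
                       "sgn_eps": 0.05, "dqdt_filter_tau_s": 5.0e-3},
        "blood": {"density_g_per_ml": 1.026, "viscosity_pa_s": 0.004},
        "parameters": {k: float(v) for k, v in spec.theta_star.as_dict().items()},
        "patient": {"height_m": spec.height_m, "weight_kg": spec.weight_kg,
                    "sex": spec.sex, "lv_mass_g": spec.lv_mass_g},
        "chambers": {
            "ra": {"v0_ml": 10.0, "activation_onset_s": 0.45 * T,
                   "tau_rise_s": 0.08 * T, "tau_fall_s": 0.10 * T},
            "rv": {"v0_ml": 20.0, "activation_onset_s": 0.60 * T,
                   "tau_rise_s": 0.20 * T, "tau_fall_s": 0.18 * T},
            "la": {"waveform_csv": "la_volume.csv"},
            "lv": {"waveform_csv": "lv_volume.csv"},
        },
        "coronary": {"k_im": spec.k_im},
        "unstressed_volumes_ml": {
            "sys_ar": 400.0, "sys_ven": float(spec.v_un_sys_ven) * MM3_TO_ML,
            "pul_ar": 50.0, "pul_ven": 350.0, "cor": 5.0},
        "valves": valves,
        "pump": {"a_pa": spec.pump.a, "b_pa_s_per_mm3": spec.pump.b,
                 "c_pa_s2_per_mm6": spec.pump.c, "d_pa_s3_per_mm9": spec.pump.d,
                 "speed_rpm": spec.pump.speed_rpm},
    }


def export_patient(spec: SyntheticPatientSpec, out_dir,
                   noise_level: Optional[float] = None,
                   sim: Optional[SimSettings] = None) -> dict:
    """Write waveform CSVs, config YAML, ground-truth parameters and the
    noisy target table of a synthetic patient into ``out_dir``.

    Returns a manifest dict of the written files.
    """
    from pathlib import Path

    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = resolve(spec)
    lv_tab, la_tab = volume_waveforms(spec)
    lv_tab.to_csv(out / "lv_volume.csv", index=False)
    la_tab.to_csv(out / "la_volume.csv", index=False)
    cfg = config_dict(spec)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    with open(out / "theta_star.yaml", "w") as fh:
        yaml.safe_dump({k: float(v) for k, v in spec.theta_star.as_dict().items()},
                       fh, sort_keys=False)
    targets = make_targets(spec, noise_level=noise_level, sim=sim)
    frame = targets.to_frame()
    frame["severity"] = ""
    frame.to_csv(out / "targets.csv", index=False)
    return {"files": ["lv_volume.csv", "la_volume.csv", "config.yaml",
                      "theta_star.yaml", "targets.csv"],
            "seed": spec.seed}


class SyntheticPatientRunner:
    """Forward-model runner over the synthetic patient (ModelRunner protocol).

    ``predict(theta)`` rebuilds the network with the candidate parameter
    vector (waveforms, pump, valve geometry and unstressed volumes held
    fixed), simulates to periodic steady state and returns the 20 named
    clinical quantities; ``total_blood_volume_l`` evaluates the volume
    constraint at the resting initial state, where the stressed volumes
    C_i * P_init depend on the candidate compliances.
    """

    def __init__(self, spec: SyntheticPatientSpec,
                 sim: Optional[SimSettings] = None,
                 require_periodic: bool = False):
        self.spec = resolve(spec)
        self.sim = sim or SimSettings()
        self.require_periodic = require_periodic

    def _simulate(self, theta: ParameterVector):
        net = build_network(self.spec, theta)
        cycles, periodic = run_cycles(
            net, self.sim.cfg, n_min_cycles=self.sim.n_min_cycles,
            max_cycles=self.sim.max_cycles,
            periodicity_threshold=self.sim.periodicity_threshold)
        if self.require_periodic and not periodic:
            raise RuntimeError("simulation did not reach periodic steady state")
        return net, cycles

    def predict(self, theta: ParameterVector) -> Dict[str, float]:
        net, cycles = self._simulate(theta)
        return targets_from_cycle(cycles[-1], net)

    def total_blood_volume_l(self, theta: ParameterVector) -> float:
        net = build_network(self.spec, theta)
        y0 = net.initial_state(0.0, cfg=self.sim.cfg)
        return net.total_blood_volume(y0, 0.0) / L_TO_MM3
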