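"""YAML model configuration: schema, validation, round-trip and assembly.

Every field carries its unit in the key name.  Internal solver units are Pa,
mm^3 and mm^3/s; the configuration uses the clinical-facing units declared
below (mmHg only appears in outputs, never in the schema).

Schema (version 1)::

    version: 1
    cycle:       period_s, n_min_cycles, max_cycles, periodicity_threshold
    integrator:  dt_s, theta, newton_tol, max_newton_iters, dp_eps_pa,
                 sgn_eps, dqdt_filter_tau_s
    blood:       density_g_per_ml, viscosity_pa_s
    parameters:  the 23 circuit parameters (Pa*s/mm^3, mm^3/Pa,
                 Pa*s^2/mm^3, Pa/mm^3, mm^2)
    patient:     height_m, weight_kg, sex, lv_mass_g
    chambers:
      ra/rv:     v0_ml, activation_onset_s, tau_rise_s, tau_fall_s
      la/lv:     waveform_csv (2 columns: t_seconds, volume_mL)
    coronary:    k_im (fraction of LV pressure squeezing the coronary bed)
    unstressed_volumes_ml: sys_ar, sys_ven, pul_ar, pul_ven, cor
    valves:
      mv/av/tv/pv: shape (ellipse|circle), l_a_mm, l_b_mm,
                   roa_mm2 OR severity (none|mild|moderate|severe),
                   c1, c2_per_pa, c3_s_per_mm3, tau_q_s, g_min (optional
                   override; 0 models a repaired valve)
    pump:        a_pa, b_pa_s_per_mm3, c_pa_s2_per_mm6, d_pa_s3_per_mm9,
                 speed_rpm   (or null for no device)
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import numpy as np
import pandas as pd
import yaml

from .chambers import ElastanceChamber, PrescribedVolumeChamber
from .network import CirculationNetwork, IntegratorConfig
from .parameters import PARAMETER_NAMES, BloodProperties, ParameterVector
from .personalization import severity_bounds
from .pump import PumpHQ
from .units import ML_TO_MM3
from .valves import ValveGeometry, ValveState, g_min_from_roa

__all__ = ["ModelConfig", "load_config", "save_config",
           "network_from_config", "integrator_from_config"]


class ConfigError(ValueError):
    pass


_SECTION_KEYS = {
    "cycle": {"period_s", "n_min_cycles", "max_cycles", "periodicity_threshold"},
    "integrator": {"dt_s", "theta", "newton_tol", "max_newton_iters",
                   "dp_eps_pa", "sgn_eps", "dqdt_filter_tau_s"},
    "blood": {"density_g_per_ml", "viscosity_pa_s"},
    "patient": {"height_m", "weight_kg", "sex", "lv_mass_g"},
    "coronary": {"k_im"},
    "unstressed_volumes_ml": {"sys_ar", "sys_ven", "pul_ar", "pul_ven", "cor"},
}
_VALVE_KEYS = {"shape", "l_a_mm", "l_b_mm", "roa_mm2", "severity", "c1",
               "c2_per_pa", "c3_s_per_mm3", "tau_q_s", "g_min"}
_CHAMBER_EL_KEYS = {"v0_ml", "activation_onset_s", "tau_rise_s", "tau_fall_s"}
_PUMP_KEYS = {"a_pa", "b_pa_s_per_mm3", "c_pa_s2_per_mm6", "d_pa_s3_per_mm9",
              "speed_rpm"}


@dataclass
class ModelConfig:
    """Validated, round-trippable model configuration."""

    data: Dict[str, Any]
    base_dir: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        _validate(self.data)

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    def copy(self) -> "ModelConfig":
        return ModelConfig(copy.deepcopy(self.data), self.base_dir)

    def parameters(self) -> ParameterVector:
        return ParameterVector(**self.data["parameters"])

    def with_parameters(self, theta: ParameterVector) -> "ModelConfig":
        out = self.copy()
        out.data["parameters"] = theta.as_dict()
        return out


def _err(errors, msg):
    errors.append(msg)


def _check_keys(errors, section, mapping, allowed):
    unknown = set(mapping) - allowed
    if unknown:
        _err(errors, f"{section}: unknown keys {sorted(unknown)}")


def _validate(data: Dict[str, Any]) -> None:
    errors = []
    if data.get("version") != 1:
        _err(errors, "version: must be 1")
    top_allowed = {"version", "cycle", "integrator", "blood", "parameters",
                   "patient", "chambers", "coronary", "unstressed_volumes_ml",
                   "valves", "pump"}
    _check_keys(errors, "top-level", data, top_allowed)
    for sec, allowed in _SECTION_KEYS.items():
        if sec in data and isinstance(data[sec], dict):
            _check_keys(errors, sec, data[sec], allowed)
    params = data.get("parameters", {})
    _check_keys(errors, "parameters", params, set(PARAMETER_NAMES))
    missing = set(PARAMETER_NAMES) - set(params)
    if missing:
        _err(errors, f"parameters: missing {sorted(missing)}")
    for name, v in params.items():
        if name.startswith("roa_"):
            if not (isinstance(v, (int, float)) and v >= 0):
                _err(errors, f"parameters.{name}: must be >= 0, got {v!r}")
        elif not (isinstance(v, (int, float)) and v > 0):
            _err(errors, f"parameters.{name}: must be > 0, got {v!r}")
    chambers = data.get("chambers", {})
    _check_keys(errors, "chambers", chambers, {"ra", "rv", "la", "lv"})
    for ch in ("ra", "rv"):
        if ch in chambers:
            _check_keys(errors, f"chambers.{ch}", chambers[ch], _CHAMBER_EL_KEYS)
    for ch in ("la", "lv"):
        if ch in chambers:
            _check_keys(errors, f"chambers.{ch}", chambers[ch], {"waveform_csv"})
            if "waveform_csv" not in chambers.get(ch, {}):
                _err(errors, f"chambers.{ch}: waveform_csv is required")
    valves = data.get("valves", {})
    _check_keys(errors, "valves", valves, {"mv", "av", "tv", "pv"})
    for name, v in valves.items():
        _check_keys(errors, f"valves.{name}", v, _VALVE_KEYS)
        if "roa_mm2" not in v and "severity" not in v:
            _err(errors, f"valves.{name}: needs roa_mm2 or severity")
    pump = data.get("pump")
    if pump is not None:
        _check_keys(errors, "pump", pump, _PUMP_KEYS)
    integ = data.get("integrator", {})
    if "theta" in integ and not (0.0 <= integ["theta"] <= 1.0):
        _err(errors, f"integrator.theta: must be in [0,1], got {integ['theta']}")
    if "dt_s" in integ and not integ["dt_s"] > 0:
        _err(errors, f"integrator.dt_s: must be > 0, got {integ['dt_s']}")
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))


def load_config(path) -> ModelConfig:
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return ModelConfig(data, base_dir=path.parent)


def save_config(cfg: ModelConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.data, fh, sort_keys=False)


def integrator_from_config(cfg: ModelConfig) -> IntegratorConfig:
    integ = cfg.data.get("integrator", {})
    return IntegratorConfig(
        dt=integ.get("dt_s", 1.0e-3),
        theta=integ.get("theta", 0.5),
        newton_tol=integ.get("newton_tol", 1.0e-6),
        max_newton_iters=integ.get("max_newton_iters", 50),
        dp_eps=integ.get("dp_eps_pa", 0.5),
        sgn_eps=integ.get("sgn_eps", 0.05),
        dqdt_filter_tau=integ.get("dqdt_filter_tau_s", 5.0e-3),
    )


def _load_waveform(cfg: ModelConfig, chamber: str) -> PrescribedVolumeChamber:
    rel = cfg.data["chambers"][chamber]["waveform_csv"]
    path = (cfg.base_dir / rel) if not Path(rel).is_absolute() else Path(rel)
    tab = pd.read_csv(path)
    for col in ("t_seconds", "volume_mL"):
        if col not in tab.columns:
            raise ConfigError(f"{path}: waveform needs column {col!r}")
    return PrescribedVolumeChamber(tab["t_seconds"].to_numpy(),
                                   tab["volume_mL"].to_numpy() * ML_TO_MM3)


def _valve_from_config(name: str, v: Dict[str, Any]) -> ValveState:
    shape = v.get("shape", "circle")
    l_a = v["l_a_mm"]
    l_b = v.get("l_b_mm", l_a)
    geom = ValveGeometry(l_a, l_b, shape)
    if "roa_mm2" in v:
        roa = float(v["roa_mm2"])
    else:
        lo, hi = severity_bounds(v["severity"])
        roa = 0.5 * (lo + hi)   # class midpoint when only a severity is given
    g_min = v["g_min"] if "g_min" in v else g_min_from_roa(roa, geom)
    return ValveState(geometry=geom, g=1.0, g_min=float(g_min),
                      c1=v.get("c1", 800.0), c2=v.get("c2_per_pa", 1.0e-3),
                      c3=v.get("c3_s_per_mm3", 1.0e-4),
                      tau_q=v.get("tau_q_s", 0.02))


def network_from_config(cfg: ModelConfig,
                        params: Optional[ParameterVector] = None, *,
                        gmin_overrides: Optional[Dict[str, float]] = None
                        ) -> CirculationNetwork:
    params = cfg.parameters() if params is None else params
    T = cfg.data["cycle"]["period_s"]
    blood = BloodProperties(
        density=cfg.data["blood"]["density_g_per_ml"] / 1000.0,
        viscosity=cfg.data["blood"]["viscosity_pa_s"])
    la = _load_waveform(cfg, "la")
    lv = _load_waveform(cfg, "lv")
    ra_c = cfg.data["chambers"]["ra"]
    rv_c = cfg.data["chambers"]["rv"]
    ra = ElastanceChamber(params.e_ra_max, params.e_ra_min,
                          v0=ra_c["v0_ml"] * ML_TO_MM3, period=T,
                          activation_onset=ra_c["activation_onset_s"],
                          tau_rise=ra_c["tau_rise_s"],
                          tau_fall=ra_c["tau_fall_s"])
    rv = ElastanceChamber(params.e_rv_max, params.e_rv_min,
                          v0=rv_c["v0_ml"] * ML_TO_MM3, period=T,
                          activation_onset=rv_c["activation_onset_s"],
                          tau_rise=rv_c["tau_rise_s"],
                          tau_fall=rv_c["tau_fall_s"])
    valves = {name: _valve_from_config(name, v)
              for name, v in cfg.data["valves"].items()}
    for name, g_min in (gmin_overrides or {}).items():
        valves[name].g_min = float(g_min)
    pump_c = cfg.data.get("pump")
    pump = None
    if pump_c is not None:
        pump = PumpHQ(a=pump_c["a_pa"], b=pump_c["b_pa_s_per_mm3"],
                      c=pump_c["c_pa_s2_per_mm6"], d=pump_c["d_pa_s3_per_mm9"],
                      speed_rpm=pump_c.get("speed_rpm", 0.0))
    v_un = {k: v * ML_TO_MM3
            for k, v in cfg.data["unstressed_volumes_ml"].items()}
    return CirculationNetwork(params, la, lv, ra, rv, valves, pump,
                              blood=blood, k_im=cfg.data["coronary"]["k_im"],
                              v_unstressed=v_un, period=T)
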