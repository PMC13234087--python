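"""Model personalization: fitting circuit parameters to clinical targets.

The objective is the sum of half squared relative errors over the N
clinical data points,

    J(theta) = sum_i 1/2 * ((yhat_i - y_i) / y_i)^2,

minimized by a hybrid scheme: a fixed budget of projected gradient-descent
iterations followed by Levenberg-Marquardt with box projection.  Two
physiological constraints shape the feasible set: the total blood volume
must match the Nadler estimate from patient height/weight/sex (enforced as
a quadratic penalty row), and regurgitant orifice areas are box-bounded by
their echocardiographic severity class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Protocol, Sequence, Tuple

import numpy as np
import pandas as pd

from .parameters import PARAMETER_NAMES, ParameterVector
from .solver import SolverError

__all__ = [
    "TargetEntry", "ClinicalTargets", "FitConfig", "FitResult",
    "nadler_blood_volume", "coronary_flow_target", "severity_bounds",
    "objective", "fit_parameters", "sensitivity_analysis",
    "DEFAULT_SEVERITY_BOUNDS",
]

log = logging.getLogger(__name__)

#: ROA bounds (mm^2) per echocardiographic severity class.  This table is
#: configuration, not a clinical standard; classes are half-open (lo, hi].
DEFAULT_SEVERITY_BOUNDS: Dict[str, Tuple[float, float]] = {
    "none": (0.0, 0.0),
    "mild": (0.0, 20.0),
    "moderate": (20.0, 40.0),
    "severe": (40.0, 80.0),
}

#: cost assigned to a non-convergent simulation (finite and ordered so the
#: optimizer can retreat)
NONCONVERGENCE_COST = 1.0e6


@dataclass
class TargetEntry:
    name: str
    value: float
    units: str = ""
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.value == 0.0:
            raise ValueError(f"target {self.name}: relative error needs y != 0")


@dataclass
class ClinicalTargets:
    """Patient target table plus the meta data the constraints need."""

    entries: List[TargetEntry]
    height_m: float
    weight_kg: float
    sex: str
    lv_mass_g: float = 150.0
    valve_severity: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.entries) < 1:
            raise ValueError("at least one clinical target is required")

    def __len__(self) -> int:
        return len(self.entries)

    def names(self) -> List[str]:
        return [e.name for e in self.entries]

    def nadler_volume_l(self) -> float:
        return nadler_blood_volume(self.height_m, self.weight_kg, self.sex)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"name": e.name, "value": e.value,
                              "units": e.units, "weight": e.weight}
                             for e in self.entries])


class ModelRunner(Protocol):
    """Forward model interface used by the fitter."""

    def predict(self, theta: ParameterVector) -> Dict[str, float]:
        """Named clinical quantities at periodic steady state."""
        ...

    def total_blood_volume_l(self, theta: ParameterVector) -> float:
        ...


# --- closed-form clinical helpers ---------------------------------------------
def nadler_blood_volume(height_m: float, weight_kg: float, sex: str) -> float:
    """Total blood volume (L) from height, weight and sex (Nadler formula)."""
    if height_m <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    if height_m > 2.5 or height_m < 0.5 or weight_kg > 400:
        warnings.warn(f"non-physiological inputs: height={height_m} m, "
                      f"weight={weight_kg} kg", stacklevel=2)
    sex = sex.lower()
    if sex in ("f", "female"):
        return 0.3561 * height_m ** 3 + 0.03308 * weight_kg + 0.1833
    if sex in ("m", "male"):
        return 0.3669 * height_m ** 3 + 0.03219 * weight_kg + 0.6041
    raise ValueError(f"unknown sex {sex!r}")


def coronary_flow_target(lv_mass_g: float) -> float:
    """Coronary flow (mL/min) at a perfusion rate of 80 mL/min per 100 g."""
    if lv_mass_g < 0:
        raise ValueError("myocardial mass must be >= 0")
    return 0.8 * lv_mass_g


def severity_bounds(severity_class: str,
                    table: Optional[Dict[str, Tuple[float, float]]] = None
                    ) -> Tuple[float, float]:
    """(roa_min, roa_max) in mm^2 for a regurgitation severity class."""
    table = DEFAULT_SEVERITY_BOUNDS if table is None else table
    try:
        return table[severity_class]
    except KeyError:
        raise ValueError(f"unknown severity class {severity_class!r}; "
                         f"expected one of {sorted(table)}") from None


# --- objective ------------------------------------------------------------------
def _target_residuals(preds: Dict[str, float], targets: ClinicalTargets
                      ) -> np.ndarray:
    r = []
    for e in targets.entries:
        yhat = preds[e.name]
        r.append(np.sqrt(e.weight) * (yhat - e.value) / e.value)
    return np.asarray(r)


def objective(theta: ParameterVector, targets: ClinicalTargets,
              runner: ModelRunner) -> float:
    """J(theta): sum of half squared weighted relative target errors.

    A non-convergent simulation returns a large finite penalty
    (NONCONVERGENCE_COST plus the residual norm when available).
    """
    try:
        preds = runner.predict(theta)
    except SolverError as exc:
        res = exc.residual_history[-1] if exc.residual_history else 0.0
        return NONCONVERGENCE_COST + float(res)
    except RuntimeError:
        return NONCONVERGENCE_COST
    r = _target_residuals(preds, targets)
    return float(0.5 * np.sum(r ** 2))


# --- fitting ---------------------------------------------------------------------
@dataclass
class FitConfig:
    free_params: Sequence[str] = PARAMETER_NAMES
    bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    bound_factors: Tuple[float, float] = (0.2, 5.0)   # default box around start
    volume_weight: float = 100.0       # Nadler penalty weight
    gd_iters: int = 50
    gd_step: float = 0.05
    lm_max_iters: int = 60
    lm_lambda0: float = 1.0e-3
    xtol: float = 1.0e-10
    ftol: float = 1.0e-14
    fd_rel_step: float = 1.0e-4
    seed: int = 0
    severity_table: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SEVERITY_BOUNDS))

    def resolve_bounds(self, theta0: ParameterVector,
                       targets: Optional[ClinicalTargets] = None
                       ) -> Dict[str, Tuple[float, float]]:
        lo_f, hi_f = self.bound_factors
        out = {}
        for name in self.free_params:
            if name in self.bounds:
                lo, hi = self.bounds[name]
            elif name.startswith("roa_") and targets is not None and \
                    name[4:] in targets.valve_severity:
                lo, hi = severity_bounds(targets.valve_severity[name[4:]],
                                         self.severity_table)
            else:
                v = theta0[name]
                lo, hi = lo_f * v, hi_f * v
            if lo > hi:
                raise ValueError(f"infeasible bounds for {name}: ({lo}, {hi})")
            out[name] = (lo, hi)
        return out


@dataclass
class FitResult:
    theta_hat: ParameterVector
    j_trace: List[float]               # target objective along accepted steps
    j_total_trace: List[float]         # objective + volume penalty
    converged: bool
    diagnostics: Dict[str, float] = field(default_factory=dict)


class _SimFailure(Exception):
    def __init__(self, cost: float):
        self.cost = cost


def fit_parameters(targets: ClinicalTargets, cfg: FitConfig,
                   runner: ModelRunner,
                   theta0: Optional[ParameterVector] = None) -> FitResult:
    """Hybrid projected gradient-descent + Levenberg-Marquardt fit.

    The residual vector stacks the weighted relative target errors and the
    Nadler blood-volume penalty row; parameters stay inside their box
    bounds by projection.
    """
    theta0 = theta0 or ParameterVector()
    free = list(cfg.free_params)
    bounds = cfg.resolve_bounds(theta0, targets)
    lo = np.array([bounds[n][0] for n in free])
    hi = np.array([bounds[n][1] for n in free])
    v_nadler = targets.nadler_volume_l()
    scale = np.maximum(np.abs(theta0.as_array(free)), 1e-12)

    def to_theta(x: np.ndarray) -> ParameterVector:
        return theta0.with_array(x * scale, free)

    def project(x: np.ndarray) -> np.ndarray:
        return np.clip(x, lo / scale, hi / scale)

    def residuals(x: np.ndarray) -> np.ndarray:
        theta = to_theta(x)
        try:
            preds = runner.predict(theta)
        except SolverError as exc:
            res = exc.residual_history[-1] if exc.residual_history else 0.0
            raise _SimFailure(NONCONVERGENCE_COST + float(res)) from exc
        except RuntimeError:
            raise _SimFailure(NONCONVERGENCE_COST) from None
        r_t = _target_residuals(preds, targets)
        tbv = runner.total_blood_volume_l(theta)
        r_v = np.sqrt(cfg.volume_weight) * (tbv - v_nadler) / v_nadler
        return np.concatenate([r_t, [r_v]])

    def cost_split(r: np.ndarray) -> Tuple[float, float]:
        j_total = 0.5 * float(np.sum(r ** 2))
        j_targets = 0.5 * float(np.sum(r[:-1] ** 2))
        return j_targets, j_total

    def jacobian(x: np.ndarray, r0: np.ndarray) -> np.ndarray:
        jac = np.empty((r0.size, x.size))
        for k in range(x.size):
            h = cfg.fd_rel_step * max(abs(x[k]), 1e-8)
            xk = x.copy()
            xk[k] = min(xk[k] + h, (hi / scale)[k])
            if xk[k] == x[k]:  # at upper bound: step down
                xk[k] = x[k] - h
            try:
                rk = residuals(xk)
            except _SimFailure:
                rk = r0  # no information; zero column
            jac[:, k] = (rk - r0) / (xk[k] - x[k])
        return jac

    x = project(theta0.as_array(free) / scale)
    try:
        r = residuals(x)
    except _SimFailure as fail:
        return FitResult(to_theta(x), [fail.cost], [fail.cost], False,
                         {"error": "initial simulation failed"})
    j_tgt, j_tot = cost_split(r)
    j_trace, j_total_trace = [j_tgt], [j_tot]

    # ---- phase 1: projected gradient descent ----
    step = cfg.gd_step
    for _ in range(cfg.gd_iters):
        jac = jacobian(x, r)
        grad = jac.T @ r
        gnorm = np.linalg.norm(grad)
        if gnorm < 1e-14:
            break
        accepted = False
        for _ls in range(12):
            x_try = project(x - step * grad / gnorm)
            try:
                r_try = residuals(x_try)
            except _SimFailure:
                step *= 0.5
                continue
            _, j_try = cost_split(r_try)
            if j_try < j_tot:
                x, r = x_try, r_try
                j_tgt, j_tot = cost_split(r)
                j_trace.append(j_tgt)
                j_total_trace.append(j_tot)
                step *= 1.3
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break

    # ---- phase 2: Levenberg-Marquardt with box projection ----
    lam = cfg.lm_lambda0
    converged = False
    for _ in range(cfg.lm_max_iters):
        if j_tot < 1e-18:
            converged = True
            break
        jac = jacobian(x, r)
        jtj = jac.T @ jac
        g = jac.T @ r
        accepted = False
        for _inner in range(25):
            a = jtj + lam * np.diag(np.maximum(np.diag(jtj), 1e-12))
            try:
                delta = np.linalg.solve(a, -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            x_try = project(x + delta)
            try:
                r_try = residuals(x_try)
            except _SimFailure:
                lam *= 4.0
                continue
            _, j_try = cost_split(r_try)
            if j_try < j_tot:
                dx = np.linalg.norm(x_try - x)
                dj = j_tot - j_try
                x, r = x_try, r_try
                j_tgt, j_tot = cost_split(r)
                j_trace.append(j_tgt)
                j_total_trace.append(j_tot)
                lam = max(lam / 3.0, 1e-12)
                accepted = True
                if dx < cfg.xtol * (1.0 + np.linalg.norm(x)) or dj < cfg.ftol:
                    converged = True
                break
            lam *= 4.0
        if not accepted:
            converged = j_tot < 1e-3  # stalled near an optimum
            break
        if converged or j_tot < 1e-16:
            converged = True
            break

    theta_hat = to_theta(x)
    tbv = runner.total_blood_volume_l(theta_hat)
    return FitResult(
        theta_hat=theta_hat, j_trace=j_trace, j_total_trace=j_total_trace,
        converged=converged,
        diagnostics={
            "j_final": j_trace[-1],
            "j_total_final": j_total_trace[-1],
            "volume_rel_error": abs(tbv - v_nadler) / v_nadler,
            "n_evals_trace": len(j_trace),
        },
    )


# --- sensitivity ------------------------------------------------------------------
def sensitivity_analysis(theta: ParameterVector,
                         runner: ModelRunner,
                         outputs: Optional[Sequence[str]] = None,
                         params: Optional[Sequence[str]] = None,
                         delta: float = 0.1) -> pd.DataFrame:
    """Local +/-delta (default 10%) one-at-a-time sensitivity matrix.

    Rows are (parameter, direction) pairs, columns the outputs; values are
    relative output changes (NaN where the baseline output is ~ 0).
    Deterministic: identical inputs give a bit-identical matrix.
    """
    params = list(params if params is not None else PARAMETER_NAMES)
    base = runner.predict(theta)
    outputs = list(outputs if outputs is not None else base.keys())
    rows = {}
    for name in params:
        v = theta[name]
        for direction, fac in (("+10%", 1.0 + delta), ("-10%", 1.0 - delta)):
            label = direction.replace("10%", f"{100 * delta:g}%")
            pred = runner.predict(theta.with_values(**{name: v * fac}))
            rel = {}
            for out in outputs:
                b = base[out]
                if abs(b) < 1e-12:
                    rel[out] = np.nan
                else:
                    rel[out] = (pred[out] - b) / b
            rows[(name, label)] = rel
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=outputs)
    frame.index = pd.MultiIndex.from_tuples(frame.index,
                                            names=["parameter", "perturbation"])
    return frame
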