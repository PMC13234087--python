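"""Closed-loop 0D circulation network and its implicit theta-scheme residual.

Topology (one closed loop; four heart chambers, four valves, LVAD pump):

  LV --AV valve--> aortic root (junction) --Z_prox--> systemic arteries (C)
     --LVAD pump-/        \\--R_cor_prox--> coronary bed (C, squeezed by LV
                                            pressure) --R_cor_dist--> RA
  systemic arteries --R_dist,L--> systemic veins (C) --R_ven--> RA
  RA --TV--> RV --PV--> pulmonary arteries (C) --R,L--> pulmonary veins (C)
     --R,L--> LA --MV--> LV

The right atrium and ventricle are time-varying elastance chambers; the
left atrium and ventricle have prescribed (imaging-derived) volume
waveforms, so their pressures are algebraic unknowns determined by flow
balance.  The monolithic unknown vector stacks 10 differential circuit
states, 6 algebraic pressures, 4 valve opening states, 4 transvalvular
flows and the pump flow (25 unknowns).

The time discretization is the one-step theta scheme
``M (y^n - y^{n-1}) - dt [theta f(y^n) + (1-theta) f(y^{n-1})] = 0``
(theta = 0.5: midpoint/trapezoid, second order).  Pure algebraic
constraints are enforced at the new time level.  Prescribed-chamber balance
rows use the exact waveform increment on the right-hand side, which makes
total blood volume conservation exact up to the Newton tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional

import numpy as np

from .chambers import ElastanceChamber, PrescribedVolumeChamber
from .parameters import BloodProperties, ParameterVector
from .pump import PumpHQ, hq_dp, hq_invert
from .units import pa
from .valves import ValveState, effective_area, orifice_flow, valve_rhs, alpha as valve_alpha

__all__ = ["STATE_NAMES", "IntegratorConfig", "CirculationNetwork"]

# --- monolithic state layout -------------------------------------------------
STATE_NAMES = (
    "p_sys_ar", "q_sys_ar", "p_sys_ven", "v_ra", "v_rv",
    "p_pul_ar", "q_pul_ar", "p_pul_ven", "q_pul_ven", "v_cor",
    "p_ao", "p_la", "p_lv", "p_ra", "p_rv", "p_cor",
    "g_mv", "g_av", "g_tv", "g_pv",
    "q_mv", "q_av", "q_tv", "q_pv", "q_vad",
)
I = {name: k for k, name in enumerate(STATE_NAMES)}
N_STATES = len(STATE_NAMES)

DIFF_IDX = tuple(range(10))
G_IDX = (I["g_mv"], I["g_av"], I["g_tv"], I["g_pv"])
ALG_IDX = (
    I["p_ao"], I["p_la"], I["p_lv"], I["p_ra"], I["p_rv"], I["p_cor"],
    I["q_mv"], I["q_av"], I["q_tv"], I["q_pv"], I["q_vad"],
)

# typical magnitudes for nondimensionalization (Pa, mm^3, mm^3/s)
P_TYP, V_TYP, Q_TYP = 1.0e4, 1.0e5, 1.0e5
_TYP_BY_PREFIX = {"p": P_TYP, "v": V_TYP, "q": Q_TYP, "g": 1.0}
Y_TYP = np.array([_TYP_BY_PREFIX[name[0]] for name in STATE_NAMES])


@dataclass
class IntegratorConfig:
    """Time integrator settings for the monolithic solve."""

    dt: float = 1.0e-3           # s; resolves ~10 ms valve transitions
    theta: float = 0.5           # midpoint scheme
    newton_tol: float = 1.0e-6   # on the row-scaled residual L2 norm
    max_newton_iters: int = 50
    dp_eps: float = 0.5          # Pa; orifice-law slope regularization
    # smoothing width of sgn(alpha) in the valve ODE: tanh(alpha/sgn_eps).
    # the valve ODE has rate magnitude ~C1/2 for arbitrarily small |alpha|, so
    # the exact sign chatters around zero pressure gradient; 0.05 lets g
    # hover near equilibrium while saturated transitions stay at full speed
    sgn_eps: float = 0.05
    # first-order low-pass on the dQ/dt input of the valve switching signal;
    # physical valve-closing decelerations act over ~100 ms, so a 5 ms filter
    # leaves them intact while removing step-level noise of the algebraic flows
    dqdt_filter_tau: float = 5.0e-3

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0.0 <= self.theta <= 1.0):
            raise ValueError("theta must lie in [0, 1]")


_VALVE_WIRING = {
    # valve -> (g index, q index, upstream pressure, downstream pressure)
    "mv": (I["g_mv"], I["q_mv"], I["p_la"], I["p_lv"]),
    "av": (I["g_av"], I["q_av"], I["p_lv"], I["p_ao"]),
    "tv": (I["g_tv"], I["q_tv"], I["p_ra"], I["p_rv"]),
    "pv": (I["g_pv"], I["q_pv"], I["p_rv"], I["p_pul_ar"]),
}


class CirculationNetwork:
    """Assembles the closed-loop 0D system M dy/dt = f(t, y).

    Parameters
    ----------
    params : ParameterVector
        The 23 personalizable circuit parameters (internal units).
    la, lv : PrescribedVolumeChamber
        Prescribed left-heart volume waveforms.
    ra, rv : ElastanceChamber
        Elastance right-heart chambers.
    valves : dict with keys mv, av, tv, pv -> ValveState
    pump : PumpHQ or None
    k_im : float
        Fraction of LV pressure transmitted to the coronary bed
        (intramyocardial squeeze).
    v_unstressed : dict
        Unstressed volumes (mm^3) of the vascular compartments
        (sys_ar, sys_ven, pul_ar, pul_ven, cor).
    """

    def __init__(self, params: ParameterVector, la: PrescribedVolumeChamber,
                 lv: PrescribedVolumeChamber, ra: ElastanceChamber,
                 rv: ElastanceChamber, valves: Dict[str, ValveState],
                 pump: Optional[PumpHQ] = None, *,
                 blood: BloodProperties = BloodProperties(),
                 k_im: float = 0.5,
                 v_unstressed: Optional[Dict[str, float]] = None,
                 period: Optional[float] = None):
        self.params = params
        self.la, self.lv, self.ra, self.rv = la, lv, ra, rv
        if set(valves) != {"mv", "av", "tv", "pv"}:
            raise ValueError("valves must provide exactly mv, av, tv, pv")
        self.valves = valves
        self.pump = pump
        self.blood = blood
        self.k_im = k_im
        self.v_unstressed = dict(v_unstressed or {
            "sys_ar": 4.0e5, "sys_ven": 2.8e6, "pul_ar": 5.0e4,
            "pul_ven": 3.5e5, "cor": 5.0e3,
        })
        self.period = float(period if period is not None else la.period)
        for ch in (la, lv):
            if abs(ch.period - self.period) > 1e-9:
                raise ValueError("prescribed waveforms must share the cycle length")

    # --- mass matrix and row scaling -----------------------------------------
    def mass_diag(self) -> np.ndarray:
        p = self.params
        m = np.zeros(N_STATES)
        m[I["p_sys_ar"]] = p.c_sys_ar
        m[I["q_sys_ar"]] = p.l_sys_ar
        m[I["p_sys_ven"]] = p.c_sys_ven
        m[I["v_ra"]] = 1.0
        m[I["v_rv"]] = 1.0
        m[I["p_pul_ar"]] = p.c_pul_ar
        m[I["q_pul_ar"]] = p.l_pul_ar
        m[I["p_pul_ven"]] = p.c_pul_ven
        m[I["q_pul_ven"]] = p.l_pul_ven
        m[I["v_cor"]] = 1.0
        for g in G_IDX:
            m[g] = 1.0
        return m

    def row_scales(self, dt: float) -> np.ndarray:
        s = np.ones(N_STATES)
        for k in (0, 2, 3, 4, 5, 7, 9):           # volume-balance rows (mm^3)
            s[k] = dt * Q_TYP
        for k in (1, 6, 8):                        # flow-ODE rows (Pa*s)
            s[k] = dt * P_TYP
        for name in ("p_ao", "p_la", "p_lv"):      # junction/balance rows (mm^3/s)
            s[I[name]] = Q_TYP
        for name in ("p_ra", "p_rv", "p_cor"):     # pressure definitions (Pa)
            s[I[name]] = P_TYP
        for g in G_IDX:
            s[g] = 1.0
        for name in ("q_mv", "q_av", "q_tv", "q_pv"):
            s[I[name]] = Q_TYP
        s[I["q_vad"]] = P_TYP
        return s

    # --- right-hand side of the circuit ODE rows -----------------------------
    def f_circuit(self, t, y):
        """Rates f for the 10 differential rows (M dy/dt = f)."""
        p = self.params
        q_prox = (y[I["p_ao"]] - y[I["p_sys_ar"]]) / p.z_sys_prox
        q_sv = (y[I["p_sys_ven"]] - y[I["p_ra"]]) / p.r_sys_ven
        q_corp = (y[I["p_ao"]] - y[I["p_cor"]]) / p.r_cor_prox
        q_cord = (y[I["p_cor"]] - y[I["p_ra"]]) / p.r_cor_dist
        shape = np.shape(y[0])
        f = np.empty((10,) + shape)
        f[0] = q_prox - y[I["q_sys_ar"]]
        f[1] = y[I["p_sys_ar"]] - y[I["p_sys_ven"]] - p.r_sys_dist * y[I["q_sys_ar"]]
        f[2] = y[I["q_sys_ar"]] - q_sv
        f[3] = q_sv + q_cord - y[I["q_tv"]]
        f[4] = y[I["q_tv"]] - y[I["q_pv"]]
        f[5] = y[I["q_pv"]] - y[I["q_pul_ar"]]
        f[6] = y[I["p_pul_ar"]] - y[I["p_pul_ven"]] - p.r_pul_ar * y[I["q_pul_ar"]]
        f[7] = y[I["q_pul_ar"]] - y[I["q_pul_ven"]]
        f[8] = y[I["p_pul_ven"]] - y[I["p_la"]] - p.r_pul_ven * y[I["q_pul_ven"]]
        f[9] = q_corp - q_cord
        return f

    # --- algebraic constraint rows -------------------------------------------
    def _valve_flow_rows(self, y, cfg: IntegratorConfig):
        rows = {}
        for name, (gi, qi, ui, di) in _VALVE_WIRING.items():
            vs = self.valves[name]
            g_eff = np.maximum(np.clip(y[gi], 0.0, 1.0), vs.g_min)
            area = effective_area(g_eff, vs.geometry)
            rows[qi] = y[qi] - orifice_flow(
                y[ui], y[di], area, self.blood, dp_eps=cfg.dp_eps
            )
        return rows

    def algebraic_rows(self, t, y, cfg: IntegratorConfig,
                       dvdt_la=None, dvdt_lv=None):
        """Constraint values for the 11 algebraic unknowns (point form).

        The LA/LV balance rows use instantaneous dV/dt (used for consistent
        initialization); time stepping replaces them with exact-increment
        trapezoid rows.
        """
        p = self.params
        if dvdt_la is None:
            dvdt_la = self.la.dvdt(t)
        if dvdt_lv is None:
            dvdt_lv = self.lv.dvdt(t)
        q_prox = (y[I["p_ao"]] - y[I["p_sys_ar"]]) / p.z_sys_prox
        q_corp = (y[I["p_ao"]] - y[I["p_cor"]]) / p.r_cor_prox
        rows = {
            I["p_ao"]: y[I["q_av"]] + y[I["q_vad"]] - q_prox - q_corp,
            I["p_la"]: y[I["q_pul_ven"]] - y[I["q_mv"]] - dvdt_la,
            I["p_lv"]: y[I["q_mv"]] - y[I["q_av"]] - y[I["q_vad"]] - dvdt_lv,
            I["p_ra"]: y[I["p_ra"]] - self.ra.pressure(y[I["v_ra"]], t),
            I["p_rv"]: y[I["p_rv"]] - self.rv.pressure(y[I["v_rv"]], t),
            I["p_cor"]: y[I["p_cor"]] - (y[I["v_cor"]] / p.c_cor
                                         + self.k_im * y[I["p_lv"]]),
        }
        rows.update(self._valve_flow_rows(y, cfg))
        if self.pump is not None:
            rows[I["q_vad"]] = (y[I["p_ao"]] - y[I["p_lv"]]
                                - hq_dp(self.pump, y[I["q_vad"]]))
        else:
            rows[I["q_vad"]] = y[I["q_vad"]]
        return rows

    # --- valve ODE rows --------------------------------------------------------
    def valve_alphas(self, y, dqdt) -> Dict[str, float]:
        """Switching variables of all four valves at one state."""
        out = {}
        for name, (gi, qi, ui, di) in _VALVE_WIRING.items():
            vs = self.valves[name]
            out[name] = valve_alpha(y[ui] - y[di], y[qi], dqdt[name],
                                    vs.c2, vs.c3, vs.tau_q)
        return out

    def _valve_g_rows(self, y_n, y_prev_b, dt, theta, alphas, sgn_eps):
        """Theta-scheme rows for dg/dt with the switching signal alpha frozen
        at the previous time level (semi-implicit).

        With alpha constant during the solve, the row is linear in g_n with
        a damping slope, so Newton handles it exactly; sgn(alpha) is
        smoothed as tanh(alpha/sgn_eps) to avoid step-level chatter around
        the zero crossing.
        """
        rows = {}
        for name, (gi, qi, ui, di) in _VALVE_WIRING.items():
            vs = self.valves[name]
            a = alphas[name]
            rhs_n = valve_rhs(y_n[gi], a, vs.c1, sgn_eps=sgn_eps)
            rhs_p = valve_rhs(y_prev_b[gi], a, vs.c1, sgn_eps=sgn_eps)
            rows[gi] = (y_n[gi] - y_prev_b[gi]
                        - dt * (theta * rhs_n + (1.0 - theta) * rhs_p))
        return rows

    # --- full theta-scheme residual -------------------------------------------
    def make_step_residual(self, t_prev: float, y_prev: np.ndarray, t_n: float,
                           cfg: IntegratorConfig,
                           dqdt_prev: Optional[Dict[str, float]] = None
                           ) -> Callable[[np.ndarray], np.ndarray]:
        """Residual closure for one implicit step; accepts y_n of shape
        (25,) or (25, m) (vectorized over trial columns).  ``dqdt_prev``
        carries the (low-pass filtered) backward-difference flow derivative
        per valve at the previous level; omitted on the first step."""
        if not np.all(np.isfinite(y_prev)):
            bad = [STATE_NAMES[k] for k in np.flatnonzero(~np.isfinite(y_prev))]
            raise FloatingPointError(f"non-finite previous state in {bad}")
        dt = t_n - t_prev
        theta = cfg.theta
        mass = self.mass_diag()
        f_prev = self.f_circuit(t_prev, y_prev)
        if dqdt_prev is None:
            dqdt_prev = {name: 0.0 for name in _VALVE_WIRING}
        alphas = self.valve_alphas(y_prev, dqdt_prev)
        dv_la = self.la.increment(t_prev, t_n)
        dv_lv = self.lv.increment(t_prev, t_n)
        if not (np.isfinite(dv_la) and np.isfinite(dv_lv)):
            raise FloatingPointError("non-finite prescribed volume increment")
        qp, qm, qa, qv = (y_prev[I[k]] for k in ("q_pul_ven", "q_mv", "q_av", "q_vad"))
        bal_la_prev = qp - qm
        bal_lv_prev = qm - qa - qv

        def residual(y_n: np.ndarray) -> np.ndarray:
            y_prev_b = y_prev if y_n.ndim == 1 else y_prev[:, None]
            res = np.empty_like(y_n, dtype=float)
            f_n = self.f_circuit(t_n, y_n)
            f_prev_b = f_prev if y_n.ndim == 1 else f_prev[:, None]
            for k in DIFF_IDX:
                res[k] = (mass[k] * (y_n[k] - y_prev_b[k])
                          - dt * (theta * f_n[k] + (1 - theta) * f_prev_b[k]))
            alg = self.algebraic_rows(t_n, y_n, cfg)
            # overwrite LA/LV balance with exact-increment trapezoid rows
            alg[I["p_la"]] = (theta * (y_n[I["q_pul_ven"]] - y_n[I["q_mv"]])
                              + (1 - theta) * bal_la_prev - dv_la / dt)
            alg[I["p_lv"]] = (theta * (y_n[I["q_mv"]] - y_n[I["q_av"]]
                                       - y_n[I["q_vad"]])
                              + (1 - theta) * bal_lv_prev - dv_lv / dt)
            for k, v in alg.items():
                res[k] = v
            for k, v in self._valve_g_rows(y_n, y_prev_b, dt, theta,
                                           alphas, cfg.sgn_eps).items():
                res[k] = v
            return res

        return residual

    # spec-facing alias
    def assemble_residual(self, y_n, y_prev, t_n, t_prev, cfg: IntegratorConfig,
                          dqdt_prev=None):
        return self.make_step_residual(
            t_prev, np.asarray(y_prev, float), t_n, cfg, dqdt_prev
        )(np.asarray(y_n, float))

    # --- bookkeeping -----------------------------------------------------------
    def total_blood_volume(self, y: np.ndarray, t: float) -> float:
        """Total (stressed + unstressed) blood volume, mm^3."""
        p = self.params
        stressed = (p.c_sys_ar * y[I["p_sys_ar"]]
                    + p.c_sys_ven * y[I["p_sys_ven"]]
                    + p.c_pul_ar * y[I["p_pul_ar"]]
                    + p.c_pul_ven * y[I["p_pul_ven"]])
        chambers = (float(self.la.volume(t)) + float(self.lv.volume(t))
                    + y[I["v_ra"]] + y[I["v_rv"]] + y[I["v_cor"]])
        return float(stressed + chambers + sum(self.v_unstressed.values()))

    # --- initialization --------------------------------------------------------
    def initial_state(self, t0: float = 0.0,
                      pressures_mmhg: Optional[Dict[str, float]] = None,
                      cfg: Optional[IntegratorConfig] = None) -> np.ndarray:
        """Resting initial state with algebraically consistent unknowns."""
        cfg = cfg or IntegratorConfig()
        # resting distribution of a congested, LVAD-supported circulation
        # (elevated venous and pulmonary filling pressures); this fixes the
        # stressed-volume pool and puts startup near the operating point
        pr = {
            "p_sys_ar": 70.0, "p_sys_ven": 14.0, "p_pul_ar": 16.0,
            "p_pul_ven": 9.0, "p_ao": 70.0, "p_la": 8.0, "p_lv": 6.0,
            "p_ra": 7.0, "p_rv": 7.0,
        }
        pr.update(pressures_mmhg or {})
        p = self.params
        y = np.zeros(N_STATES)
        for name in ("p_sys_ar", "p_sys_ven", "p_pul_ar", "p_pul_ven",
                     "p_ao", "p_la", "p_lv", "p_ra", "p_rv"):
            y[I[name]] = pa(pr[name])
        y[I["v_ra"]] = self.ra.v0 + y[I["p_ra"]] / self.ra.elastance(t0)
        y[I["v_rv"]] = self.rv.v0 + y[I["p_rv"]] / self.rv.elastance(t0)
        y[I["p_cor"]] = pa(0.5 * (pr["p_ao"] + pr["p_sys_ven"]))
        y[I["v_cor"]] = p.c_cor * (y[I["p_cor"]] - self.k_im * y[I["p_lv"]])
        y[I["q_sys_ar"]] = (y[I["p_sys_ar"]] - y[I["p_sys_ven"]]) / p.r_sys_dist
        y[I["q_pul_ar"]] = (y[I["p_pul_ar"]] - y[I["p_pul_ven"]]) / p.r_pul_ar
        # start the series flows at a common nominal forward flow so the
        # consistent-state solve lands in a physiological regime
        y[I["q_pul_ven"]] = y[I["q_pul_ar"]]
        y[I["g_mv"]] = 1.0
        y[I["g_av"]] = self.valves["av"].g_min
        y[I["g_tv"]] = 1.0
        y[I["g_pv"]] = self.valves["pv"].g_min
        if self.pump is not None:
            y[I["q_vad"]] = hq_invert(self.pump, y[I["p_ao"]] - y[I["p_lv"]])
        return self.solve_consistent(t0, y, cfg)

    def solve_consistent(self, t0: float, y0: np.ndarray,
                         cfg: IntegratorConfig, tol: float = 1.0e-9,
                         max_iters: int = 60) -> np.ndarray:
        """Newton solve of the algebraic rows with differential states held."""
        y = y0.copy()
        idx = np.array(ALG_IDX)
        scales = self.row_scales(cfg.dt)[idx]

        def res(yy):
            rows = self.algebraic_rows(t0, yy, cfg)
            if yy.ndim == 1:
                return np.array([rows[k] for k in idx])
            return np.stack([np.broadcast_to(rows[k], yy.shape[1:]) for k in idx])

        for _ in range(max_iters):
            r = res(y) / scales
            if np.linalg.norm(r) < tol * np.sqrt(idx.size):
                return y
            h = 1.0e-7 * Y_TYP[idx]
            ycols = np.repeat(y[:, None], idx.size, axis=1)
            ycols[idx, np.arange(idx.size)] += h
            jac = (res(ycols) / scales[:, None] - r[:, None]) / h[None, :]
            try:
                step = np.linalg.solve(jac, -r)
            except np.linalg.LinAlgError as exc:
                raise RuntimeError(
                    "singular Jacobian during consistent initialization "
                    "(sealed chamber with no pump?)"
                ) from exc
            # damped update for robustness against the stiff orifice law
            lam = 1.0
            for _ls in range(30):
                y_try = y.copy()
                y_try[idx] += lam * step
                r_try = res(y_try) / scales
                if np.linalg.norm(r_try) < np.linalg.norm(r):
                    y = y_try
                    break
                lam *= 0.5
            else:
                y[idx] += step
        r = res(y) / scales
        if np.linalg.norm(r) < 1.0e-6 * np.sqrt(idx.size):
            return y
        raise RuntimeError(
            f"consistent initialization failed; scaled residual {np.linalg.norm(r):.3e}"
        )
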