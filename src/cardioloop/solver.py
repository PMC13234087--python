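"""Monolithic per-timestep Newton solve and cardiac-cycle driver.

All unknowns (circuit states, valve opening states, transvalvular flows,
pump flow and the monitored chamber pressures) are solved simultaneously at
each time step with a damped Newton iteration on the theta-scheme residual;
the Jacobian is built by vectorized forward finite differences over the
25-entry monolithic vector.  The run driver advances whole cardiac cycles
and stops once the periodic-steady-state criterion (strictly less than a
5% change of every cycle-mean pressure and flow between successive cycles)
is met, after a minimum number of cycles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .network import (ALG_IDX, G_IDX, I, N_STATES, STATE_NAMES, Y_TYP,
                      CirculationNetwork, IntegratorConfig)

__all__ = [
    "SolverError", "CycleRecord", "MonolithicSolver",
    "run_cycles", "periodicity_check", "integrate_theta",
]

log = logging.getLogger(__name__)

#: signals checked by the periodic-steady-state criterion (pressures/flows)
MONITORED_SIGNALS = tuple(n for n in STATE_NAMES if n[0] in ("p", "q"))


def integrate_theta(mass_diag, f, y0, t_grid, theta: float = 0.5,
                    newton_tol: float = 1.0e-12, max_iters: int = 20):
    """Generic one-step theta scheme M dy/dt = f(t, y) on a time grid.

    Solves M (y^n - y^{n-1}) = dt [theta f(t_n, y^n) + (1-theta) f(t_{n-1},
    y^{n-1})] with a damped Newton iteration (finite-difference Jacobian).
    Returns (trajectory of shape (len(t_grid), n), max Newton iterations
    observed).  theta = 0.5 is the second-order midpoint/trapezoid scheme;
    this small utility is the reference integrator for convergence
    benchmarks of the full monolithic solver.
    """
    m = np.asarray(mass_diag, dtype=float)
    y = np.asarray(y0, dtype=float).copy()
    out = np.empty((len(t_grid), y.size))
    out[0] = y
    worst = 0
    for j in range(len(t_grid) - 1):
        t0, t1 = t_grid[j], t_grid[j + 1]
        dt = t1 - t0
        f0 = np.asarray(f(t0, y), dtype=float)

        def res(yn):
            return m * (yn - y) - dt * (theta * np.asarray(f(t1, yn))
                                        + (1 - theta) * f0)

        yn = y.copy()
        for it in range(1, max_iters + 1):
            r = res(yn)
            if np.linalg.norm(r) < newton_tol * max(1.0, np.linalg.norm(yn)):
                it -= 1
                break
            h = 1e-8 * np.maximum(np.abs(yn), 1.0)
            jac = np.empty((y.size, y.size))
            for k in range(y.size):
                yk = yn.copy()
                yk[k] += h[k]
                jac[:, k] = (res(yk) - r) / h[k]
            yn = yn + np.linalg.solve(jac, -r)
        worst = max(worst, it)
        y = yn
        out[j + 1] = y
    return out, worst


class SolverError(RuntimeError):
    """Newton nonconvergence; carries the residual-norm history."""

    def __init__(self, message: str, residual_history=None, t=None):
        super().__init__(message)
        self.residual_history = list(residual_history or [])
        self.t = t


@dataclass
class CycleRecord:
    """Trajectories of the monolithic state over one cardiac cycle.

    The grid covers [k*T, (k+1)*T] inclusive of both endpoints.
    """

    index: int
    t: np.ndarray
    data: Dict[str, np.ndarray]
    newton_iters: Optional[np.ndarray] = None

    @property
    def period(self) -> float:
        return float(self.t[-1] - self.t[0])

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[name]

    def mean(self, name: str) -> float:
        # time average by trapezoid over the inclusive grid
        return float(np.trapezoid(self.data[name], self.t) / self.period)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time": self.t, **self.data})

    def to_tidy_frame(self):
        frame = self.to_frame().melt(id_vars="time", var_name="variable",
                                     value_name="value")
        return frame


class MonolithicSolver:
    """Implicit theta-scheme stepper for a :class:`CirculationNetwork`."""

    def __init__(self, network: CirculationNetwork,
                 cfg: Optional[IntegratorConfig] = None):
        self.network = network
        self.cfg = cfg or IntegratorConfig()
        self._scales = network.row_scales(self.cfg.dt)

    def newton_step(self, t_prev: float, y_prev: np.ndarray, t_n: float,
                    dqdt_prev: Optional[Dict[str, float]] = None
                    ) -> Tuple[np.ndarray, int]:
        """Advance one step; returns (y_n, newton iteration count)."""
        cfg = self.cfg
        residual = self.network.make_step_residual(t_prev, y_prev, t_n, cfg,
                                                   dqdt_prev)
        scales = self._scales
        sqrtn = np.sqrt(N_STATES)
        def masked(r_vec: np.ndarray, y_vec: np.ndarray) -> np.ndarray:
            # complementarity at the valve-state bounds: when g sits on a
            # bound and its ODE row pushes outward, the clamp is the
            # solution and the row is dropped from the system
            r_out = r_vec.copy()
            for g in G_IDX:
                if (y_vec[g] <= 0.0 and r_out[g] > 0.0) or \
                        (y_vec[g] >= 1.0 and r_out[g] < 0.0):
                    r_out[g] = 0.0
            return r_out

        y = y_prev.copy()
        history = []
        r = masked(residual(y) / scales, y)
        norm = np.linalg.norm(r) / sqrtn
        history.append(norm)
        if norm < cfg.newton_tol:
            return y, 0
        h = 1.0e-7 * Y_TYP
        for it in range(1, cfg.max_newton_iters + 1):
            ycols = np.repeat(y[:, None], N_STATES, axis=1)
            ycols[np.arange(N_STATES), np.arange(N_STATES)] += h
            rcols = residual(ycols) / scales[:, None]
            jac = (rcols - r[:, None]) / h[None, :]
            for g in G_IDX:
                if r[g] == 0.0 and (y[g] <= 0.0 or y[g] >= 1.0):
                    jac[g, :] = 0.0
                    jac[g, g] = 1.0
            try:
                lu = lu_factor(jac)
                step = lu_solve(lu, -r)
            except (np.linalg.LinAlgError, ValueError) as exc:
                raise SolverError(f"singular Jacobian at t={t_n:.4f}s: {exc}",
                                  history, t_n) from exc
            # damped Newton: prefer a residual-reducing step but fall back to
            # the full step (the path is non-monotone near the orifice-law
            # zero crossings, so strict monotone searches stall)
            best = None
            for lam in (1.0, 0.5, 0.25):
                y_try = y + lam * step
                for g in G_IDX:
                    y_try[g] = np.clip(y_try[g], 0.0, 1.0)
                r_try = masked(residual(y_try) / scales, y_try)
                norm_try = np.linalg.norm(r_try) / sqrtn
                if lam == 1.0 and np.isfinite(norm_try):
                    best = (y_try, r_try, norm_try)
                if np.isfinite(norm_try) and norm_try < norm:
                    best = (y_try, r_try, norm_try)
                    break
            if best is None:  # full step non-finite: shrink hard
                lam = 0.1
                while True:
                    y_try = y + lam * step
                    for g in G_IDX:
                        y_try[g] = np.clip(y_try[g], 0.0, 1.0)
                    r_try = masked(residual(y_try) / scales, y_try)
                    norm_try = np.linalg.norm(r_try) / sqrtn
                    if np.isfinite(norm_try) or lam < 1e-6:
                        break
                    lam *= 0.1
                best = (y_try, r_try, norm_try)
            y, r, norm = best
            history.append(norm)
            if norm < cfg.newton_tol:
                return y, it
        raise SolverError(
            f"Newton failed to converge at t={t_n:.4f}s "
            f"(residual {norm:.3e} after {cfg.max_newton_iters} iters)",
            history, t_n)


def periodicity_check(cycle_k: CycleRecord, cycle_km1: CycleRecord,
                      threshold: float = 0.05, floor: float = 1.0e-6
                      ) -> Tuple[bool, Dict[str, float]]:
    """Strict "< threshold" relative change of cycle-mean pressures/flows.

    Returns (is_periodic, per-signal relative changes).  The floor guards
    division by near-zero cycle means (internal units).
    """
    if cycle_k.t.shape != cycle_km1.t.shape or not np.allclose(
            cycle_k.t - cycle_k.t[0], cycle_km1.t - cycle_km1.t[0]):
        raise ValueError("cycle records are not on matching time grids")
    changes = {}
    for name in MONITORED_SIGNALS:
        m_k = cycle_k.mean(name)
        m_km1 = cycle_km1.mean(name)
        changes[name] = abs(m_k - m_km1) / max(abs(m_km1), floor)
    return max(changes.values()) < threshold, changes


def run_cycles(network: CirculationNetwork,
               cfg: Optional[IntegratorConfig] = None, *,
               y0: Optional[np.ndarray] = None,
               n_min_cycles: int = 3, max_cycles: int = 12,
               periodicity_threshold: float = 0.05
               ) -> Tuple[List[CycleRecord], bool]:
    """Advance whole cardiac cycles until periodic steady state.

    Returns (cycle records, periodic_flag).  At least ``n_min_cycles`` are
    simulated; the run stops early once two successive cycles agree to the
    periodicity criterion, or at ``max_cycles`` with periodic_flag False.
    """
    cfg = cfg or IntegratorConfig()
    solver = MonolithicSolver(network, cfg)
    T = network.period
    n_steps = int(round(T / cfg.dt))
    if abs(n_steps * cfg.dt - T) > 1e-9 * T:
        raise ValueError(f"cycle length {T} is not an integer number of steps dt={cfg.dt}")
    y = network.initial_state(0.0, cfg=cfg) if y0 is None else np.asarray(y0, float).copy()
    from .network import _VALVE_WIRING

    q_idx = {name: qi for name, (gi, qi, ui, di) in _VALVE_WIRING.items()}
    dqdt = {name: 0.0 for name in q_idx}

    def advance(t0: float, y_in: np.ndarray, dt: float, depth: int = 0
                ) -> Tuple[np.ndarray, int]:
        """One implicit step with recursive halving on nonconvergence
        (valve transitions under suction can be too violent for one step)."""
        try:
            y_out, it = solver.newton_step(t0, y_in, t0 + dt, dqdt)
        except SolverError:
            if depth >= 6:
                raise
            y_mid, it1 = advance(t0, y_in, 0.5 * dt, depth + 1)
            y_out, it2 = advance(t0 + 0.5 * dt, y_mid, 0.5 * dt, depth + 1)
            return y_out, it1 + it2
        b = dt / (dt + cfg.dqdt_filter_tau)
        for name, qi in q_idx.items():
            raw = (y_out[qi] - y_in[qi]) / dt
            dqdt[name] = b * raw + (1.0 - b) * dqdt[name]
        return y_out, it

    cycles: List[CycleRecord] = []
    periodic = False
    for k in range(max_cycles):
        t_grid = k * T + cfg.dt * np.arange(n_steps + 1)
        traj = np.empty((n_steps + 1, N_STATES))
        iters = np.zeros(n_steps + 1, dtype=int)
        traj[0] = y
        for j in range(n_steps):
            try:
                y, it = advance(t_grid[j], y, cfg.dt)
            except SolverError as exc:
                raise SolverError(
                    f"cycle {k}, step {j + 1}: {exc}",
                    exc.residual_history, exc.t) from exc
            traj[j + 1] = y
            iters[j + 1] = it
        data = {name: traj[:, i].copy() for i, name in enumerate(STATE_NAMES)}
        # derived: prescribed chamber volumes and coronary flows
        data["v_la"] = np.asarray(network.la.volume(t_grid), dtype=float)
        data["v_lv"] = np.asarray(network.lv.volume(t_grid), dtype=float)
        data["q_cor"] = (data["p_cor"] - data["p_ra"]) / network.params.r_cor_dist
        rec = CycleRecord(index=k, t=t_grid, data=data, newton_iters=iters)
        cycles.append(rec)
        log.info("cycle %d: mean Newton iters %.1f", k, iters[1:].mean())
        if k >= 1:
            periodic, changes = periodicity_check(
                rec, cycles[-2], threshold=periodicity_threshold)
            log.info("cycle %d: max periodicity delta %.3f", k,
                     max(changes.values()))
            if periodic and k + 1 >= n_min_cycles:
                break
            periodic = False
    return cycles, periodic
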