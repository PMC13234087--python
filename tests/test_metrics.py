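"""Per-cycle clinical metrics against analytic oracles."""

import numpy as np
import pytest

from cardioloop.metrics import (e_wave_proxy, forward_co, forward_volume,
                                pulse_pressure, pv_loop, regurgitant_volume)
from cardioloop.solver import CycleRecord
from cardioloop.units import LMIN_TO_MM3S, pa
from cardioloop.valves import ValveGeometry

MV = ValveGeometry(17.0, 9.0)


def _record(T=1.0, n=1001, **signals):
    t = np.linspace(0.0, T, n)
    data = {}
    for name, val in signals.items():
        data[name] = val(t) if callable(val) else np.full(n, float(val))
    return CycleRecord(index=0, t=t, data=data), t


class TestRegurgitantVolume:
    def test_all_forward_flow_gives_zero(self):
        rec, _ = _record(q_mv=25000.0)
        assert regurgitant_volume(rec, "mv") == 0.0

    def test_square_pulse_analytic_integral(self):
        # Q = -1000 mm^3/s over the whole 0.1 s record: 100 mm^3 = 0.1 mL
        rec, _ = _record(T=0.1, q_av=-1000.0)
        assert regurgitant_volume(rec, "av") == pytest.approx(0.1)

    def test_sign_flip_swaps_forward_and_regurgitant(self):
        rec, _ = _record(q_tv=lambda t: 30000 * np.sin(2 * np.pi * t))
        fwd = forward_volume(rec, "tv")
        reg = regurgitant_volume(rec, "tv")
        assert regurgitant_volume(rec, "tv", forward_sign=-1) == \
            pytest.approx(fwd)
        assert forward_volume(rec, "tv", forward_sign=-1) == pytest.approx(reg)

    def test_decomposition_is_trapezoid_exact(self):
        rng = np.random.default_rng(42)
        q = rng.normal(0.0, 2e4, 501)
        rec, t = _record(n=501, q_pv=lambda tt: np.interp(tt, np.linspace(0, 1, 501), q))
        net = np.trapezoid(rec["q_pv"], rec.t) / 1000.0
        assert forward_volume(rec, "pv") - regurgitant_volume(rec, "pv") == \
            pytest.approx(net, abs=1e-12)


class TestForwardCO:
    def test_constant_pump_only(self):
        rec, _ = _record(q_vad=3.7 * LMIN_TO_MM3S, q_av=0.0)
        assert forward_co(rec) == pytest.approx(3.7)

    def test_pump_with_aortic_backflow(self):
        # 3.7 L/min pump, 6.5 mL/beat AV backflow, T = 0.722 s
        T = 0.722
        back = -6500.0 / T    # constant backward flow summing to 6.5 mL
        rec, _ = _record(T=T, q_vad=3.7 * LMIN_TO_MM3S, q_av=back)
        expected = 3.7 - 6.5e-3 * 60.0 / T
        assert forward_co(rec) == pytest.approx(expected, rel=1e-12)
        assert forward_co(rec) == pytest.approx(3.16, abs=0.005)

    def test_pulsatile_ejection_no_pump(self):
        # 70 mL/beat at T = 1 s -> 4.2 L/min
        # half-sine ejection over [0, 0.5] s integrating to 70 mL/beat
        rec, _ = _record(q_vad=0.0,
                         q_av=lambda t: np.where(
                             t < 0.5,
                             70e3 * np.pi / (2 * 0.5) * np.sin(np.pi * t / 0.5),
                             0.0))
        assert forward_co(rec) == pytest.approx(4.2, rel=1e-3)


class TestPulsePressure:
    def test_constant_pressure(self):
        rec, _ = _record(p_ao=pa(90.0))
        assert pulse_pressure(rec) == 0.0

    def test_sinusoid_peak_to_trough(self):
        rec, _ = _record(p_ao=lambda t: pa(90 + 10 * np.sin(2 * np.pi * t)))
        assert pulse_pressure(rec) == pytest.approx(20.0, rel=1e-4)

    def test_time_shift_invariance(self):
        f = lambda t: pa(80 + 15 * np.sin(2 * np.pi * t) + 5 * np.cos(4 * np.pi * t))
        rec1, _ = _record(p_ao=f)
        rec2, _ = _record(p_ao=lambda t: f(t + 0.31))
        assert pulse_pressure(rec1) == pytest.approx(pulse_pressure(rec2),
                                                     rel=1e-3)


class TestPVLoop:
    def test_sinusoidal_volume_extrema(self):
        rec, _ = _record(
            v_lv=lambda t: (130 + 30 * np.sin(2 * np.pi * t)) * 1e3,
            p_lv=lambda t: pa(20 + 15 * np.cos(2 * np.pi * t)))
        _, idx = pv_loop(rec, "lv")
        assert idx["edv_ml"] == pytest.approx(160.0, rel=1e-4)
        assert idx["esv_ml"] == pytest.approx(100.0, rel=1e-4)
        assert idx["sv_ml"] == pytest.approx(60.0, rel=1e-3)
        # ED is at maximum volume (t = 0.25): P = 20 mmHg there
        assert idx["edp_mmhg"] == pytest.approx(20.0, abs=0.01)
        assert not idx["degenerate"]

    def test_ef_arithmetic(self):
        rec, _ = _record(
            v_rv=lambda t: (167.0 - 60.0 * np.clip(np.sin(np.pi * t), 0, 1)) * 1e3,
            p_rv=pa(15.0))
        _, idx = pv_loop(rec, "rv")
        assert idx["ef"] == pytest.approx(60.0 / 167.0, rel=1e-3)

    def test_constant_volume_flagged_degenerate(self):
        rec, _ = _record(v_lv=150e3, p_lv=pa(10.0))
        _, idx = pv_loop(rec, "lv")
        assert idx["degenerate"]
        assert idx["sv_ml"] == 0.0
        assert idx["ef"] == 0.0


class TestEWaveProxy:
    def test_velocity_division(self):
        # 480660 mm^3/s through the fully open MV (480.66 mm^2)
        # = 1000 mm/s = 100 cm/s
        rec, _ = _record(g_mv=1.0, q_mv=480660.0)
        assert e_wave_proxy(rec, MV) == pytest.approx(
            480660.0 / (np.pi * 153.0) / 10.0, rel=1e-9)
        assert e_wave_proxy(rec, MV) == pytest.approx(100.0, rel=1e-3)

    def test_zero_flow_gives_zero(self):
        rec, _ = _record(g_mv=1.0, q_mv=0.0)
        assert e_wave_proxy(rec, MV) == 0.0

    def test_never_open_is_missing(self):
        rec, _ = _record(g_mv=0.1, q_mv=500.0)
        assert e_wave_proxy(rec, MV) is None

    def test_halved_area_doubles_velocity(self):
        rec1, _ = _record(g_mv=1.0, q_mv=40000.0)
        rec2, _ = _record(g_mv=1.0 / np.sqrt(2.0), q_mv=40000.0)
        assert e_wave_proxy(rec2, MV) == pytest.approx(
            2.0 * e_wave_proxy(rec1, MV))
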