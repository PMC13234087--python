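"""Valve geometry, opening-state ODE and orifice flow law."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardioloop.parameters import BloodProperties
from cardioloop.valves import (ValveGeometry, ValveState, alpha,
                               effective_area, g_min_from_roa, orifice_flow,
                               valve_rhs)

MV = ValveGeometry(17.0, 9.0, "ellipse")
AV = ValveGeometry.circle(13.0)
BLOOD = BloodProperties()


class TestGeometry:
    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            ValveGeometry(9.0, 17.0)        # l_a < l_b
        with pytest.raises(ValueError):
            ValveGeometry(17.0, 9.0, "circle")

    @pytest.mark.parametrize("roa, geom, expected", [
        (44.0, MV, 0.302556),   # mitral floor from the fitted ROA
        (6.0, AV, 0.106306),    # aortic floor
        (np.pi * 17 * 9, MV, 1.0),
        (0.0, MV, 0.0),
    ])
    def test_gmin_from_roa(self, roa, geom, expected):
        assert g_min_from_roa(roa, geom) == pytest.approx(expected, abs=5e-6)

    def test_roa_above_full_open_area_rejected(self):
        with pytest.raises(ValueError):
            g_min_from_roa(MV.full_open_area + 1.0, MV)

    def test_effective_area_full_open(self):
        assert effective_area(1.0, MV) == pytest.approx(np.pi * 153.0)
        assert effective_area(0.0, MV) == 0.0

    @given(st.floats(0.01, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_area_gmin_round_trip(self, g):
        assert g_min_from_roa(effective_area(g, MV), MV) == pytest.approx(g)

    def test_area_strictly_increasing_in_g(self):
        g = np.linspace(0.0, 1.0, 50)
        assert np.all(np.diff(effective_area(g, AV)) > 0)


class TestSwitchingVariable:
    def test_zero_inputs_give_zero(self):
        assert alpha(0.0, 0.0, 0.0) == 0.0

    def test_tanh_saturation(self):
        assert alpha(1e9, 0.0, 0.0) == pytest.approx(1.0)
        assert alpha(-1e9, 0.0, 0.0) == pytest.approx(-1.0)

    def test_unit_argument(self):
        # C2 * dP = 1 with no flow terms
        assert alpha(1000.0, 0.0, 0.0, c2=0.001) == pytest.approx(np.tanh(1.0))


class TestValveOde:
    def test_rhs_zero_at_alpha_zero(self):
        assert valve_rhs(0.5, 0.0) == 0.0      # sgn(0) = 0

    def test_fixed_points(self):
        assert valve_rhs(1.0, 1.0) == pytest.approx(0.0)
        assert valve_rhs(0.0, -1.0) == pytest.approx(0.0)

    def test_closing_matches_exponential_decay(self):
        # alpha = -1: dg/dt = -C1 g, so g(t) = exp(-C1 t)
        c1, t_end, n = 800.0, 0.0015, 3000
        g = 1.0
        dt = t_end / n
        for _ in range(n):   # RK4 as an independent numerical oracle
            k1 = valve_rhs(g, -1.0, c1)
            k2 = valve_rhs(g + 0.5 * dt * k1, -1.0, c1)
            k3 = valve_rhs(g + 0.5 * dt * k2, -1.0, c1)
            k4 = valve_rhs(g + dt * k3, -1.0, c1)
            g += dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        assert g == pytest.approx(np.exp(-c1 * t_end), rel=1e-6)
        assert g == pytest.approx(0.301, abs=5e-4)

    def test_full_transition_within_one_percent_of_cycle(self):
        # saturated alpha = -1: time from g=0.99 to g=0.01 is ln(99)/C1
        assert np.log(0.99 / 0.01) / 800.0 <= 0.01
        # opening with alpha = +1: dg/dt = C1 (1 - g), same time constant
        assert np.log(0.99 / 0.01) / 800.0 == pytest.approx(0.00574, abs=1e-4)

    @given(st.lists(st.floats(-1.0, 1.0), min_size=5, max_size=60))
    @settings(max_examples=30, deadline=None)
    def test_g_stays_in_unit_interval(self, alphas):
        g, dt = 0.5, 1e-3
        for a in alphas:
            g = float(np.clip(g + dt * valve_rhs(g, a, sgn_eps=0.05), 0.0, 1.0))
            assert 0.0 <= g <= 1.0


class TestOrificeFlow:
    def test_zero_cases(self):
        assert orifice_flow(100.0, 100.0, 50.0, BLOOD) == 0.0
        assert orifice_flow(5000.0, 0.0, 0.0, BLOOD) == 0.0  # competent valve

    def test_bernoulli_hand_value(self):
        # area 100 mm^2, dP 1000 Pa: Q = 100 * sqrt(2*1000/1.026e-3)
        q = orifice_flow(1000.0, 0.0, 100.0, BLOOD)
        assert q == pytest.approx(100.0 * np.sqrt(2000.0 / 1.026e-3), rel=1e-12)
        assert q == pytest.approx(1.396e5, rel=1e-3)

    def test_odd_in_pressure_difference(self):
        q_fwd = orifice_flow(1200.0, 200.0, 80.0, BLOOD)
        q_bwd = orifice_flow(200.0, 1200.0, 80.0, BLOOD)
        assert q_fwd == -q_bwd

    def test_monotone_in_dp_and_area(self):
        dps = np.linspace(-2000, 2000, 41)
        q = orifice_flow(dps, 0.0, 100.0, BLOOD)
        assert np.all(np.diff(q) > 0)
        areas = np.linspace(0.0, 400.0, 30)
        q = orifice_flow(800.0, 0.0, areas, BLOOD)
        assert np.all(np.diff(q) > 0)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            orifice_flow(100.0, 0.0, -1.0, BLOOD)

    def test_regularized_law_matches_away_from_crossing(self):
        exact = orifice_flow(1000.0, 0.0, 100.0, BLOOD)
        reg = orifice_flow(1000.0, 0.0, 100.0, BLOOD, dp_eps=0.5)
        assert reg == pytest.approx(exact, rel=1e-3)

    def test_repair_limit_no_regurgitation(self):
        # g_min = 0 and sustained alpha = -1: g -> 0, area -> 0, flow -> 0
        vs = ValveState(geometry=MV, g=1.0, g_min=0.0)
        g, dt = vs.g, 1e-4
        for _ in range(1000):
            g = float(np.clip(g + dt * valve_rhs(g, -1.0, vs.c1), 0.0, 1.0))
        area = effective_area(max(g, vs.g_min), MV)
        assert area < 1e-30
        assert orifice_flow(8000.0, 0.0, area, BLOOD) < 1e-12
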