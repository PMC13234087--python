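"""Objective, clinical constraint helpers, fitter machinery and sensitivity.

The heavy simulator-in-the-loop recovery test lives in the acceptance
suite; here the fitter is exercised against cheap analytic mock models so
its machinery (projection, GD -> LM hand-off, penalty row) is tested in
isolation.
"""

import numpy as np
import pytest

from cardioloop.parameters import ParameterVector
from cardioloop.personalization import (ClinicalTargets, FitConfig,
                                        TargetEntry, coronary_flow_target,
                                        fit_parameters, nadler_blood_volume,
                                        objective, sensitivity_analysis,
                                        severity_bounds)


def _targets(values: dict, **meta) -> ClinicalTargets:
    meta = {"height_m": 1.75, "weight_kg": 80.0, "sex": "male", **meta}
    return ClinicalTargets(
        entries=[TargetEntry(k, v) for k, v in values.items()], **meta)


class _MockRunner:
    """Forward model: each output is a smooth function of two parameters."""

    def __init__(self, scale=1.0):
        self.scale = scale

    def predict(self, theta: ParameterVector):
        r, c = theta.r_sys_dist, theta.c_sys_ar
        return {
            "flow": 10.0 / r,             # pure series-resistance branch
            "pressure": 50.0 * r + 2.0 * c,
            "volume": 12.0 * c,
            "constant": 7.0,              # no causal path to any parameter
        }

    def total_blood_volume_l(self, theta: ParameterVector):
        # depends on the fitted compliance, as in the full model
        return 5.0 + 0.01 * (theta.c_sys_ar - 11.0)


class TestObjective:
    def test_exact_match_is_zero(self):
        runner = _MockRunner()
        preds = runner.predict(ParameterVector())
        assert objective(ParameterVector(), _targets(preds), runner) == 0.0

    def test_single_ten_percent_error(self):
        runner = _MockRunner()
        preds = runner.predict(ParameterVector())
        preds["flow"] /= 1.1   # model overshoots this target by 10%
        t = _targets(preds)
        j = objective(ParameterVector(), t, runner)
        assert j == pytest.approx(0.5 * 0.1 ** 2, rel=1e-9)

    def test_twenty_targets_all_off_ten_percent(self):
        class Wide:
            def predict(self, theta):
                return {f"y{i}": 1.1 for i in range(20)}

            def total_blood_volume_l(self, theta):
                return 5.0

        t = _targets({f"y{i}": 1.0 for i in range(20)})
        assert objective(ParameterVector(), t, Wide()) == \
            pytest.approx(20 * 0.005, rel=1e-12)

    def test_permutation_invariance(self):
        runner = _MockRunner()
        preds = runner.predict(ParameterVector())
        items = list(preds.items())
        j1 = objective(ParameterVector(), _targets(dict(items)), runner)
        j2 = objective(ParameterVector(), _targets(dict(items[::-1])), runner)
        assert j1 == j2

    def test_zero_valued_target_rejected(self):
        with pytest.raises(ValueError):
            TargetEntry("bad", 0.0)


class TestClinicalHelpers:
    def test_nadler_hand_values(self):
        # female 1.63 m / 70 kg and male 1.80 m / 80 kg, cited constants
        assert nadler_blood_volume(1.63, 70.0, "female") == \
            pytest.approx(0.3561 * 1.63 ** 3 + 0.03308 * 70 + 0.1833, rel=1e-12)
        assert nadler_blood_volume(1.63, 70.0, "f") == pytest.approx(4.041, abs=5e-4)
        assert nadler_blood_volume(1.80, 80.0, "male") == pytest.approx(5.319, abs=5e-4)

    def test_nadler_intercepts_and_warnings(self):
        tiny = 1e-9
        with pytest.warns(UserWarning):
            assert nadler_blood_volume(tiny, tiny, "female") == \
                pytest.approx(0.1833, abs=1e-6)
        with pytest.warns(UserWarning):
            assert nadler_blood_volume(tiny, tiny, "male") == \
                pytest.approx(0.6041, abs=1e-6)
        with pytest.warns(UserWarning):
            nadler_blood_volume(2.7, 80.0, "male")
        with pytest.raises(ValueError):
            nadler_blood_volume(1.7, 70.0, "unknown")

    def test_coronary_flow_scaling(self):
        assert coronary_flow_target(100.0) == 80.0
        assert coronary_flow_target(150.0) == 120.0
        assert coronary_flow_target(0.0) == 0.0
        with pytest.raises(ValueError):
            coronary_flow_target(-1.0)

    def test_severity_bounds_table(self):
        assert severity_bounds("none") == (0.0, 0.0)
        lo, hi = severity_bounds("severe")
        assert lo < 44.0 <= hi       # the fitted mitral ROA is admissible
        lo, hi = severity_bounds("mild")
        assert lo < 6.0 <= hi        # the fitted aortic ROA is admissible
        with pytest.raises(ValueError):
            severity_bounds("catastrophic")


class TestFitter:
    FREE = ("r_sys_dist", "c_sys_ar")

    def test_infeasible_bounds_rejected(self):
        cfg = FitConfig(free_params=self.FREE,
                        bounds={"r_sys_dist": (1.0, 0.5)})
        with pytest.raises(ValueError):
            cfg.resolve_bounds(ParameterVector())

    def test_severity_class_maps_to_roa_bounds(self):
        cfg = FitConfig(free_params=("roa_mv",))
        t = _targets({"flow": 1.0}, valve_severity={"mv": "moderate"})
        assert cfg.resolve_bounds(ParameterVector(), t)["roa_mv"] == (20.0, 40.0)

    def test_start_at_optimum_converges_immediately(self):
        runner = _MockRunner()
        theta_star = ParameterVector(c_sys_ar=11.0)  # TBV(theta*) = 5.0 L
        t = _targets(runner.predict(theta_star),
                     height_m=1.6265, weight_kg=60.0)  # Nadler ~ 5.0 L
        v_n = t.nadler_volume_l()
        # shift weight so the Nadler volume matches TBV(theta*) exactly
        t.weight_kg += (5.0 - v_n) / 0.03219
        res = fit_parameters(t, FitConfig(free_params=self.FREE, gd_iters=2),
                             runner, theta0=theta_star)
        assert res.j_trace[0] == pytest.approx(0.0, abs=1e-20)
        assert res.diagnostics["j_total_final"] < 1e-10

    def test_recovery_from_perturbed_start(self):
        runner = _MockRunner()
        theta_star = ParameterVector()
        t = _targets(runner.predict(theta_star), height_m=1.6265,
                     weight_kg=60.0)
        t.weight_kg += (runner.total_blood_volume_l(theta_star)
                        - t.nadler_volume_l()) / 0.03219
        theta0 = theta_star.with_values(r_sys_dist=0.2, c_sys_ar=8.0)
        res = fit_parameters(t, FitConfig(free_params=self.FREE, gd_iters=5),
                             runner, theta0=theta0)
        assert res.diagnostics["j_final"] < 1e-12
        assert res.theta_hat.r_sys_dist == pytest.approx(0.13, rel=1e-4)
        assert res.theta_hat.c_sys_ar == pytest.approx(11.0, rel=1e-4)
        # objective non-increasing along the accepted-step trace
        assert np.all(np.diff(res.j_total_trace) <= 1e-15)

    def test_matches_scipy_lm_on_unconstrained_problem(self):
        from scipy.optimize import least_squares

        runner = _MockRunner()
        theta_star = ParameterVector()
        t = _targets(runner.predict(theta_star), height_m=1.6265,
                     weight_kg=60.0)
        t.weight_kg += (runner.total_blood_volume_l(theta_star)
                        - t.nadler_volume_l()) / 0.03219
        v_n = t.nadler_volume_l()

        def resid(x):
            th = theta_star.with_array(x, self.FREE)
            preds = runner.predict(th)
            r = [(preds[e.name] - e.value) / e.value for e in t.entries]
            r.append(10.0 * (runner.total_blood_volume_l(th) - v_n) / v_n)
            return np.array(r)

        x0 = np.array([0.2, 8.0])
        ref = least_squares(resid, x0, method="lm")
        res = fit_parameters(t, FitConfig(free_params=self.FREE, gd_iters=0),
                             runner,
                             theta0=theta_star.with_array(x0, self.FREE))
        assert res.theta_hat.as_array(self.FREE) == pytest.approx(
            ref.x, rel=1e-4)

    def test_noise_scaling_of_fitted_objective(self):
        # with multiplicative target noise the residual left after fitting
        # 2 parameters against 4 targets scales with the noise variance
        rng = np.random.default_rng(7)
        runner = _MockRunner()
        theta_star = ParameterVector()
        base = runner.predict(theta_star)
        j_hat = {}
        for noise in (0.02, 0.05):
            z = rng.standard_normal(len(base))
            noisy = {k: v * (1 + noise * zi)
                     for (k, v), zi in zip(base.items(), z)}
            t = _targets(noisy, height_m=1.6265, weight_kg=60.0)
            t.weight_kg += (5.0 - t.nadler_volume_l()) / 0.03219
            res = fit_parameters(
                t, FitConfig(free_params=self.FREE, gd_iters=3,
                             volume_weight=1e-6), runner, theta0=theta_star)
            expectation = 0.5 * np.sum((noise * z) ** 2)
            j_hat[noise] = (res.diagnostics["j_final"], expectation)
        for j, expect in j_hat.values():
            assert j < 3.0 * expect


class TestSensitivity:
    def test_series_resistance_ohmic_closed_form(self):
        runner = _MockRunner()
        m = sensitivity_analysis(ParameterVector(), runner,
                                 params=["r_sys_dist"], delta=0.1)
        up = m.loc[("r_sys_dist", "+10%"), "flow"]
        down = m.loc[("r_sys_dist", "-10%"), "flow"]
        assert up == pytest.approx(1 / 1.1 - 1, rel=1e-9)     # -9.09%
        assert down == pytest.approx(1 / 0.9 - 1, rel=1e-9)   # +11.1%

    def test_no_causal_path_gives_zero_change(self):
        runner = _MockRunner()
        m = sensitivity_analysis(ParameterVector(), runner,
                                 params=["r_pul_ar"])
        assert (m.loc[("r_pul_ar", "+10%")] == 0.0).all()

    def test_bit_exact_reproducibility(self):
        runner = _MockRunner()
        m1 = sensitivity_analysis(ParameterVector(), runner,
                                  params=["r_sys_dist", "c_sys_ar"])
        m2 = sensitivity_analysis(ParameterVector(), runner,
                                  params=["r_sys_dist", "c_sys_ar"])
        assert m1.equals(m2)

    def test_matrix_shape_covers_both_directions(self):
        runner = _MockRunner()
        m = sensitivity_analysis(ParameterVector(), runner)
        assert m.shape == (23 * 2, 4)
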