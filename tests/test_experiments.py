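"""Experiment drivers: sweeps, regressions, slope studies, reports."""
import numpy as np
import pandas as pd
import pytest

import pogo
from pogo.experiments import (GaitMetrics, SweepResult, _parabolic_min,
                              kram_taylor_regression, load_grf_table,
                              unified_nominal_report)


class TestKramTaylorRegression:
    @staticmethod
    def _synthetic_sweep(cost_rate, contact_time, v):
        rows = [dict(v=vi, cost_rate=ci, contact_time=ti, converged=True)
                for vi, ci, ti in zip(v, cost_rate, contact_time)]
        return SweepResult(rows, [None] * len(rows), "x", "y")

    def test_perfectly_proportional_inputs_give_r2_of_one(self):
        v = np.linspace(2, 4, 7)
        tc = 1.0 / (2.0 + 0.8 * v)        # 1/tc affine in v
        cost = 50.0 + 400.0 / tc          # cost affine in 1/tc
        sweep = self._synthetic_sweep(cost, tc, v)
        r2a, r2b = kram_taylor_regression(sweep)
        assert r2a == pytest.approx(1.0, abs=1e-12)
        assert r2b == pytest.approx(1.0, abs=1e-12)

    def test_r2_invariant_to_affine_unit_rescaling(self):
        rng = np.random.default_rng(5)
        v = np.linspace(2, 4, 9)
        tc = 1.0 / (2.0 + 0.8 * v + 0.05 * rng.standard_normal(9))
        cost = 50 + 400 / tc + 20 * rng.standard_normal(9)
        base = kram_taylor_regression(self._synthetic_sweep(cost, tc, v))
        resc = kram_taylor_regression(
            self._synthetic_sweep(cost * 4.184 + 7.0, tc, v))
        assert resc[0] == pytest.approx(base[0], rel=1e-12)
        assert resc[1] == pytest.approx(base[1], rel=1e-12)

    def test_too_few_points_rejected(self):
        sweep = self._synthetic_sweep([1, 2], [0.2, 0.19], [2, 3])
        with pytest.raises(ValueError):
            kram_taylor_regression(sweep)


class TestSpeedSweep:
    def test_cost_rate_increases_with_speed(self, speed_sweep_result):
        df = speed_sweep_result.converged
        assert len(df) == 9
        assert df.cost_rate.is_monotonic_increasing

    def test_work_share_in_expected_band(self, speed_sweep_result):
        """Across 2-4 m/s the work cost dominates the total."""
        df = speed_sweep_result.converged
        share = df.E_W / (df.E_W + df.E_R)
        assert (share > 0.5).all()
        assert share.max() - share.min() < 0.15  # a narrow, stable band

    def test_contact_time_decreases_with_speed(self, speed_sweep_result):
        df = speed_sweep_result.converged
        assert df.contact_time.is_monotonic_decreasing

    def test_rows_carry_provenance(self, speed_sweep_result):
        assert speed_sweep_result.params_hash
        assert speed_sweep_result.config_hash
        assert set(["cost_rate", "contact_time", "duty_factor"]) <= set(
            speed_sweep_result.table.columns)


class TestSlopeStudy:
    def test_minimum_on_a_gentle_downhill(self, slope_study_result):
        sweep, summary = slope_study_result
        assert -0.12 < summary["grade_at_min_cot"] < -0.04

    def test_level_point_consistent_with_direct_solve(self,
                                                      slope_study_result,
                                                      nominal_solution):
        sweep, _ = slope_study_result
        df = sweep.converged
        row = df[df.grade == 0.0].iloc[0]
        audit = pogo.energy_audit(nominal_solution)
        assert row.E_total == pytest.approx(audit.E_total, rel=5e-3)

    def test_slope_curve_continuous_across_zero(self, slope_study_result):
        sweep, _ = slope_study_result
        df = sweep.converged.sort_values("grade").reset_index()
        i0 = df.index[df.grade == 0.0][0]
        # one-sided secant slopes bracket the level point smoothly
        left = (df.E_total[i0] - df.E_total[i0 - 1]) / 0.02
        right = (df.E_total[i0 + 1] - df.E_total[i0]) / 0.02
        assert np.sign(left) == np.sign(right)
        assert abs(right - left) < 0.6 * max(abs(left), abs(right))

    def test_asymptote_slopes_move_toward_efficiency_lines(
            self, slope_study_result, nominal_params):
        _, summary = slope_study_result
        up = summary["uphill_asymptote_slope"]
        down = summary["downhill_asymptote_slope"]
        assert up == pytest.approx(1 / nominal_params.eta_pos, rel=0.5)
        assert down < 0  # descending gets cheaper toward the negative line

    def test_parabolic_refinement_recovers_vertex(self):
        x = np.array([-0.10, -0.08, -0.06])
        y = 3.0 + 5.0 * (x + 0.083) ** 2
        assert _parabolic_min(x, y) == pytest.approx(-0.083, abs=1e-12)


class TestUnifiedReport:
    def test_report_contents(self, nominal_params, fast_config):
        sol, audit, metrics, report = unified_nominal_report(
            nominal_params, v=3.0, f=2.94, config=fast_config)
        assert isinstance(metrics, GaitMetrics)
        assert 0.4 < report["elastic_return_fraction"] < 0.8
        assert metrics.duty_factor == pytest.approx(
            sol.t_stance * sol.task.f, rel=1e-9)
        assert len(report["work_loop"]["vertical_displacement"]) == \
            fast_config.n_nodes

    def test_grf_rises_faster_than_it_falls(self, nominal_solution):
        """Time asymmetry of the optimal vertical GRF, as in human
        running: the force peak occurs before mid-stance."""
        gy = nominal_solution.grf[1]
        t = nominal_solution.t
        t_peak = t[int(np.argmax(gy))]
        assert t_peak < 0.5 * nominal_solution.t_stance


class TestGrfOverlay:
    def test_loads_plain_tabular_trace(self, tmp_path):
        path = tmp_path / "grf.csv"
        pd.DataFrame({"Time": [0, 0.01], "GRF_y": [0.0, 400.0]}).to_csv(
            path, index=False)
        df = load_grf_table(path)
        assert list(df.columns) == ["time", "grf_y"]

    def test_requires_time_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"a": [1], "b": [2]}).to_csv(path, index=False)
        with pytest.raises(ValueError):
            load_grf_table(path)
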