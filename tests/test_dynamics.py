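"""Unit tests for the stance/flight mechanics primitives."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

import pogo
from pogo.dynamics import (BodyState, collision_map, flight_map, grf,
                           leg_geometry, leg_powers, series_state,
                           spring_damper_force, stance_derivatives)


class TestLegGeometry:
    @pytest.mark.parametrize("x, y, L_l, unit", [
        (0.0, 0.9, 0.9, (0.0, 1.0)),
        (0.3, 0.4, 0.5, (0.6, 0.8)),
        (-0.2, 0.85, np.hypot(-0.2, 0.85), (-0.2 / np.hypot(-0.2, 0.85),
                                            0.85 / np.hypot(-0.2, 0.85))),
    ])
    def test_length_and_unit_vector(self, x, y, L_l, unit):
        length, (ux, uy) = leg_geometry(x, y)
        assert length == pytest.approx(L_l)
        assert (ux, uy) == pytest.approx(unit)

    def test_degenerate_states_rejected(self):
        with pytest.raises(ValueError):
            leg_geometry(0.3, 0.0)
        with pytest.raises(ValueError):
            leg_geometry(0.0, -0.1)


class TestSpringDamperForce:
    def test_unloaded_spring_gives_zero(self, nominal_params):
        assert spring_damper_force(0.0, 0.0, nominal_params) == 0.0

    def test_pure_spring_force_at_nominal_stiffness(self):
        # k* = 35.6 kN/m compressed 5 cm -> 1780 N
        p = pogo.ModelParams.nominal(k=35.6e3)
        assert spring_damper_force(0.05, 0.0, p) == pytest.approx(1780.0)

    def test_damper_silent_while_unloading(self, nominal_params):
        p = nominal_params
        F = spring_damper_force(0.05, -0.3, p)
        assert F == pytest.approx(p.k * 0.05)

    def test_damper_adds_force_while_loading(self, nominal_params):
        p = nominal_params
        F = spring_damper_force(0.05, +0.3, p)
        assert F == pytest.approx(p.k * 0.05 + p.c * 0.3)

    def test_smooth_switch_matches_exact_away_from_zero(self, nominal_params):
        p = nominal_params
        exact = spring_damper_force(0.04, 0.5, p)
        smooth = spring_damper_force(0.04, 0.5, p, smooth=0.01)
        assert smooth == pytest.approx(exact, rel=1e-9)


class TestStanceDerivatives:
    def test_static_balance_under_body_weight(self, nominal_params):
        p = nominal_params
        # vertical leg compressed so the spring carries exactly M g
        delta = p.M * p.g / p.k
        s = BodyState(0.0, p.L - delta, 0.0, 0.0)
        ds = stance_derivatives(s, 0.0, p)
        assert ds[2] == pytest.approx(0.0, abs=1e-10)
        assert ds[3] == pytest.approx(0.0, abs=1e-10)

    def test_unloaded_leg_free_falls(self, nominal_params):
        p = nominal_params
        # at rest length and extending: spring unloaded, damper silent
        s = BodyState(0.0, p.L, 0.0, +0.5)
        ds = stance_derivatives(s, 0.0, p)
        assert ds[2] == pytest.approx(0.0)
        assert ds[3] == pytest.approx(-p.g)

    def test_three_four_five_leg_acceleration(self):
        # independent hand computation of F * unit / M - g yhat
        p = pogo.ModelParams.nominal(M=70.0, zeta=0.0)
        s = BodyState(0.3, 0.4, 0.0, 0.0)
        _, _, _, F = series_state(s, p)
        ds = stance_derivatives(s, 0.0, p)
        assert ds[2] == pytest.approx(F * 0.6 / 70.0)
        assert ds[3] == pytest.approx(F * 0.8 / 70.0 - 9.81)

    def test_actuator_chain_integrates_jerk(self, nominal_params):
        s = BodyState(0.0, 0.8, 0.0, 0.0, q=0.01, dq=0.2, ddq=-1.0)
        ds = stance_derivatives(s, 5.0, nominal_params)
        assert tuple(ds[4:]) == (0.2, -1.0, 5.0)


class TestFlightMap:
    def test_zero_duration_is_identity(self):
        assert flight_map(0.1, 1.0, 3.0, -0.2, 0.0, 9.81) == (0.1, 1.0, 3.0, -0.2)

    def test_symmetric_parabola(self):
        g = 9.81
        x, y, vx, vy = flight_map(0.0, 1.0, 2.0, 1.0, 2.0 / g, g)
        assert vy == pytest.approx(-1.0)
        assert y == pytest.approx(1.0)

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            flight_map(0, 1, 1, 0, -0.1, 9.81)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(vx=st.floats(-3, 5), vy=st.floats(-3, 3),
           dur=st.floats(0.0, 0.6))
    def test_closed_form_matches_integration_oracle(self, vx, vy, dur):
        g = 9.81

        def rhs(t, s):
            return [s[2], s[3], 0.0, -g]

        num = solve_ivp(rhs, [0, dur], [0.2, 1.1, vx, vy],
                        rtol=1e-12, atol=1e-13).y[:, -1]
        ana = flight_map(0.2, 1.1, vx, vy, dur, g)
        assert np.allclose(num, ana, rtol=1e-10, atol=1e-10)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(vx=st.floats(-3, 5), vy=st.floats(-3, 3),
           dur=st.floats(0.0, 0.6))
    def test_flight_conserves_energy_and_horizontal_momentum(self, vx, vy, dur):
        g = 9.81
        x1, y1, vx1, vy1 = flight_map(0.0, 1.0, vx, vy, dur, g)
        assert vx1 == vx
        E0 = 0.5 * (vx**2 + vy**2) + g * 1.0
        E1 = 0.5 * (vx1**2 + vy1**2) + g * y1
        assert E1 == pytest.approx(E0, rel=1e-10, abs=1e-9)


class TestCollisionMap:
    def test_identity_without_collision(self):
        v = np.array([3.0, -0.7])
        assert np.allclose(collision_map(v, 0.0), v)

    def test_nominal_collision_loses_5_9_percent_energy(self):
        v = np.array([3.0, -0.7])
        v2 = collision_map(v, 0.03)
        loss = 1.0 - (v2 @ v2) / (v @ v)
        assert loss == pytest.approx(0.059, abs=5e-4)

    def test_double_collision_fraction(self):
        v = np.array([2.0, -1.0])
        v2 = collision_map(v, 0.06)
        assert 1.0 - (v2 @ v2) / (v @ v) == pytest.approx(1 - 0.94**2)

    @pytest.mark.parametrize("CF", [-0.1, 1.0, 1.2])
    def test_invalid_fraction_rejected(self, CF):
        with pytest.raises(ValueError):
            collision_map([1.0, 0.0], CF)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(vx=st.floats(-5, 5), vy=st.floats(-5, 5),
           CF=st.floats(0, 0.99, exclude_max=False))
    def test_energy_identity_and_direction(self, vx, vy, CF):
        v = np.array([vx, vy])
        v2 = collision_map(v, CF)
        assert v2 @ v2 == pytest.approx((1 - CF) ** 2 * (v @ v), rel=1e-12)
        # direction preserved: planar cross product vanishes
        assert v[0] * v2[1] - v[1] * v2[0] == pytest.approx(0.0, abs=1e-9)


class TestPowersAndForces:
    def test_loading_damper_never_returns_energy(self, nominal_params):
        rng = np.random.default_rng(0)
        for _ in range(50):
            s = BodyState(*rng.uniform([-0.4, 0.5, 0, -2, -0.1, -1, -5],
                                       [0.4, 0.95, 3, 2, 0.1, 1, 5]))
            _, _, _, P_damp = leg_powers(s, nominal_params)
            assert P_damp <= 0.0

    def test_grf_aligned_with_leg(self, nominal_params):
        s = BodyState(0.2, 0.8, 1.0, -0.5, q=0.02)
        gx, gy = grf(s, nominal_params)
        assert gx / gy == pytest.approx(0.2 / 0.8)

    def test_series_equilibrium_consistency(self, nominal_params):
        """Massless leg: the axial force from the series chain equals the
        spring-damper force at the resolved compression state."""
        p = nominal_params
        s = BodyState(0.1, 0.82, 1.2, -0.4, q=0.01, dq=0.1)
        L_l, delta, ddelta, F = series_state(s, p)
        assert delta == pytest.approx(p.L - L_l + s.q)
        assert F == pytest.approx(float(spring_damper_force(delta, ddelta, p)))
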