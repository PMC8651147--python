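"""Stance and flight mechanics of the actuated spring-mass runner.

Pure functions over SI-unit state, shared by the shooting integrator,
the post-hoc energy audit and the tests. The collocation NLP evaluates
the same model through the generated normalized kernels in
``pogo._kernels``; the two implementations are cross-checked in the test
suite.

State convention: the CoM position (x_b, y_b) is measured from the
stance foot contact point in a world frame with gravity (0, -g). The
leg force acts along the foot-to-CoM unit vector and is positive in
extension (pushing). The series chain satisfies L_l = L + q - delta,
where q is the actuator displacement from its nominal length and delta
the spring compression (positive into the spring), so the spring is at
rest when the leg is at full length L with the actuator nominal.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import ModelParams


@dataclass
class BodyState:
    """CoM kinematics plus the actuator chain at one stance instant."""

    x_b: float
    y_b: float
    vx_b: float
    vy_b: float
    q: float = 0.0       # actuator displacement from nominal length [m]
    dq: float = 0.0      # actuator lengthening rate [m/s]
    ddq: float = 0.0     # actuator acceleration [m/s^2]

    def as_array(self) -> np.ndarray:
        return np.array([self.x_b, self.y_b, self.vx_b, self.vy_b,
                         self.q, self.dq, self.ddq])


def leg_geometry(x_b, y_b):
    """Leg length and foot-to-CoM unit vector. Rejects y_b <= 0 (CoM at
    or below the contact) and the degenerate zero-length leg."""
    if np.any(np.asarray(y_b) <= 0):
        raise ValueError("stance requires the CoM above the contact (y_b > 0)")
    L_l = np.hypot(x_b, y_b)
    if np.any(L_l == 0):
        raise ValueError("degenerate leg of zero length")
    return L_l, (x_b / L_l, y_b / L_l)


def spring_damper_force(delta, ddelta, params: ModelParams, smooth: float = 0.0):
    """Axial force of the parallel spring-damper [N]: F = k delta +
    c ddelta while the spring is loading (ddelta > 0, compression
    increasing), and the pure spring force k delta while unloading.

    ``smooth`` > 0 replaces the on/off damper switch by a sigmoid of the
    compression rate with that width [m/s], matching the optimizer's
    differentiable model; the default is the exact switch.
    """
    delta = np.asarray(delta, dtype=float)
    ddelta = np.asarray(ddelta, dtype=float)
    if smooth > 0:
        gate = 0.5 * (1.0 + np.tanh(ddelta / (2.0 * smooth)))
    else:
        gate = (ddelta > 0).astype(float)
    return params.k * delta + params.c * ddelta * gate


def series_state(state: BodyState, params: ModelParams):
    """Resolve the massless series chain: returns (L_l, delta, ddelta,
    F_m). The spring compression follows from leg geometry and actuator
    displacement, delta = L - L_l + q."""
    L_l, _ = leg_geometry(state.x_b, state.y_b)
    dL_l = (state.x_b * state.vx_b + state.y_b * state.vy_b) / L_l
    delta = params.L - L_l + state.q
    ddelta = state.dq - dL_l
    F_m = spring_damper_force(delta, ddelta, params)
    return L_l, delta, ddelta, float(F_m)


def stance_derivatives(state: BodyState, jerk: float, params: ModelParams) -> np.ndarray:
    """Time derivative of the stance state under actuator jerk control.

    The CoM accelerates under the axial leg force (equal to the
    spring-damper force by series equilibrium of the massless leg) plus
    gravity; the actuator chain integrates (q, dq, ddq) driven by the
    jerk. Returns d/dt [x_b, y_b, vx_b, vy_b, q, dq, ddq].
    """
    _, (ux, uy) = leg_geometry(state.x_b, state.y_b)
    _, _, _, F_m = series_state(state, params)
    ax = F_m * ux / params.M
    ay = F_m * uy / params.M - params.g
    return np.array([state.vx_b, state.vy_b, ax, ay,
                     state.dq, state.ddq, jerk])


def flight_map(x, y, vx, vy, duration: float, g: float):
    """Ballistic flight: closed-form parabolic CoM trajectory. Horizontal
    velocity is conserved; duration 0 (grounded running) is the
    identity. Returns the incoming state at the end of the flight."""
    if duration < 0:
        raise ValueError("flight duration must be >= 0")
    return (x + vx * duration,
            y + vy * duration - 0.5 * g * duration**2,
            vx,
            vy - g * duration)


def collision_map(velocity, CF: float) -> np.ndarray:
    """Touchdown collision: the CoM velocity vector keeps its direction
    and loses the fraction CF of its magnitude, so kinetic energy drops
    by 1 - (1 - CF)^2."""
    if not 0.0 <= CF < 1.0:
        raise ValueError("collision fraction CF must be in [0, 1)")
    return (1.0 - CF) * np.asarray(velocity, dtype=float)


def grf(state: BodyState, params: ModelParams):
    """Ground reaction force components [N] (equal and opposite to the
    leg force on the ground; acts along the leg on the CoM)."""
    _, (ux, uy) = leg_geometry(state.x_b, state.y_b)
    _, _, _, F_m = series_state(state, params)
    return F_m * ux, F_m * uy


def leg_powers(state: BodyState, params: ModelParams):
    """Instantaneous power decomposition [W]: returns (P_leg, P_spring,
    P_actuator, P_damper). P_leg = F . v is the total leg power on the
    CoM; the spring term is the release rate of stored elastic energy
    (-k delta ddelta); the damper power is never positive.
    """
    L_l, delta, ddelta, F_m = series_state(state, params)
    P_leg = F_m * (state.x_b * state.vx_b + state.y_b * state.vy_b) / L_l
    P_spring = -params.k * delta * ddelta
    P_act = F_m * state.dq
    P_damp = -params.c * ddelta**2 * (1.0 if ddelta > 0 else 0.0)
    return P_leg, P_spring, P_act, P_damp


def touchdown_state(angle: float, speed_in, params: ModelParams,
                    CF: float | None = None) -> BodyState:
    """Initial stance state for a leg landing at full length L, tilted
    ``angle`` rad forward of vertical, with incoming CoM velocity
    ``speed_in`` = (vx, vy); the collision map is applied."""
    CF = params.CF if CF is None else CF
    vx, vy = collision_map(speed_in, CF)
    return BodyState(-params.L * math.sin(angle), params.L * math.cos(angle), vx, vy)
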