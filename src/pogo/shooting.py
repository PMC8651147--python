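"""Passive spring-mass (SLIP) gaits by shooting.

The conservative spring-mass runner — point mass on a massless linear
leg spring, no actuator, no losses — admits periodic running gaits
found by shooting on the touchdown condition. These serve two roles:
as an independent oracle for the collocation transcription in the
conservative limit, and as the initial guess for the actuated solves.

All computations here are in normalized units (M = g = L = 1).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root


class ShootingError(RuntimeError):
    """No periodic passive gait found for the requested (k, v, f)."""


def _stance_rhs(t, s, k):
    x, y, vx, vy = s
    L_l = np.hypot(x, y)
    F = k * max(1.0 - L_l, 0.0)
    return [vx, vy, F * x / L_l, F * y / L_l - 1.0]


def integrate_stance(k: float, angle: float, vx0: float, vy0: float,
                     t_max: float = 6.0):
    """Integrate one passive stance from touchdown at full leg length,
    leg tilted ``angle`` rad forward of vertical, until the spring
    returns to its rest length (takeoff). Returns the solve_ivp result
    with dense output, or None if takeoff never occurs."""
    s0 = [-np.sin(angle), np.cos(angle), vx0, vy0]

    def takeoff(t, s, k):
        return (1.0 - np.hypot(s[0], s[1])) - 1e-12

    takeoff.terminal = True
    takeoff.direction = -1
    sol = solve_ivp(_stance_rhs, [0.0, t_max], s0, args=(k,), events=takeoff,
                    rtol=1e-10, atol=1e-12, dense_output=True)
    if not sol.t_events[0].size:
        return None
    return sol


@dataclass
class PassiveGait:
    """A periodic passive spring-mass gait (normalized units)."""

    k: float
    angle: float          # touchdown leg angle from vertical [rad]
    vx_td: float
    vy_td: float
    t_stance: float
    t_flight: float
    stance: object        # dense-output solve_ivp result

    def sample(self, n: int) -> np.ndarray:
        """States (x, y, vx, vy) at n equally spaced stance times,
        shape (n, 4)."""
        tt = np.linspace(0.0, self.t_stance, n)
        return self.stance.sol(tt).T

    @property
    def takeoff_state(self) -> np.ndarray:
        return self.stance.y_events[0][0]


def find_periodic_gait(k: float, v: float, f: float,
                       guess=None) -> PassiveGait:
    """Shoot for a symmetric periodic gait at stiffness k, speed v and
    step frequency f (normalized). Unknowns are the touchdown angle and
    touchdown velocity; residuals enforce horizontal-velocity
    periodicity, the step period and the step length. Energy
    conservation makes the vertical-velocity condition redundant."""
    T = 1.0 / f
    s_len = v * T

    def residuals(z):
        angle, vx0, vy0 = z
        sol = integrate_stance(k, angle, vx0, vy0)
        if sol is None:
            return [10.0, 10.0, 10.0]
        ts = sol.t_events[0][0]
        x1, y1, vx1, vy1 = sol.y_events[0][0]
        y_td = np.cos(angle)
        disc = vy1**2 - 2.0 * (y_td - y1)
        tf = vy1 + np.sqrt(disc) if disc >= 0 else 0.0
        dist = x1 + vx1 * tf + np.sin(angle)
        return [vx1 - vx0, ts + tf - T, dist - s_len]

    tried = []
    if guess is not None:
        tried.append(tuple(guess))
    tried += [(0.25, v, -0.35), (0.15, v, -0.2), (0.35, v, -0.5)]
    for g0 in tried:
        res = root(residuals, g0, method="hybr", tol=1e-12)
        if res.success and abs(res.fun[0]) < 1e-8:
            angle, vx0, vy0 = res.x
            sol = integrate_stance(k, angle, vx0, vy0)
            ts = sol.t_events[0][0]
            return PassiveGait(k, angle, vx0, vy0, ts, T - ts, sol)
    raise ShootingError(
        f"no periodic passive spring-mass gait at k={k:g}, v={v:g}, f={f:g}")


def mechanical_energy(states: np.ndarray, k: float) -> np.ndarray:
    """Total mechanical energy along passive stance states (n, 4):
    kinetic + gravitational + elastic (normalized units)."""
    x, y, vx, vy = states.T
    L_l = np.hypot(x, y)
    delta = np.maximum(1.0 - L_l, 0.0)
    return 0.5 * (vx**2 + vy**2) + y + 0.5 * k * delta**2
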