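"""Metabolic objective and per-step energy bookkeeping.

The cost of one step is E = E_W + E_R: a work cost that charges
positive and negative actuator work at their signed muscle efficiencies,

    E_W = W+ / eta+  +  W- / eta-      (eta+ > 0, eta- < 0),

and a force-rate cost proportional to the time integral of the squared
actuator force rate, E_R = epsilon * int(dF_m/dt)^2 dt. The audit
additionally splits the passive channels: elastic energy stored and
returned by the spring, hysteresis dissipated by the loading-only
damper, and kinetic energy lost in the touchdown collision.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .collocation import StanceSolution


def _trapz(y, t):
    return float(np.trapezoid(y, t))


def work_cost(t, P_m, eta_pos: float, eta_neg: float,
              smooth: float = 0.0) -> float:
    """Metabolic cost of the actuator power trace P_m(t) over one step.

    Positive power is charged at 1/eta_pos, negative power at 1/eta_neg
    (eta_neg < 0 makes both contributions non-negative). ``smooth`` > 0
    uses the optimizer's soft rectification P+ = (P + sqrt(P^2 + s^2))/2
    instead of the exact split.
    """
    if eta_pos <= 0:
        raise ValueError("eta_pos must be positive")
    if eta_neg >= 0:
        raise ValueError("eta_neg must be negative")
    P = np.asarray(P_m, dtype=float)
    if smooth > 0:
        Pp = 0.5 * (P + np.sqrt(P * P + smooth * smooth))
    else:
        Pp = np.maximum(P, 0.0)
    Pn = P - Pp
    return _trapz(Pp / eta_pos + Pn / eta_neg, t)


def force_rate_cost(t, dF_m, epsilon: float) -> float:
    """Force-rate cost: epsilon times the integral of the squared force
    rate over the step."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    dF = np.asarray(dF_m, dtype=float)
    return epsilon * _trapz(dF * dF, t)


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-step energy decomposition [J] (SI).

    Work terms are actuator work (W_pos_act >= 0, W_neg_act <= 0);
    W_spring_pos is the positive (return) work of the spring; E_hyst and
    E_coll are the damper and collision loss magnitudes; E_peak_spring
    the peak elastic energy stored in the cycle. E_W and E_R are the
    metabolic work and force-rate costs; balance_residual is the
    periodic energy-balance defect (see :func:`energy_audit`).
    """

    W_pos_act: float
    W_neg_act: float
    W_spring_pos: float
    E_hyst: float
    E_coll: float
    E_peak_spring: float
    E_W: float
    E_R: float
    step_period: float
    step_length: float
    weight: float
    balance_residual: float
    periodic: bool = True

    @property
    def E_total(self) -> float:
        return self.E_W + self.E_R

    @property
    def cost_rate(self) -> float:
        """Metabolic cost per unit time [W]."""
        return self.E_total / self.step_period

    @property
    def cost_of_transport(self) -> float:
        """Metabolic cost per unit weight and distance [dimensionless]."""
        return self.E_total / (self.weight * self.step_length)

    @property
    def elastic_return_fraction(self) -> float:
        """Share of the positive leg work per step delivered passively
        by the spring."""
        tot = self.W_spring_pos + self.W_pos_act
        return self.W_spring_pos / tot if tot > 0 else 0.0

    def hysteresis_fraction(self, convention: str = "loop") -> float:
        """Damper loss per stretch-shortening cycle.

        ``"loop"`` (default): loss divided by the energy absorbed while
        loading (stored + lost) — the loading/unloading work-loop area
        ratio, as tendon hysteresis is conventionally measured.
        ``"stored"``: loss divided by the peak stored elastic energy.
        """
        if convention == "loop":
            den = self.E_peak_spring + self.E_hyst
        elif convention == "stored":
            den = self.E_peak_spring
        else:
            raise ValueError(f"unknown convention {convention!r}")
        return self.E_hyst / den if den > 0 else 0.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(E_total=self.E_total, cost_rate=self.cost_rate,
                 cost_of_transport=self.cost_of_transport,
                 elastic_return_fraction=self.elastic_return_fraction,
                 hysteresis_loop=self.hysteresis_fraction("loop"),
                 hysteresis_stored=self.hysteresis_fraction("stored"))
        return d


def _refined(t, channels, refine):
    """Resample power channels on a ``refine`` x denser grid (cubic)
    to reduce quadrature error at sign changes and the damper switch."""
    from scipy.interpolate import CubicSpline

    td = np.linspace(t[0], t[-1], refine * (len(t) - 1) + 1)
    return td, [CubicSpline(t, ch)(td) for ch in channels]


def energy_audit(sol: StanceSolution, refine: int = 8) -> EnergyBreakdown:
    """Channel-wise energy decomposition of a converged stance solution,
    with exact (non-smoothed) rectification and damper switching.

    The periodic balance on level ground is W+ + W- = E_hyst + E_coll;
    on a slope the net rise per step M g dh is added to the right-hand
    side. Its residual is reported relative to nothing — callers decide
    what tolerance is meaningful. Non-periodic trajectories are still
    audited but flagged.
    """
    p = sol.params
    t = sol.t
    P_leg, P_spring, P_act, P_damp = sol.powers()
    dF = sol.dF_m
    if refine > 1:
        t, (P_spring, P_act, P_damp, dF) = _refined(
            sol.t, (P_spring, P_act, P_damp, dF), refine)
    W_pos = _trapz(np.maximum(P_act, 0.0), t)
    W_neg = _trapz(np.minimum(P_act, 0.0), t)
    W_spring_pos = _trapz(np.maximum(P_spring, 0.0), t)
    E_hyst = -_trapz(P_damp, t)
    E_peak = 0.5 * p.k * float(np.max(sol.delta, initial=0.0)) ** 2
    vin = sol.touchdown_incoming_velocity
    KE_in = 0.5 * p.M * (vin[0] ** 2 + vin[1] ** 2)
    E_coll = KE_in * (1.0 - (1.0 - p.CF) ** 2)
    E_W = work_cost(t, P_act, p.eta_pos, p.eta_neg)
    if p.variant == "spring_mass":
        E_R = 0.0  # no actuator, hence no force-production cost
    else:
        E_R = force_rate_cost(t, dF, p.epsilon * p.scales.epsilon)
    task = sol.task
    rise = task.s * np.sin(task.incline)
    residual = (W_pos + W_neg) - (E_hyst + E_coll + p.M * p.g * rise)
    return EnergyBreakdown(
        W_pos_act=W_pos, W_neg_act=W_neg, W_spring_pos=W_spring_pos,
        E_hyst=E_hyst, E_coll=E_coll, E_peak_spring=E_peak,
        E_W=E_W, E_R=E_R,
        step_period=task.T, step_length=task.s, weight=p.M * p.g,
        balance_residual=float(residual),
        periodic=bool(sol.converged),
    )


def mechanical_energy_scale(sol: StanceSolution) -> float:
    """The body's mechanical energy at touchdown [J]: kinetic energy of
    the incoming CoM plus gravitational potential above the ground
    contact. Used to express passive dissipation as a fraction of the
    body's mechanical energy."""
    p = sol.params
    vin = sol.touchdown_incoming_velocity
    KE = 0.5 * p.M * (vin[0] ** 2 + vin[1] ** 2)
    PE = p.M * p.g * float(sol.y_b[0])
    return KE + PE
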