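"""Model parameters, gait tasks, solver configuration and unit scaling.

The model is a point-mass runner on a massless leg consisting of an
actuator in series with a linear spring; a damper in parallel with the
spring dissipates energy only while the spring loads, and a fraction of
CoM momentum is lost in the touchdown collision. All quantities are SI
at the API surface; the optimizer works in normalized units with body
mass ``M``, gravitational acceleration ``g`` and maximum leg length
``L`` as base units (so normalized M = g = L = 1).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

VARIANTS = ("actuated_spring_mass", "spring_mass", "actuator_only")

#: Nominal human-like parameter set (the "unified" model): 70 kg runner,
#: 0.9 m legs, spring stiffness 46.7 Mg/L (35.6 kN/m), 3% collision
#: fraction, damping ratio 0.1, signed work efficiencies +32% / -105%,
#: force-rate coefficient 0.5e-3 in normalized units.
NOMINAL = dict(
    M=70.0, g=9.81, L=0.9,
    k_norm=46.7, zeta=0.1, CF=0.03,
    eta_pos=0.32, eta_neg=-1.05, epsilon=5e-4,
    variant="actuated_spring_mass",
)


class ConfigError(ValueError):
    """A configuration value violates a model invariant."""


@dataclass(frozen=True)
class Scales:
    """Base units for nondimensionalization: mass M [kg], gravity g
    [m/s^2], length L [m]. Derived scales follow from these three."""

    M: float = 70.0
    g: float = 9.81
    L: float = 0.9

    def __post_init__(self):
        if self.M <= 0 or self.g <= 0 or self.L <= 0:
            raise ConfigError("base units M, g, L must be positive")

    @property
    def time(self) -> float:
        return math.sqrt(self.L / self.g)

    @property
    def speed(self) -> float:
        return math.sqrt(self.g * self.L)

    @property
    def force(self) -> float:
        return self.M * self.g

    @property
    def stiffness(self) -> float:
        return self.M * self.g / self.L

    @property
    def energy(self) -> float:
        return self.M * self.g * self.L

    @property
    def power(self) -> float:
        return self.energy / self.time

    @property
    def epsilon(self) -> float:
        """Scale of the force-rate coefficient: energy / (force^2 / time),
        i.e. M^-1 g^-1.5 L^1.5."""
        return self.energy / (self.force**2 / self.time)

    def to_norm(self, value, quantity: str):
        return value / getattr(self, quantity)

    def from_norm(self, value, quantity: str):
        return value * getattr(self, quantity)


@dataclass(frozen=True)
class ModelParams:
    """Physical and cost parameters of one model variant (SI units).

    ``k`` is the series-spring stiffness [N/m]; ``zeta`` the damping
    ratio of the parallel damper, zeta = c / (2 sqrt(M k)); ``CF`` the
    fraction of CoM momentum magnitude lost at touchdown; ``eta_pos`` /
    ``eta_neg`` the signed efficiencies of positive/negative actuator
    work (work divided by metabolic cost, so eta_neg < 0); ``epsilon``
    the force-rate cost coefficient expressed in normalized units
    (M^-1 g^-1.5 L^1.5), as it is conventionally reported.
    """

    M: float = NOMINAL["M"]
    g: float = NOMINAL["g"]
    L: float = NOMINAL["L"]
    k: float = NOMINAL["k_norm"] * NOMINAL["M"] * NOMINAL["g"] / NOMINAL["L"]
    zeta: float = NOMINAL["zeta"]
    CF: float = NOMINAL["CF"]
    eta_pos: float = NOMINAL["eta_pos"]
    eta_neg: float = NOMINAL["eta_neg"]
    epsilon: float = NOMINAL["epsilon"]
    variant: str = NOMINAL["variant"]

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigError(f"unknown variant {self.variant!r}")
        for name in ("M", "g", "L"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.k <= 0 and self.variant != "actuator_only":
            raise ConfigError("spring stiffness k must be positive")
        if self.zeta < 0:
            raise ConfigError("damping ratio zeta must be >= 0")
        if not 0.0 <= self.CF < 1.0:
            raise ConfigError("collision fraction CF must be in [0, 1)")
        if self.eta_pos <= 0:
            raise ConfigError("eta_pos must be positive")
        if self.eta_neg >= 0:
            raise ConfigError("eta_neg must be negative (signed efficiency)")
        if self.epsilon < 0:
            raise ConfigError("epsilon must be >= 0")
        if self.variant == "spring_mass" and (self.zeta != 0 or self.CF != 0):
            raise ConfigError("spring_mass variant is conservative: zeta=CF=0")

    @classmethod
    def nominal(cls, **overrides) -> "ModelParams":
        return cls(**overrides) if overrides else cls()

    @property
    def scales(self) -> Scales:
        return Scales(self.M, self.g, self.L)

    @property
    def k_norm(self) -> float:
        return self.k / self.scales.stiffness

    @property
    def c(self) -> float:
        """Damping coefficient [N s/m], c = 2 zeta sqrt(M k)."""
        return 2.0 * self.zeta * math.sqrt(self.M * self.k)

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class GaitTask:
    """The imposed gait: mean speed v [m/s] along the direction of
    travel, step frequency f [Hz] and ground grade (rise over run,
    signed). Step period T = 1/f and step length s = v T follow."""

    v: float
    f: float
    grade: float = 0.0

    def __post_init__(self):
        if self.v <= 0:
            raise ConfigError("speed v must be positive")
        if self.f <= 0:
            raise ConfigError("step frequency f must be positive")

    @property
    def T(self) -> float:
        return 1.0 / self.f

    @property
    def s(self) -> float:
        return self.v * self.T

    @property
    def incline(self) -> float:
        """Ground inclination angle [rad] (atan of the grade)."""
        return math.atan(self.grade)


def preferred_step_frequency(v: float) -> float:
    """Empirical human preferred step frequency [Hz] at speed v [m/s]:
    f = 0.26 v + 2.17."""
    return 0.26 * v + 2.17


@dataclass(frozen=True)
class TranscriptionConfig:
    """Direct-collocation and NLP settings.

    ``n_nodes`` collocation nodes over the stance phase (trapezoidal
    scheme); ``tol`` NLP convergence tolerance on the KKT optimality
    measure; ``smoothing_damper`` / ``smoothing_power`` are the widths of
    the smooth damper switch [normalized speed] and of the smooth power
    rectification [normalized power] used inside the optimizer (post-hoc
    energy audits use exact switching); ``n_starts`` perturbed initial
    guesses per cold solve (best objective retained); ``jerk_bound`` box
    bound on the actuator jerk control [normalized]; ``stiff_emulation``
    normalized stiffness used to emulate the spring-free actuator-only
    variant (its spring stores a vanishing F^2/2k of energy).
    """

    n_nodes: int = 30
    tol: float = 1e-7
    max_iter: int = 900
    smoothing_damper: float = 0.01
    smoothing_power: float = 1e-3
    n_starts: int = 3
    perturbation: float = 1e-3
    seed: int = 0
    jerk_bound: float = 2000.0
    stiff_emulation: float = 500.0
    ts_min_frac: float = 0.05
    ts_max_frac: float = 1.0
    ftol_rel: float = 1e-7
    stall_iters: int = 40

    def __post_init__(self):
        if self.n_nodes < 10:
            raise ConfigError("n_nodes must be >= 10")
        if self.tol <= 0:
            raise ConfigError("tol must be positive")
        if self.n_starts < 1:
            raise ConfigError("n_starts must be >= 1")
        if not 0 < self.ts_min_frac < self.ts_max_frac <= 1.0:
            raise ConfigError("need 0 < ts_min_frac < ts_max_frac <= 1")


_PARAM_KEYS = {f.name for f in fields(ModelParams)}
_TASK_KEYS = {f.name for f in fields(GaitTask)}
_CONFIG_KEYS = {f.name for f in fields(TranscriptionConfig)}
_ALIASES = {"cf": "CF", "slope": "grade", "eps": "epsilon"}


def validate_config(raw: dict | None):
    """Build (ModelParams, GaitTask, TranscriptionConfig) from one flat
    key-value namespace. Unknown keys are rejected; omitted keys take
    the nominal defaults (task defaults: v = 3 m/s at the preferred step
    frequency, level ground). Each violated invariant is reported with
    the offending key."""
    raw = dict(raw or {})
    p, t, c = {}, {}, {}
    for key, val in raw.items():
        name = _ALIASES.get(key, key)
        if name in _PARAM_KEYS:
            p[name] = val
        elif name in _TASK_KEYS:
            t[name] = val
        elif name in _CONFIG_KEYS:
            c[name] = val
        else:
            raise ConfigError(f"unknown configuration key {key!r}")
    t.setdefault("v", 3.0)
    t.setdefault("f", preferred_step_frequency(t["v"]))
    try:
        return ModelParams(**p), GaitTask(**t), TranscriptionConfig(**c)
    except TypeError as exc:  # non-numeric values and similar
        raise ConfigError(str(exc)) from None
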