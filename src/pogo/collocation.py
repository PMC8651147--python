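"""Direct collocation of one periodic stance phase.

One running step is transcribed as a trapezoidal collocation NLP over
the stance phase, with the ballistic flight phase in closed form and
the touchdown collision as a boundary map. Decision variables are the
node states (CoM position/velocity relative to the stance foot and the
actuator displacement chain q, dq, ddq), the actuator jerk control at
each node, and the free stance duration. Constraints: trapezoidal
dynamics defects, periodicity of the CoM state across stance + flight
(displaced one step length along the ground, with the collision map
applied at touchdown), an unloaded spring at touchdown and takeoff
(the massless series chain cannot carry force in the air), leg length
not exceeding L, and non-negative axial leg force. The objective is
the metabolic cost per step: work cost plus force-rate cost.

The NLP is solved with scipy's interior-point solver (trust-constr)
using exact first and second derivatives assembled from the generated
kernels in ``pogo._kernels``. Everything inside the NLP is in
normalized units (M = g = L = 1).
"""
from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import NonlinearConstraint, minimize
from scipy.sparse import csr_matrix

from . import _kernels
from .params import GaitTask, ModelParams, TranscriptionConfig
from .shooting import ShootingError, find_periodic_gait

_STATE = 7   # x, y, vx, vy, q, dq, ddq
_VARS = 8    # + jerk control


class SolveError(RuntimeError):
    """The stance optimization failed to converge; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


def _stack(vals, shape):
    return np.stack([np.broadcast_to(np.asarray(v, float), shape) for v in vals])


def _sym(upper, shape):
    """Expand a row-major upper triangle (36 entries) into (..., 8, 8)."""
    H = np.zeros((8, 8) + shape)
    idx = 0
    for i in range(8):
        for j in range(i, 8):
            H[i, j] = H[j, i] = np.broadcast_to(np.asarray(upper[idx], float), shape)
            idx += 1
    return np.moveaxis(H, (0, 1), (-2, -1))


class _StanceNLP:
    """Normalized trapezoidal transcription for one stance phase."""

    def __init__(self, k, zeta, CF, eta_pos, eta_neg, eps, v, f, grade,
                 config: TranscriptionConfig):
        self.k, self.zeta, self.CF = k, zeta, CF
        self.c = 2.0 * zeta * np.sqrt(k)
        self.T = 1.0 / f
        self.s_len = v * self.T
        den = np.sqrt(1.0 + grade * grade)
        self.sx, self.sy = self.s_len / den, self.s_len * grade / den
        self.cfg = config
        self.N = config.n_nodes - 1          # intervals
        self.nz = _VARS * (self.N + 1) + 1
        self.tw = np.ones(self.N + 1)
        self.tw[0] = self.tw[-1] = 0.5
        self.pargs = (k, self.c, eps, eta_pos, eta_neg,
                      config.smoothing_damper, config.smoothing_power)

    # -- variable layout: per node [x, y, vx, vy, q, dq, ddq, u]; then ts
    def split(self, z):
        S = z[:_VARS * (self.N + 1)].reshape(self.N + 1, _VARS)
        return S, z[-1]

    def _nodes(self, z):
        S, ts = self.split(z)
        cols = [S[:, i] for i in range(_VARS)]
        out = _kernels.dyn(*cols, *self.pargs)
        f = np.stack(out[:7], axis=1)
        return f, out[7], out[8], out[9], out[10], out[11], out[12], S, ts

    def constraints(self, z):
        N = self.N
        f, F, dF, delta, dd, Ll, ell, S, ts = self._nodes(z)
        h = ts / N
        Sst = S[:, :_STATE]
        defects = Sst[1:] - Sst[:-1] - 0.5 * h * (f[1:] + f[:-1])
        tf = self.T - ts
        b = np.array([
            S[-1, 0] + S[-1, 2] * tf - S[0, 0] - self.sx,
            S[-1, 1] + S[-1, 3] * tf - 0.5 * tf**2 - S[0, 1] - self.sy,
            S[0, 2] - (1.0 - self.CF) * S[-1, 2],
            S[0, 3] - (1.0 - self.CF) * (S[-1, 3] - tf),
            delta[0], delta[-1],
        ])
        # F >= 0 only at interior nodes: the unloaded-spring boundary
        # equalities pin the endpoint forces and duplicating them would
        # make the constraint Jacobian rank-deficient.
        return np.concatenate([defects.ravel(), b, F[1:-1], Ll])

    def con_bounds(self):
        N = self.N
        n_eq = _STATE * N + 6
        lb = np.concatenate([np.zeros(n_eq), np.zeros(N - 1),
                             np.full(N + 1, -np.inf)])
        ub = np.concatenate([np.zeros(n_eq), np.full(N - 1, np.inf),
                             np.ones(N + 1)])
        return lb, ub

    def con_jac(self, z):
        N, nz = self.N, self.nz
        f, F, dF, delta, dd, Ll, ell, S, ts = self._nodes(z)
        cols = [S[:, i] for i in range(_VARS)]
        sh = (N + 1,)
        Jf = _stack(_kernels.jac_dyn(*cols, *self.pargs), sh) \
            .reshape(7, 8, N + 1).transpose(2, 0, 1)
        gF = _stack(_kernels.grad_F(*cols, *self.pargs), sh).T
        gL = _stack(_kernels.grad_Ll(*cols, *self.pargs), sh).T
        h = ts / N
        ncon = _STATE * N + 6 + (N - 1) + (N + 1)
        J = np.zeros((ncon, nz))
        I78 = np.zeros((7, 8))
        I78[:, :7] = np.eye(7)
        for i in range(N):
            r = slice(7 * i, 7 * i + 7)
            J[r, 8 * i:8 * i + 8] = -I78 - 0.5 * h * Jf[i]
            J[r, 8 * (i + 1):8 * (i + 1) + 8] = I78 - 0.5 * h * Jf[i + 1]
            J[r, -1] = -(f[i] + f[i + 1]) / (2 * N)
        r = _STATE * N
        tf = self.T - ts
        CF = self.CF
        J[r, 0] = -1; J[r, 8 * N] = 1; J[r, 8 * N + 2] = tf; J[r, -1] = -S[-1, 2]
        J[r + 1, 1] = -1; J[r + 1, 8 * N + 1] = 1; J[r + 1, 8 * N + 3] = tf
        J[r + 1, -1] = -S[-1, 3] + tf
        J[r + 2, 2] = 1; J[r + 2, 8 * N + 2] = -(1 - CF)
        J[r + 3, 3] = 1; J[r + 3, 8 * N + 3] = -(1 - CF); J[r + 3, -1] = -(1 - CF)
        J[r + 4, 0:8] = -gL[0]; J[r + 4, 4] += 1.0
        J[r + 5, 8 * N:8 * N + 8] = -gL[-1]; J[r + 5, 8 * N + 4] += 1.0
        r += 6
        for i in range(1, N):
            J[r + i - 1, 8 * i:8 * i + 8] = gF[i]
        r += N - 1
        for i in range(N + 1):
            J[r + i, 8 * i:8 * i + 8] = gL[i]
        return csr_matrix(J)

    def con_hess(self, z, v):
        N, nz = self.N, self.nz
        S, ts = self.split(z)
        cols = [S[:, i] for i in range(_VARS)]
        sh = (N + 1,)
        vd = v[:_STATE * N].reshape(N, 7)
        w = np.zeros((N + 1, 7))
        w[:-1] += vd
        w[1:] += vd
        vb = v[_STATE * N:_STATE * N + 6]
        vF = np.zeros(N + 1)
        vF[1:N] = v[_STATE * N + 6:_STATE * N + 6 + N - 1]
        vL = v[_STATE * N + 5 + N:]
        H = np.zeros((nz, nz))
        wcols = [w[:, i] for i in range(7)]
        Hphi = _sym(_kernels.hess_phi(*cols, *self.pargs, *wcols), sh)
        gphi = _stack(_kernels.grad_phi(*cols, *self.pargs, *wcols), sh).T
        HF = _sym(_kernels.hess_F(*cols, *self.pargs), sh)
        HL = _sym(_kernels.hess_Ll(*cols, *self.pargs), sh)
        for i in range(N + 1):
            s = slice(8 * i, 8 * i + 8)
            blk = -(ts / (2 * N)) * Hphi[i] + vF[i] * HF[i] + vL[i] * HL[i]
            if i == 0:
                blk -= vb[4] * HL[i]
            if i == N:
                blk -= vb[5] * HL[i]
            H[s, s] += blk
            cross = -(1.0 / (2 * N)) * gphi[i]
            H[s, -1] += cross
            H[-1, s] += cross
        H[8 * N + 2, -1] -= vb[0]; H[-1, 8 * N + 2] -= vb[0]
        H[8 * N + 3, -1] -= vb[1]; H[-1, 8 * N + 3] -= vb[1]
        H[-1, -1] -= vb[1]
        return H

    def objective(self, z):
        f, F, dF, delta, dd, Ll, ell, S, ts = self._nodes(z)
        return (ts / self.N) * float((self.tw * ell).sum())

    def obj_grad(self, z):
        N = self.N
        f, F, dF, delta, dd, Ll, ell, S, ts = self._nodes(z)
        cols = [S[:, i] for i in range(_VARS)]
        gell = _stack(_kernels.grad_ell(*cols, *self.pargs), (N + 1,)).T
        g = np.zeros(self.nz)
        g[:8 * (N + 1)] = ((ts / N) * self.tw[:, None] * gell).ravel()
        g[-1] = (self.tw * ell).sum() / N
        return g

    def obj_hess(self, z):
        N = self.N
        f, F, dF, delta, dd, Ll, ell, S, ts = self._nodes(z)
        cols = [S[:, i] for i in range(_VARS)]
        gell = _stack(_kernels.grad_ell(*cols, *self.pargs), (N + 1,)).T
        Hell = _sym(_kernels.hess_ell(*cols, *self.pargs), (N + 1,))
        H = np.zeros((self.nz, self.nz))
        for i in range(N + 1):
            s = slice(8 * i, 8 * i + 8)
            H[s, s] = (ts / N) * self.tw[i] * Hell[i]
            cr = (self.tw[i] / N) * gell[i]
            H[s, -1] += cr
            H[-1, s] += cr
        return H

    def var_bounds(self):
        N = self.N
        jb = self.cfg.jerk_bound
        lb = np.tile([-2.0, 0.15, 0.0, -3.0, -0.6, -3.0, -50.0, -jb], N + 1)
        ub = np.tile([2.0, 1.3, 3.5, 3.0, 0.6, 3.0, 50.0, jb], N + 1)
        lb = np.append(lb, self.cfg.ts_min_frac * self.T)
        ub = np.append(ub, self.cfg.ts_max_frac * self.T)
        return lb, ub

    def solve(self, z0, maxiter=None):
        cfg = self.cfg
        maxiter = maxiter or cfg.max_iter
        lb, ub = self.con_bounds()
        con = NonlinearConstraint(self.constraints, lb, ub,
                                  jac=self.con_jac, hess=self.con_hess)
        vlb, vub = self.var_bounds()
        z0 = np.clip(np.asarray(z0, float), vlb, vub)
        hist = []

        def cb(xk, state):
            # stop once feasible, past the barrier tail and stalled
            hist.append(state.fun)
            if (len(hist) > cfg.stall_iters and state.constr_violation < 1e-8
                    and state.barrier_parameter < 1e-8):
                span = max(hist[-cfg.stall_iters:]) - min(hist[-cfg.stall_iters:])
                if span < cfg.ftol_rel * max(1.0, abs(state.fun)):
                    return True
            return False

        return minimize(self.objective, z0, method="trust-constr",
                        jac=self.obj_grad, hess=self.obj_hess,
                        constraints=[con], bounds=list(zip(vlb, vub)),
                        callback=cb,
                        options=dict(maxiter=maxiter, gtol=cfg.tol,
                                     xtol=1e-12, verbose=0))

    # -- initial guesses ------------------------------------------------
    def guess_from_passive(self):
        """Passive spring-mass gait (level, stiffness capped for
        shootability), resampled on the node grid, zero actuator."""
        k_g = min(self.k, 300.0)
        gait = find_periodic_gait(k_g, self.s_len / self.T, 1.0 / self.T)
        Z = np.zeros((self.N + 1, _VARS))
        Z[:, :4] = gait.sample(self.N + 1)
        return np.append(Z.ravel(), gait.t_stance)

    def guess_analytic(self):
        """Kinematic fallback guess: stance sweeps 60% of the step
        length at constant horizontal speed under a near-full-length
        leg; used when passive shooting fails (extreme parameters or
        steep grades)."""
        ts = 0.5 * self.T
        v = self.s_len / self.T
        xs = np.linspace(-0.3 * self.s_len, 0.3 * self.s_len, self.N + 1)
        ys = np.sqrt(np.maximum(1.0 - xs**2, 0.5)) - 0.02
        ys = ys + xs * self.sy / max(self.sx, 1e-9)
        Z = np.zeros((self.N + 1, _VARS))
        Z[:, 0] = xs
        Z[:, 1] = ys
        Z[:, 2] = v
        Z[:, 3] = np.linspace(-0.2, 0.2, self.N + 1)
        return np.append(Z.ravel(), ts)

    def initial_guesses(self):
        try:
            yield self.guess_from_passive()
        except ShootingError:
            pass
        yield self.guess_analytic()


@dataclass
class StanceSolution:
    """A converged periodic stance solution in SI units.

    Node arrays span the stance phase; the flight phase is ballistic
    with duration ``t_flight``. ``E`` is the metabolic objective per
    step [J] (work cost + force-rate cost, from the optimizer's smooth
    rectification; the exact post-hoc decomposition lives in
    ``pogo.energetics.energy_audit``).
    """

    params: ModelParams
    task: GaitTask
    config: TranscriptionConfig
    t: np.ndarray           # node times [s], 0 .. t_stance
    x_b: np.ndarray
    y_b: np.ndarray
    vx_b: np.ndarray
    vy_b: np.ndarray
    q: np.ndarray           # actuator displacement from nominal [m]
    dq: np.ndarray
    ddq: np.ndarray
    jerk: np.ndarray
    F_m: np.ndarray         # axial leg/actuator force [N] (exact switch)
    dF_m: np.ndarray        # force rate [N/s]
    delta: np.ndarray       # spring compression [m]
    ddelta: np.ndarray
    t_stance: float
    t_flight: float
    E: float                # objective per step [J]
    converged: bool
    diagnostics: dict = field(default_factory=dict)
    multipliers: list = field(default_factory=list)
    z_norm: np.ndarray | None = None   # normalized NLP vector (warm starts)

    @property
    def touchdown_angle(self) -> float:
        """Leg angle from vertical at touchdown [rad] (forward lean
        positive, i.e. foot ahead of the CoM)."""
        return float(np.arctan2(-self.x_b[0], self.y_b[0]))

    @property
    def L_l(self) -> np.ndarray:
        return np.hypot(self.x_b, self.y_b)

    @property
    def grf(self):
        L_l = self.L_l
        return self.F_m * self.x_b / L_l, self.F_m * self.y_b / L_l

    @property
    def takeoff_velocity(self):
        return float(self.vx_b[-1]), float(self.vy_b[-1])

    @property
    def touchdown_incoming_velocity(self):
        """CoM velocity at the end of flight, before the collision."""
        return (float(self.vx_b[-1]),
                float(self.vy_b[-1]) - self.params.g * self.t_flight)

    def powers(self):
        """(P_leg, P_spring, P_actuator, P_damper) node arrays [W],
        with exact damper switching."""
        p = self.params
        L_l = self.L_l
        dL_l = (self.x_b * self.vx_b + self.y_b * self.vy_b) / L_l
        P_leg = self.F_m * dL_l
        P_spring = -p.k * self.delta * self.ddelta
        P_act = self.F_m * self.dq
        P_damp = -p.c * self.ddelta**2 * (self.ddelta > 0)
        return P_leg, P_spring, P_act, P_damp

    def to_frame(self):
        """Trajectory as a pandas DataFrame with one row per node.

        The actuator/spring length split uses the reporting convention
        L_m = L/2 + q and L_t = L/2 - delta (only q and delta are
        dynamically meaningful; the rest lengths are arbitrary)."""
        import pandas as pd

        P_leg, P_spring, P_act, P_damp = self.powers()
        gx, gy = self.grf
        return pd.DataFrame({
            "time": self.t, "x_b": self.x_b, "y_b": self.y_b,
            "vx_b": self.vx_b, "vy_b": self.vy_b, "L_l": self.L_l,
            "L_m": self.params.L / 2 + self.q,
            "L_t": self.params.L / 2 - self.delta,
            "F_m": self.F_m, "dF_m": self.dF_m,
            "GRF_x": gx, "GRF_y": gy,
            "P_leg": P_leg, "P_spring": P_spring,
            "P_actuator": P_act, "P_damper": P_damp,
        })

    def summary(self) -> dict:
        return dict(
            v=self.task.v, f=self.task.f, grade=self.task.grade,
            E_per_step=self.E, t_stance=self.t_stance,
            t_flight=self.t_flight,
            touchdown_angle=self.touchdown_angle,
            peak_grf_bw=float(np.max(self.grf[1]) / (self.params.M * self.params.g)),
            converged=self.converged, **self.diagnostics,
        )


def _effective_norm_params(params: ModelParams, config: TranscriptionConfig):
    """Normalized (k, zeta, CF, eta+, eta-, eps) for the NLP, resolving
    the variant: the actuator-only model is the stiff-spring limit (the
    spring stores a vanishing F^2/2k), and the passive spring-mass model
    is conservative with a frozen actuator."""
    k = params.k_norm
    zeta, CF = params.zeta, params.CF
    if params.variant == "actuator_only":
        k, zeta = config.stiff_emulation, 0.0
    return k, zeta, CF, params.eta_pos, params.eta_neg, params.epsilon


def _build_nlp(params: ModelParams, task: GaitTask, config: TranscriptionConfig):
    sc = params.scales
    k, zeta, CF, ep, en, eps = _effective_norm_params(params, config)
    return _StanceNLP(k, zeta, CF, ep, en, eps,
                      v=task.v / sc.speed, f=task.f * sc.time,
                      grade=task.grade, config=config)


def _package(nlp: _StanceNLP, res, params: ModelParams, task: GaitTask,
             config: TranscriptionConfig) -> StanceSolution:
    sc = params.scales
    S, ts = nlp.split(res.x)
    tt = np.linspace(0.0, ts, nlp.N + 1) * sc.time
    x, y, vx, vy, q, dq, ddq, u = (S[:, i] for i in range(_VARS))
    # exact-switch force and smooth-model force rate at the nodes
    out = _kernels.dyn(x, y, vx, vy, q, dq, ddq, u, *nlp.pargs)
    dF = np.asarray(out[8], float)
    delta, ddelta = np.asarray(out[9], float), np.asarray(out[10], float)
    F_exact = nlp.k * delta + nlp.c * ddelta * (ddelta > 0)
    diag = dict(status=int(res.status), nit=int(res.nit),
                constr_violation=float(res.constr_violation),
                optimality=float(res.optimality),
                execution_time=float(res.execution_time))
    return StanceSolution(
        params=params, task=task, config=config,
        t=tt,
        x_b=x * sc.L, y_b=y * sc.L,
        vx_b=vx * sc.speed, vy_b=vy * sc.speed,
        q=q * sc.L, dq=dq * sc.speed, ddq=ddq * sc.g,
        jerk=u * sc.g / sc.time,
        F_m=F_exact * sc.force, dF_m=dF * sc.force / sc.time,
        delta=delta * sc.L, ddelta=ddelta * sc.speed,
        t_stance=float(ts * sc.time), t_flight=float((nlp.T - ts) * sc.time),
        E=float(res.fun * sc.energy),
        converged=bool(res.constr_violation < 1e-6),
        diagnostics=diag,
        multipliers=[np.asarray(vi) for vi in res.v],
        z_norm=res.x.copy(),
    )


def _passive_solution(params: ModelParams, task: GaitTask,
                      config: TranscriptionConfig) -> StanceSolution:
    """Spring-mass variant: periodic gait by shooting, packaged in the
    same container (zero actuator, zero metabolic cost)."""
    sc = params.scales
    gait = find_periodic_gait(params.k_norm, task.v / sc.speed,
                              task.f * sc.time)
    n = config.n_nodes
    st = gait.sample(n)
    ts = gait.t_stance
    x, y, vx, vy = st.T
    L_l = np.hypot(x, y)
    delta = np.maximum(1.0 - L_l, 0.0)
    dd = -(x * vx + y * vy) / L_l
    F = params.k_norm * delta
    dF = params.k_norm * dd
    zeros = np.zeros(n)
    diag = dict(status=0, nit=0, constr_violation=0.0, optimality=0.0,
                execution_time=0.0)
    return StanceSolution(
        params=params, task=task, config=config,
        t=np.linspace(0, ts, n) * sc.time,
        x_b=x * sc.L, y_b=y * sc.L,
        vx_b=vx * sc.speed, vy_b=vy * sc.speed,
        q=zeros, dq=zeros, ddq=zeros, jerk=zeros,
        F_m=F * sc.force, dF_m=dF * sc.force / sc.time,
        delta=delta * sc.L, ddelta=dd * sc.speed,
        t_stance=float(ts * sc.time), t_flight=float(gait.t_flight * sc.time),
        E=0.0, converged=True, diagnostics=diag,
    )


def solve_stance(params: ModelParams, task: GaitTask,
                 config: TranscriptionConfig | None = None,
                 warm_start: StanceSolution | np.ndarray | None = None,
                 ) -> StanceSolution:
    """Solve one periodic stance phase for minimum metabolic cost.

    Cold solves start from the passive spring-mass gait (plus a
    kinematic fallback) and ``config.n_starts`` seeded perturbations,
    keeping the best feasible objective. A ``warm_start`` (a previous
    solution with the same node count, or a raw normalized vector) is
    tried first and skips the multistart when it converges.

    Raises :class:`SolveError` with per-start diagnostics if no start
    converges; never returns a silent partial answer.
    """
    if config is None:
        config = TranscriptionConfig()
    if params.variant == "spring_mass":
        return _passive_solution(params, task, config)
    nlp = _build_nlp(params, task, config)
    t0 = time.perf_counter()

    attempts = []
    results = []

    def attempt(z0, label):
        try:
            res = nlp.solve(z0)
        except Exception as exc:  # pragma: no cover - solver internals
            attempts.append((label, f"exception: {exc}"))
            return None
        feas = res.constr_violation < 1e-6
        attempts.append((label, f"status={res.status} E={res.fun:.6g} "
                                f"viol={res.constr_violation:.2g}"))
        if feas:
            results.append(res)
        return res if feas else None

    if warm_start is not None:
        if isinstance(warm_start, StanceSolution):
            zw = warm_start.z_norm
            if zw is not None and warm_start.config.n_nodes != config.n_nodes:
                zw = resample_warm_start(warm_start, config.n_nodes)
        else:
            zw = warm_start
        if zw is not None and zw.size == nlp.nz:
            if attempt(np.asarray(zw, float), "warm") is not None:
                return _package(nlp, results[0], params, task, config)

    rng = np.random.default_rng(config.seed)
    base = list(nlp.initial_guesses())
    vlb, vub = nlp.var_bounds()
    for i in range(config.n_starts):
        g = base[min(i, len(base) - 1)].copy()
        if i >= len(base):
            g = base[0] + config.perturbation * rng.standard_normal(base[0].size)
            g = np.clip(g, vlb, vub)
        attempt(g, f"start{i}")
        # stop early if we already have two feasible answers that agree
        if len(results) >= 2:
            Es = sorted(r.fun for r in results)
            if (Es[1] - Es[0]) < 1e-3 * max(abs(Es[0]), 1e-9):
                break
    if not results:
        raise SolveError(
            f"stance optimization failed for v={task.v:g} m/s, f={task.f:g} Hz, "
            f"grade={task.grade:g}", dict(attempts=attempts,
                                          time=time.perf_counter() - t0))
    best = min(results, key=lambda r: r.fun)
    return _package(nlp, best, params, task, config)


def resample_warm_start(sol: StanceSolution, n_nodes: int) -> np.ndarray:
    """Resample a solution's normalized NLP vector onto a different
    node count (cubic interpolation in scaled stance time), for warm
    starting mesh-refined solves."""
    from scipy.interpolate import CubicSpline

    z = sol.z_norm
    n_old = sol.config.n_nodes
    S = z[:_VARS * n_old].reshape(n_old, _VARS)
    grid_old = np.linspace(0.0, 1.0, n_old)
    grid_new = np.linspace(0.0, 1.0, n_nodes)
    S_new = CubicSpline(grid_old, S, axis=0)(grid_new)
    return np.append(S_new.ravel(), z[-1])


def continuation_sweep(params_tasks, config: TranscriptionConfig | None = None,
                       warm_start: StanceSolution | None = None,
                       max_bisect: int = 4):
    """Solve an ordered list of (ModelParams, GaitTask) points, warm
    starting each from its converged neighbor. On a failure the gap to
    the last good point is bisected (synthetic intermediate tasks) to
    rebuild a usable warm start; points that still fail are returned as
    SolveError entries alongside the successes.

    Returns a list aligned with the input: StanceSolution or SolveError.
    """
    if config is None:
        config = TranscriptionConfig()
    out = []
    prev = warm_start
    pts = list(params_tasks)
    for params, task in pts:
        try:
            sol = solve_stance(params, task, config, warm_start=prev)
            out.append(sol)
            prev = sol
            continue
        except SolveError as err:
            if prev is None:
                out.append(err)
                continue
            # bisection refinement between the last good and failing point
            sol = None
            lo_p, lo_t = prev.params, prev.task
            for _ in range(max_bisect):
                mid_t = GaitTask(v=0.5 * (lo_t.v + task.v),
                                 f=0.5 * (lo_t.f + task.f),
                                 grade=0.5 * (lo_t.grade + task.grade))
                mid_p = _interp_params(lo_p, params)
                try:
                    mid = solve_stance(mid_p, mid_t, config, warm_start=prev)
                except SolveError:
                    break
                try:
                    sol = solve_stance(params, task, config, warm_start=mid)
                    break
                except SolveError:
                    lo_p, lo_t, prev = mid_p, mid_t, mid
            if sol is None:
                out.append(err)
            else:
                out.append(sol)
                prev = sol
    return out


def _interp_params(a: ModelParams, b: ModelParams) -> ModelParams:
    if a == b:
        return a
    mid = {}
    for name in ("k", "zeta", "CF", "eta_pos", "eta_neg", "epsilon"):
        mid[name] = 0.5 * (getattr(a, name) + getattr(b, name))
    return b.replace(**mid)
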