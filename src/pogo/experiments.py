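"""Scripted studies over speeds, stiffnesses, slopes and cost weights.

Each experiment drives :func:`pogo.collocation.solve_stance` over a
parameter grid with warm-started continuation, audits every converged
solution, and collects results in a :class:`SweepResult` table. Derived
gait metrics (contact time, duty factor, peak force) feed the classic
cost-rate/contact-time correlations of running energetics.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .collocation import (SolveError, StanceSolution, continuation_sweep,
                          solve_stance)
from .energetics import EnergyBreakdown, energy_audit
from .params import (GaitTask, ModelParams, TranscriptionConfig,
                     preferred_step_frequency)


def _hash(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class GaitMetrics:
    """Per-gait observables: contact (stance) and flight times [s], duty
    factor, peak vertical GRF [body weights], touchdown leg angle [rad],
    and the passive (spring) share of positive leg work."""

    contact_time: float
    flight_time: float
    duty_factor: float
    peak_vertical_grf_bw: float
    touchdown_angle: float
    elastic_return_fraction: float

    @classmethod
    def from_solution(cls, sol: StanceSolution,
                      audit: EnergyBreakdown) -> "GaitMetrics":
        _, gy = sol.grf
        bw = sol.params.M * sol.params.g
        return cls(
            contact_time=sol.t_stance,
            flight_time=sol.t_flight,
            duty_factor=sol.t_stance / sol.task.T,
            peak_vertical_grf_bw=float(np.max(gy) / bw),
            touchdown_angle=sol.touchdown_angle,
            elastic_return_fraction=audit.elastic_return_fraction,
        )


class SweepResult:
    """Table of solved grid points with per-point energy breakdown and
    gait metrics. Every row traces to a converged solution (or carries
    converged=False); provenance hashes identify parameters and solver
    configuration."""

    def __init__(self, rows, solutions, params_hash, config_hash):
        self.table = pd.DataFrame(rows)
        self.solutions = solutions
        self.params_hash = params_hash
        self.config_hash = config_hash

    @property
    def converged(self) -> pd.DataFrame:
        return self.table[self.table.converged]

    def to_csv(self, path):
        self.table.to_csv(path, index=False)


def _row(sol_or_err, point: dict):
    if isinstance(sol_or_err, SolveError):
        return dict(point, converged=False), None
    sol = sol_or_err
    audit = energy_audit(sol)
    m = GaitMetrics.from_solution(sol, audit)
    row = dict(point, converged=sol.converged, **audit.to_dict())
    for key, val in asdict(m).items():
        row.setdefault(key, val)
    return row, sol


def _sweep(points, params_list, tasks, config, warm=None):
    sols = continuation_sweep(list(zip(params_list, tasks)), config,
                              warm_start=warm)
    rows, kept = [], []
    for point, sol in zip(points, sols):
        row, s = _row(sol, point)
        rows.append(row)
        kept.append(s)
    return rows, kept


def speed_sweep(params: ModelParams, speeds=None,
                frequency_law=preferred_step_frequency,
                config: TranscriptionConfig | None = None) -> SweepResult:
    """Cost vs. running speed at the preferred-step-frequency law
    (f = 0.26 v + 2.17 by default), warm-started in increasing speed."""
    if speeds is None:
        speeds = np.linspace(2.0, 4.0, 9)
    speeds = np.asarray(speeds, dtype=float)
    tasks = [GaitTask(v=float(v), f=float(frequency_law(v))) for v in speeds]
    points = [dict(v=t.v, f=t.f, grade=0.0) for t in tasks]
    rows, sols = _sweep(points, [params] * len(tasks), tasks, config)
    return SweepResult(rows, sols, _hash(asdict(params)),
                       _hash(asdict(config or TranscriptionConfig())))


def kram_taylor_regression(sweep: SweepResult):
    """The two classic correlations across a speed sweep: metabolic rate
    against inverse contact time, and inverse contact time against
    speed. Returns (R^2 cost-rate vs 1/t_c, R^2 1/t_c vs v) from OLS
    fits with intercept."""
    df = sweep.converged
    if len(df) < 3:
        raise ValueError("need at least 3 converged speed points")
    import statsmodels.api as sm

    inv_tc = 1.0 / df.contact_time.to_numpy()
    fit1 = sm.OLS(df.cost_rate.to_numpy(), sm.add_constant(inv_tc)).fit()
    fit2 = sm.OLS(inv_tc, sm.add_constant(df.v.to_numpy())).fit()
    return float(fit1.rsquared), float(fit2.rsquared)


def slope_study(params: ModelParams, grades=None, v: float = 3.0,
                f: float = 2.94,
                config: TranscriptionConfig | None = None):
    """Cost of transport vs. ground grade at fixed speed and step
    frequency, solved outward from level in both directions (each
    direction warm-starts from the level solution).

    Returns (SweepResult, summary dict) where the summary reports the
    grade minimizing cost of transport (parabolic refinement around the
    grid minimum) and the apparent uphill/downhill asymptote slopes
    d(CoT)/d(grade) at the extreme grades, to compare against the
    reciprocal work efficiencies 1/eta+ and 1/eta-."""
    if grades is None:
        grades = np.round(np.arange(-0.20, 0.1001, 0.02), 4)
    grades = np.asarray(grades, dtype=float)
    level = solve_stance(params, GaitTask(v=v, f=f, grade=0.0), config)
    rows_all = {}
    sols_all = {}
    for branch in (np.sort(grades[grades <= 0])[::-1], np.sort(grades[grades > 0])):
        if branch.size == 0:
            continue
        tasks = [GaitTask(v=v, f=f, grade=float(g)) for g in branch]
        points = [dict(v=v, f=f, grade=t.grade) for t in tasks]
        rows, sols = _sweep(points, [params] * len(tasks), tasks, config,
                            warm=level)
        for g, r, s in zip(branch, rows, sols):
            rows_all[float(g)] = r
            sols_all[float(g)] = s
    order = sorted(rows_all)
    sweep = SweepResult([rows_all[g] for g in order],
                        [sols_all[g] for g in order],
                        _hash(asdict(params)),
                        _hash(asdict(config or TranscriptionConfig())))
    df = sweep.converged
    g_arr = df.grade.to_numpy()
    cot = df.cost_of_transport.to_numpy()
    imin = int(np.argmin(cot))
    g_min = float(g_arr[imin])
    if 0 < imin < len(g_arr) - 1:
        g_min = _parabolic_min(g_arr[imin - 1:imin + 2], cot[imin - 1:imin + 2])
    summary = dict(
        grade_at_min_cot=g_min,
        cot_min=float(cot[imin]),
        uphill_asymptote_slope=_edge_slope(g_arr, cot, end="up"),
        downhill_asymptote_slope=_edge_slope(g_arr, cot, end="down"),
        inv_eta_pos=1.0 / params.eta_pos,
        inv_eta_neg=1.0 / params.eta_neg,
    )
    return sweep, summary


def _parabolic_min(x, y):
    x1, x2, x3 = x
    y1, y2, y3 = y
    denom = (x1 - x2) * (x1 - x3) * (x2 - x3)
    A = (x3 * (y2 - y1) + x2 * (y1 - y3) + x1 * (y3 - y2)) / denom
    B = (x3**2 * (y1 - y2) + x2**2 * (y3 - y1) + x1**2 * (y2 - y3)) / denom
    return float(-B / (2 * A)) if A > 0 else float(x2)


def _edge_slope(g, cot, end):
    if end == "up":
        i, j = -2, -1
    else:
        i, j = 1, 0
    return float((cot[j] - cot[i]) / (g[j] - g[i]))


def sensitivity_traces(params: ModelParams, name: str, values,
                       grades=None, v: float = 3.0, f: float = 2.94,
                       config: TranscriptionConfig | None = None):
    """Families of cost-vs-grade curves while varying one parameter of
    {k, epsilon, zeta, CF}. Returns {value: (SweepResult, summary)}."""
    if name not in ("k", "epsilon", "zeta", "CF"):
        raise ValueError("vary one of k, epsilon, zeta, CF")
    out = {}
    for val in values:
        p = params.replace(**{name: float(val)})
        out[float(val)] = slope_study(p, grades=grades, v=v, f=f,
                                      config=config)
    return out


def unified_nominal_report(params: ModelParams, v: float, f: float,
                           config: TranscriptionConfig | None = None):
    """Solve one unified-nominal gait and report trajectory exports,
    gait metrics and the energy breakdown.

    Returns (solution, audit, metrics, report dict). The report
    includes the vertical work-loop samples (vertical acceleration vs.
    vertical displacement) and a force time-asymmetry indicator
    (rise-rate minus fall-rate of the vertical GRF, positive when force
    rises faster than it falls, as in human running)."""
    sol = solve_stance(params, GaitTask(v=v, f=f), config)
    audit = energy_audit(sol)
    metrics = GaitMetrics.from_solution(sol, audit)
    _, gy = sol.grf
    ipk = int(np.argmax(gy))
    t_rise = sol.t[ipk] - sol.t[0]
    t_fall = sol.t[-1] - sol.t[ipk]
    asym = (1.0 / max(t_rise, 1e-9) - 1.0 / max(t_fall, 1e-9))
    acc_y = np.gradient(sol.vy_b, sol.t)
    report = dict(
        v=v, f=f,
        elastic_return_fraction=audit.elastic_return_fraction,
        force_time_asymmetry=float(asym),
        work_loop=dict(vertical_displacement=(sol.y_b - sol.y_b[0]).tolist(),
                       vertical_acceleration=acc_y.tolist()),
        energy=audit.to_dict(),
        metrics=asdict(metrics),
    )
    return sol, audit, metrics, report


def load_grf_table(path) -> pd.DataFrame:
    """Read a user-supplied ground-reaction-force trace (CSV/TSV with
    columns time and GRF components) for qualitative overlay against
    model outputs. Never required by any computation here."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    if "time" not in df.columns:
        raise ValueError("GRF table needs a 'time' column")
    return df
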