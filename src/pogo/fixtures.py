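"""Run manifests and deterministic reference fixtures.

A :class:`RunManifest` records everything needed to reproduce a solve:
parameters, task, solver configuration, seed and software version.
:func:`generate_fixtures` produces the reference objects used by the
regression tests — passive spring-mass trajectories from the shooting
oracle, analytic collision/flight cases, and one frozen unified-nominal
solution with its energy breakdown.
"""
from __future__ import annotations

import json
import platform
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from . import __version__
from .collocation import solve_stance
from .energetics import energy_audit
from .params import (GaitTask, ModelParams, TranscriptionConfig,
                     validate_config)
from .shooting import find_periodic_gait, mechanical_energy


class RunManifest:
    """Serializable record sufficient to re-run a solve reproducibly
    (up to solver tolerance)."""

    def __init__(self, params: ModelParams, task: GaitTask,
                 config: TranscriptionConfig, diagnostics=None):
        self.data = dict(
            params=asdict(params), task=asdict(task), config=asdict(config),
            version=__version__, python=platform.python_version(),
            created=datetime.now(timezone.utc).isoformat(),
            diagnostics=diagnostics or {},
        )

    def save(self, path):
        Path(path).write_text(json.dumps(self.data, indent=2, default=float))

    @classmethod
    def load(cls, path):
        data = json.loads(Path(path).read_text())
        m = cls.__new__(cls)
        m.data = data
        return m

    def rerun(self):
        """Re-solve the recorded task; returns (solution, audit)."""
        params = ModelParams(**self.data["params"])
        task = GaitTask(**self.data["task"])
        config = TranscriptionConfig(**self.data["config"])
        sol = solve_stance(params, task, config)
        return sol, energy_audit(sol)


def run_from_config(raw: dict):
    """Validate a flat config mapping, solve, and return
    (solution, audit, manifest)."""
    params, task, config = validate_config(raw)
    sol = solve_stance(params, task, config)
    audit = energy_audit(sol)
    manifest = RunManifest(params, task, config,
                           diagnostics=sol.diagnostics)
    return sol, audit, manifest


def generate_fixtures(seed: int = 0, stiffnesses=(25.0, 46.7, 90.0),
                      v: float = 3.0, f: float = 2.94):
    """Deterministic reference fixtures (all values computed here, none
    hard-coded):

    a. passive spring-mass gaits at three normalized stiffnesses from
       the shooting oracle, with their mechanical-energy traces;
    b. analytic collision and flight cases with closed-form expected
       values;
    c. one frozen unified-nominal solution summary for regression.
    """
    sc = ModelParams.nominal().scales
    v_n, f_n = v / sc.speed, f * sc.time
    passive = {}
    for k in stiffnesses:
        gait = find_periodic_gait(k, v_n, f_n)
        states = gait.sample(200)
        passive[k] = dict(
            gait=gait,
            states=states,
            energy=mechanical_energy(states, k),
        )

    analytic = dict(
        collision=[
            dict(CF=0.0, ke_loss=0.0),
            dict(CF=0.03, ke_loss=1.0 - 0.97**2),
            dict(CF=0.06, ke_loss=1.0 - 0.94**2),
        ],
        flight=dict(vy0=1.0, duration=2.0 / 9.81,
                    vy_end=-1.0, height_change=0.0),
    )

    params = ModelParams.nominal()
    task = GaitTask(v=v, f=f)
    config = TranscriptionConfig(seed=seed)
    sol = solve_stance(params, task, config)
    audit = energy_audit(sol)
    frozen = dict(E_total=audit.E_total, breakdown=audit.to_dict(),
                  t_stance=sol.t_stance, seed=seed)
    return dict(passive=passive, analytic=analytic, frozen_nominal=frozen,
                solution=sol)


def write_fixtures(outdir, seed: int = 0):
    """Materialize the fixture set as CSV/JSON files under ``outdir``."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fx = generate_fixtures(seed=seed)
    for k, item in fx["passive"].items():
        df = pd.DataFrame(item["states"], columns=["x", "y", "vx", "vy"])
        df["energy"] = item["energy"]
        df.to_csv(outdir / f"passive_k{k:g}.csv", index=False)
    (outdir / "analytic_cases.json").write_text(
        json.dumps(fx["analytic"], indent=2))
    (outdir / "frozen_nominal.json").write_text(
        json.dumps(fx["frozen_nominal"], indent=2, default=float))
    fx["solution"].to_frame().to_csv(outdir / "nominal_trajectory.csv",
                                     index=False)
    return outdir
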