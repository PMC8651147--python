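# Methods

## The model

`pogo` simulates steady running of a point-mass body on a massless,
actuated, elastic leg. Between flight phases the body's center of mass
(CoM) is supported by one stance leg whose axial force is generated by
a linear spring (stiffness `k`) in series with an ideal actuator, the
arrangement standing in for a muscle–tendon unit. Two passive loss
channels make the gait cost energy:

- **Tendon hysteresis.** A viscous damper in parallel with the spring
  dissipates energy only while the spring loads (compression rate
  > 0); once the spring recoils the damper is silent. The damper
  strength is expressed as a damping ratio `zeta = c / (2 sqrt(M k))`.
- **Touchdown collision.** At foot contact the CoM velocity vector
  keeps its direction but loses the fraction `CF` of its magnitude, so
  the kinetic energy drops by `1 - (1 - CF)^2` (5.91% at the nominal
  `CF = 0.03`).

Because the leg is massless, the actuator force, spring–damper force
and axial leg force are one and the same (`F_m`), acting along the
foot-to-CoM line and constrained non-negative (the ground cannot
pull). The series kinematics are `L_l = L + q - delta`, where `L_l` is
leg length, `q` the actuator displacement from its nominal length and
`delta` the spring compression; the spring is at rest when the leg is
at its maximum length `L` with the actuator nominal. In the air the
chain is force-free, so the spring must be unloaded (`delta = 0`) at
both touchdown and takeoff; these are boundary conditions of the
optimization. An immediate consequence is that the ground-reaction
force starts at the (small) damper value `c * ddelta(0)` and ends at
exactly zero.

## The metabolic objective

One step costs `E = E_W + E_R`:

- **Work cost** `E_W = W+ / eta+ + W- / eta-`, with positive and
  negative actuator work priced at signed efficiencies (defaults
  `eta+ = 0.32`, `eta- = -1.05`; both terms are non-negative).
- **Force-rate cost** `E_R = epsilon * int (dF_m/dt)^2 dt`, a penalty
  on rapid force production. `epsilon` is given in normalized units
  (`M^-1 g^-1.5 L^1.5`, default `0.5e-3`); the force rate is the
  analytic derivative of the spring–damper force along the trajectory,
  which is why the actuator jerk (third derivative of its length) is
  the control variable — it keeps `dF_m` a smooth state function.

The objective integrates over the stance phase; during flight the leg
is force-free and contributes nothing. The collision is a velocity
impulse outside the force-rate integral.

## Trajectory optimization

One periodic step is transcribed by trapezoidal direct collocation
(default 30 nodes) over the stance phase with free stance duration;
the flight phase is handled in closed form and the step is closed by
periodicity constraints: the CoM state at the end of stance, propagated
ballistically for the flight time and through the collision map, must
reproduce the start-of-stance state displaced by one step length along
the ground. Speed and step frequency are imposed per task (the model
does not choose them); the touchdown leg angle is free.

Path constraints: `F_m >= 0` at interior nodes (the boundary nodes are
pinned by the unloaded-spring equalities; duplicating them would make
the constraint Jacobian rank-deficient), `L_l <= L`, CoM above the
contact, and a large, inactive-by-default box on the jerk control
(±2000 normalized; reported in outputs).

The NLP is solved by scipy's interior-point method (`trust-constr`)
with **exact first and second derivatives**: the per-node gradients,
Jacobians and Hessians of the dynamics, the path constraints and the
cost integrand are generated symbolically once (`scripts/
generate_kernels.py`, requiring sympy) and shipped as plain numpy code
in `pogo._kernels`. Quasi-Newton approximations (SLSQP or BFGS-based
trust-constr) stall far from the optimum on this problem — they leave
the actuator profile essentially unshaped — so the exact Hessians are
load-bearing, not an optimization nicety. The solver stops when
feasible (violation < 1e-8), past the interior-point barrier tail, and
stalled in objective (relative change < 1e-7 over 40 iterations).

Two smoothing devices make the problem differentiable inside the
optimizer, both with exact counterparts in the post-hoc audit: the
damper's on/off switch becomes a tanh gate of width 0.01 normalized
velocity, and the positive/negative power split uses soft
rectification of width 1e-3 normalized power. On converged solutions
the smooth objective and the exactly-rectified audit agree within
0.5%.

Cold solves start from a periodic passive spring-mass gait found by
shooting (an independent `solve_ivp` integration with a root find on
the touchdown angle and velocity), plus seeded perturbed restarts
(default 3, best objective kept); parameter sweeps warm-start each
point from its converged neighbor and bisect the gap on failure. All
randomness is the perturbation noise, driven by one seed.

### Normalization

Everything inside the NLP uses body mass `M`, gravitational
acceleration `g` and leg length `L` as base units (`M = g = L = 1`;
defaults 70 kg, 9.81 m/s², 0.9 m). The API accepts and returns SI;
invariance under the choice of base units holds exactly at the
nondimensionalization layer and to solver tolerance across re-solves
with different bases.

### Model variants

- `actuated_spring_mass` — the full model above.
- `spring_mass` — the classic conservative template: no actuator, no
  damper, no collision. Solved by shooting, not by the NLP; it also
  serves as the independent oracle for the transcription (locked-
  actuator collocation reproduces its trajectories to ≤1e-4 RMS).
- `actuator_only` — a spring-free, fully active leg, emulated as the
  stiff-spring limit (default emulation stiffness 500 normalized, at
  which the "spring" stores a vanishing `F^2/2k`). With a force-rate
  cost this behaves as the literature's actuator-only runner (near-zero
  elastic return, roughly 2.5× the actuated model's cost); with a
  work-only cost its optimum collapses onto the emulation spring's own
  passive bounce, whose stance duration shrinks toward the impulsive
  limit as the emulation stiffness grows. Conclusions about the
  work-only actuator-only model should respect that caveat.

## Energy audit

`energy_audit` decomposes a converged step with exact switching and
rectification, on an 8× refined grid (cubic resampling) to tame
quadrature error at sign changes: positive/negative actuator work,
spring return work, damper loss, collision loss (closed form from the
incoming velocity), `E_W`, `E_R`, cost rate, cost of transport, and
the elastic return fraction `W_spring+ / (W_spring+ + W_act+)`. The
periodic balance `W+ + W- = E_hyst + E_coll + M g (rise per step)`
closes to ~2e-3 relative at the default 30-node mesh (trapezoidal
discretization error, O(h²)) and to <1e-4 at 160 nodes.

**Hysteresis convention.** Tendon hysteresis is reported as the
work-loop ratio, damper loss divided by the energy absorbed during
loading (stored + lost). At `zeta = 0.1` the nominal gait dissipates
~26% per stretch-shortening cycle under this convention — matching
the value the damping ratio was calibrated to represent — whereas
dividing by peak stored energy alone gives ~35%. Both numbers are
reported; the loop convention is primary because it is how tendon
hysteresis is measured empirically.

**Mechanical-energy denominator.** "Passive dissipation as a fraction
of the body's mechanical energy" uses kinetic plus gravitational
potential energy above the ground contact, evaluated at touchdown.

## Parameters that matter

| symbol | meaning | default | units |
|---|---|---|---|
| `M`, `g`, `L` | body mass, gravity, max leg length | 70, 9.81, 0.9 | kg, m/s², m |
| `k` | series spring stiffness | 35.6e3 (46.7 Mg/L) | N/m |
| `zeta` | damping ratio of the loading-only damper | 0.1 | – |
| `CF` | momentum fraction lost at touchdown | 0.03 | – |
| `eta_pos`, `eta_neg` | signed work efficiencies | 0.32, -1.05 | – |
| `epsilon` | force-rate cost coefficient | 0.5e-3 | M⁻¹g⁻¹·⁵L¹·⁵ |
| `v`, `f` | speed, step frequency | task inputs; `f = 0.26 v + 2.17` is the human preferred-frequency law | m/s, Hz |
| `grade` | ground slope, rise over run | 0 | – |

The defaults are the unified human-like parameter set; sensitivity
studies vary `k` (6.46–160 Mg/L), `epsilon` (0–2e-2), `zeta` (0–0.2)
and `CF` (0–0.06).

## Problem sizes and numerical choices

Default runs use 30 collocation nodes (≈250 NLP variables), which
solve in ~3–10 s cold and ~1–5 s warm-started on one CPU; speed sweeps
use 9 points over 2–4 m/s and slope sweeps 16 grades over −0.20 to
+0.10, both warm-started. Mesh-doubling changes the per-step cost by
<0.2% at the nominal gait. Degenerate cases: with all losses and the
force-rate cost zeroed, the objective is flat at zero over the set of
passive gaits, and the solver returns one of them (cost < 1e-3
normalized); infeasible tasks (e.g. speeds beyond any admissible
stance state) raise an explicit `SolveError` with per-start
diagnostics.

## What the model does and does not say about real running

The model reproduces, as outcomes of optimization rather than fitted
curves: human-scale stance times and single-humped ground-reaction
profiles; spring return of ~60% of positive leg work at 3 m/s and ~54%
at 3.9 m/s; passive dissipation below 5% of the body's mechanical
energy yet responsible for essentially all of the work cost on level
ground; metabolic rate rising with speed, tightly correlated with
inverse contact time (R² ≈ 0.98 against 1/t_c, with 1/t_c ≈ linear in
speed); a cost-of-transport minimum near −8% grade; and vertical GRF
rising faster than it falls. One published-scale quantity it does not
reproduce at the printed force-rate coefficient: the split of total
cost between work and force rate comes out ≈86/14 rather than ≈68/32 —
the force-rate integral would need an effective coefficient 2–3×
larger, and no alternative local optimum of our transcription closes
the gap (verified by sweeping fixed stance durations). The remaining
headline quantities are insensitive to this split.

It is a template model: no swing-leg cost, no leg mass, no
force–velocity or activation dynamics, a single lumped spring, a
magnitude-only collision, and imposed (not optimized) speed and step
frequency. Quantities that depend on those omissions — absolute
metabolic rates including resting metabolism, for one — require an
additive offset that is deliberately left as a user parameter with no
default.
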