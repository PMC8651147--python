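# pogo — actuated spring-mass running

The classic spring-mass (SLIP) template explains the mechanics of
running — bouncing CoM trajectories, single-humped ground-reaction
forces, spring-like work loops — but, being conservative, it predicts
zero metabolic cost and cannot run on a slope. `pogo` implements an
*actuated* spring-mass runner for researchers in locomotion
biomechanics and legged robotics: a point mass `M` on a massless leg
in which an ideal actuator works in series with a linear spring `k`
(a muscle–tendon unit), a parallel damper dissipates energy only
while the spring loads (tendon hysteresis, damping ratio ζ), and the
touchdown collision removes a fraction CF of the CoM momentum.

Each periodic step is found by trajectory optimization: trapezoidal
direct collocation of the stance phase (flight in closed form,
collision as a boundary map), solved with exact symbolic first and
second derivatives, minimizing the metabolic cost per step

    E = E_W + E_R,
    E_W = W⁺/η⁺ + W⁻/η⁻              (signed efficiencies η⁺>0, η⁻<0)
    E_R = ε ∫ Ḟ_m² dt                 (force-rate cost)

subject to task constraints (speed `v`, step frequency `f`, ground
grade) and physical ones (leg length ≤ L, pushing forces only, spring
unloaded at touchdown and takeoff). With human-like parameters the
optimal gaits reproduce the mechanics *and* much of the energetics of
running: substantial elastic energy return, yet a real energy bill
dominated by the active work that restores hysteresis and collision
losses, plus a force-rate penalty that smooths the forces.

## Worked example

Solve the unified nominal gait (70 kg, 0.9 m legs, k = 35.6 kN/m,
ζ = 0.1, CF = 0.03, η = +0.32/−1.05, ε = 0.5·10⁻³) at 3 m/s and
2.94 Hz:

```python
import pogo

params = pogo.ModelParams.nominal()
sol = pogo.solve_stance(params, pogo.GaitTask(v=3.0, f=2.94))
audit = pogo.energy_audit(sol)
```

which prints, via the fields of `sol` and `audit`:

```
E per step      : 159.4 J  (work 137.4 J, force-rate 22.0 J)
cost rate       : 469 W   cost of transport: 0.227
stance / flight : 172 ms / 169 ms
spring return   : 60.0 % of positive leg work
hysteresis      : 25.7 % per cycle   collision loss: 21.5 J
peak vertical GRF: 3.21 body weights
```

Reading: the spring passively supplies 60% of the positive leg work,
and the two passive losses together are under 5% of the body's
mechanical energy — yet restoring them (plus pricing force rate) costs
159 J every step, i.e. ~6.7 W/kg of metabolic power. `sol.to_frame()`
exports the trajectory (forces, powers, lengths) as a DataFrame.

The same things are available from a shell:

```sh
pogo solve --v 3.0 --f 2.94 --out results/nominal
pogo speed-sweep --v-min 2 --v-max 4 --points 9 --out results/speeds
pogo slope-study --v 3.0 --f 2.94 --out results/slopes
pogo sensitivity --vary zeta --values 0,0.1,0.2 --out results/zeta
```

Each command writes CSV tables, a JSON summary and a manifest that
`pogo rerun` can reproduce.

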