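# fcmkit

Tools for building and analysing **fuzzy cognitive maps** (FCMs) —
signed, weighted, directed graphs in which nodes are system concepts
(e.g. *water level*, *stress*, *gene activity*) and edges encode causal
influence. FCMs are popular in systems biology, health behaviour
research and engineering because they can be elicited directly from
domain experts and then simulated, optimised and interrogated like any
other dynamical model.

`fcmkit` covers the full workflow:

* **Expert construction** — convert per-expert linguistic edge ratings
  ("positive high", "negative low", …) into a numeric weight matrix via
  fuzzy logic: triangular/trapezoidal/Gaussian membership functions,
  Mamdani or Larsen implication, four aggregation operators
  (max, algebraic/Einstein/Hamacher sums) and four defuzzifiers
  (centroid, mean/min/max of maxima), plus agreement entropy and a
  valence-consistency check.
* **Simulation** — iterate `A_i(t+1) = f(A_i(t) + Σ_j A_j(t)·w_ji)`
  (modified Kosko; plain Kosko and rescaled variants too) with sigmoid,
  tanh, bivalent or trivalent transfer `f`, until every monitored
  concept changes by less than a threshold.
* **Hebbian learning** — nonlinear (NHL, synchronous) and active (AHL,
  asynchronous, pattern-driven) Hebbian adaptation that tunes the
  expert matrix until chosen *desired output concepts* settle inside
  target ranges.
* **Genetic learning** — a real-coded genetic algorithm (generational
  or steady-state) that recovers a full weight matrix from longitudinal
  concept data, with fitness `1/(a·Error + 1)`, plus in-sample (ISE)
  and out-of-sample (OSE) validation.
* **Scenario analysis** — what-if interventions on the converged
  system: one-off state perturbations or a permanently clamped
  intervention node with an effectiveness dial, reported as equilibria
  and percent change against baseline.
* **Classification** — a deterministic Moore–Penrose FCM classifier
  over ARFF feature tables (least-squares inner weights, pseudo-inverse
  output weights, feature-importance vector).

## Worked example

The packaged `water_tank` fixture is the classic five-concept tank
control system (tank level C1, inlet/outlet valves, heater element).
NHL adapts its expert matrix so that C1 settles in [0.68, 0.74] and C5
in [0.74, 0.8]:

```python
from fcmkit import load_fixture, nhl_run

tank = load_fixture("water_tank")
res = nhl_run(tank.initial_state, tank.weight_matrix, tank.doc_values,
              learning_rate=0.01, l=0.98, decay=1.0, iterations=100)
print(res.converged_step)               # 63
print(round(res.weights.loc["C1", "C5"], 6))   # 0.472687
print(round(res.weights.loc["C4", "C1"], 6))   # -0.832174
```

The learner stops at step 63 (steps count from 0) once both target
concepts sit inside their ranges and their step-to-step change falls
below 0.002. The positive C1→C5 edge has strengthened from 0.30 to
0.473, while the strong negative C4→C1 control edge relaxed from −0.90
to −0.832 — the matrix keeps its expert topology and edge signs, only
the magnitudes adapt.

Scenario analysis on the packaged eight-concept example:

```python
from fcmkit import Intervention, load_fixture

fx = load_fixture("eight_concept")
inter = Intervention()
inter.initialize(fx.initial_state, fx.weight_matrix,
                 inference="mKosko", transfer="sigmoid", l=1,
                 thresh=0.001, iterations=50)
inter.add_intervention("cut_C1_boost_C2", "continuous",
                       impact={"C1": -0.3, "C2": 0.5}, effectiveness=1)
inter.test_intervention("cut_C1_boost_C2")
print(inter.comparison_table.round(2))
```

```
    baseline  cut_C1_boost_C2
C1       0.0           -11.19
C2       0.0            10.04
C3       0.0            -1.39
C4       0.0            -1.66
C5       0.0            -0.19
C6       0.0            -0.18
C7       0.0             0.12
C8       0.0            -0.12
```

A permanent intervention pushing C1 down by 0.3 and C2 up by 0.5 moves
the C1 equilibrium down 11.2 % and C2 up 10.0 %, with small knock-on
effects elsewhere in the network.

Every subcommand is also available from the shell via the `fcm` entry
point (`fcm build`, `fcm simulate`, `fcm nhl`, `fcm ahl`, `fcm rcga`,
`fcm validate`, `fcm intervene`, `fcm classify`).

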