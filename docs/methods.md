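# Methods

This note documents the models implemented in `fcmkit`, the numerical
choices behind them, and what the test suite does and does not
establish.

## The FCM model

A fuzzy cognitive map over concepts `C_1 … C_n` is a weight matrix
`W` with `w_ji ∈ [−1, 1]` the causal impact of source `j` (row) on
target `i` (column). Activations evolve in discrete steps:

* Kosko: `A_i(t+1) = f( Σ_j A_j(t) · w_ji )`
* modified Kosko: adds the self-memory term `A_i(t)` inside `f`
* rescaled: recenters every activation to `2A − 1` before the sum

with transfer `f` one of sigmoid `1/(1+e^{−λx})` (range [0,1], default
slope λ = 1), `tanh` ([−1,1]), bivalent (`1` if `x > 0` else `0`) and
trivalent (the sign function; ties at `x = 0` map to 0 in both
discrete variants). A run converges when **every** monitored concept
changes by less than the threshold (default 0.001) between consecutive
states; the element-wise reading of the stopping rule matters, a norm
over the state vector would stop earlier. State counts are reported
1-based including the initial state, so "converged in the 7 state"
means six updates.

## Expert construction

Linguistic terms live on the universe of discourse [−1, 1] sampled at
0.001 (configurable). The default dictionary has eleven triangular
terms, five negative grades, `na` (a numerically degenerate triangle
around 0), five positive grades. Per edge, the proportion `p_i` of
experts endorsing each term is computed **over the experts who rated
that edge** — non-raters do not dilute the distribution; this is the
reading of "proportion of the answers" that keeps proportions summing
to 1 for partially rated edges. Each endorsed term's membership
function is activated at `p_i` (Mamdani clips, Larsen scales), the
activated functions are folded with the chosen aggregation operator
(term-set order; all four operators are associative-commutative on
[0, 1] so the fold order only matters at float round-off), and the
aggregate is defuzzified. Centroid defuzzification is the discrete
`Σ x·μ(x) / Σ μ(x)` over the sampled grid, so crisp weights carry a
grid-resolution error of order the step size; an identically zero
aggregate (an all-`na` edge) defuzzifies to 0 by convention rather
than dividing 0/0.

Rating-agreement entropy is Shannon entropy (base 2) of the per-edge
term distribution: 0 for unanimity, `log2 k` for `k` equi-endorsed
terms. Valence consistency classifies a term by the sign of its center
parameter; terms centered at 0 (`na`, `±vl`) are valence-neutral and
never conflict.

## Hebbian learning

Both learners adapt the matrix so that chosen desired output concepts
(DOCs) settle inside user ranges. The termination logic is shared:
`F1 = |DOC − (min+max)/2|` must be non-increasing for every DOC, every
DOC must lie inside its range, and `F2 = |DOC(k+1) − DOC(k)| < e`
(default `e = 0.002`, the midpoint of the recommended 0.001–0.005
band). F1 is measured against the **midpoint** of the range: the
printed formula in the source literature has `(min − max)/2`, which is
negative for positive ranges and cannot serve as a target, so we treat
it as a typo for the midpoint. Learning steps are reported 0-based.

**NHL** updates all initially nonzero weights synchronously with the
Oja-normalised rule

    w_ji(k+1) = γ·w_ji(k) + η·A_i(k)·( A_j(k) − sgn(w_ji)·w_ji(k)·A_i(k) )

then advances the states one modified-Kosko + sigmoid step using the
**new** weights. Zero entries stay exactly zero; each nonzero entry is
clipped to its sign's half-interval ([0,1] or [−1,0]), so the expert
topology and edge signs survive learning. Defaults: η = 0.01, γ = 1.

**AHL** walks an activation pattern (position → concepts). Per
learning step, each position group is visited in order: the activated
concepts update their own state asynchronously (modified Kosko +
sigmoid, other states frozen), then each activated concept `j` updates
its **outgoing** edges

    w_jm(k+1) = (1−γ)·w_jm(k) + η·A_j·( A_m − w_jm·A_j ),   m ≠ j

which both tunes existing edges and grows new connections out of zero
entries (the self-loop is excluded). Termination is checked after every
position group, so a run can stop mid-pattern. The update orientation
(outgoing rows at the source's activation, states before weights) and
the per-group termination check are fixed by reproducing the published
water-tank reference runs to 1e−6: the NHL run converges at step 63
with `w(C1→C5) = 0.472687`, the AHL run at step 19 with
`w(C5→C2) = 0.368913`, and every other printed matrix entry matches to
the printed precision. Several superficially plausible alternatives
(incoming-edge updates, synchronous weight updates, cycle-boundary
termination) reproduce most but not all entries and were rejected.
AHL has no default decay; either supply γ or enable the auto-learn
schedules `η(k) = b1·e^{−λ1 k}`, `γ(k) = b2·e^{−λ2 k}`.

## Genetic learning (RCGA)

Candidates are full `n²`-gene matrices in [−1, 1] (the diagonal is
searched: self-loops are legitimate solutions). Fitness simulates the
candidate from the first observed row for `T−1` steps and scores

    Error   = α · Σ_t Σ_j |C_j(t) − Ĉ_j(t)|^p
    Fitness = 1 / (a·Error + 1)

with `α = 1/((T−1)·N)` (per-entry mean; the normalisation parameter is
otherwise unconstrained), `p` from the norm choice (L1 → 1, L2 → 2;
L∞ sums the per-step maxima) and `a = 100`. The sums run over all `N`
concepts and all `T−1` transitions — an upper bound of `N−1` would
make fitness depend on column order.

Selection draws uniformly between roulette wheel and tournament
(size 2) each generation; recombination is one-point crossover
(probability 0.9); mutation hits one uniformly chosen gene per event
(probability 0.5), either resampling it in [−1, 1] or perturbing it
non-uniformly with the Michalewicz schedule (shape b = 5), whose
magnitude collapses as the generation counter approaches the horizon.
The generational scheme keeps the best individual (elitism), making
best-ever fitness non-decreasing; the steady-state scheme inserts each
offspring over the worst member when fitter, otherwise over its
nearest (L1 gene distance) member when fitter — a concrete reading of
useful-diversity replacement. All randomness flows through one seeded
`numpy` generator.

ISE is the per-entry mean deviation of the candidate's trajectory from
the data. OSE draws `k` random initial states in [low, high]: with a
reference matrix it compares candidate and reference trajectories;
without one it compares the candidate's endpoint to the data's final
row (both modes are explicit, since the comparator is not otherwise
pinned down).

## Scenario analysis

`initialize` runs the untouched system to its attractor; that final
vector is the baseline equilibrium. Single-shot interventions restart
the simulation from the baseline equilibrium with the listed concepts
overridden — perturbing the settled system, which is the reading
consistent with requiring initialization first; the alternative
(overriding the original initial state) is noted but not used.
Continuous interventions append one clamped node whose outgoing
weights are `impact × effectiveness` (linear scaling) and which is
pinned to activation 1 after every step; it has no incoming edges, is
excluded from convergence monitoring and never appears in the output
tables. Percent change is `(equilibrium − baseline)/baseline × 100`
per concept; a zero baseline yields NaN, never infinity.

## Classifier

The Moore–Penrose FCM classifier is implemented at reduced fidelity:
the published description fixes the topology (M feature + N class
nodes), the unsupervised least-squares inner weights and the
pseudo-inverse output weights, but not the exact inner objective or
the meaning of the four squashing parameters. Our choices: inner
weights solve a ridge-regularised (1e−6) self-prediction
`min ‖XW − X‖²`; the hidden state propagates `T` steps (default 1)
through `expit(p1·x + p2−1)` with a logit input option parameterised
by `p3, p4` (defaults all 1.0); output weights are `pinv(H)·Y` onto
one-hot targets. Instances are put in a canonical sort order before
stratified k-folding so the fold-mean aggregate weights are invariant
to instance order. Feature importance is the signed per-feature sum of
output weights scaled by its maximum absolute value into [−1, 1] (the
derivation is not published; this is the package's choice). Ties in
class scores resolve to the lowest class index. Acceptance for this
module is property-based (pseudo-inverse optimality, separable-fixture
accuracy, importance bounds) — published dataset-specific weight
matrices are not reproducible from the description and are not
targets.

## Synthetic data and what the tests show

The packaged fixtures are the two reference systems (the 8-concept
map and the 5-concept water tank) plus a six-expert synthetic survey
whose (C1, C2) edge carries the canonical worked rating distribution
(half "+h", a third "+vh", a sixth "+m" — centroid ≈ 0.702) and whose
other edges cover unanimity, partial rating and all-"na" cases. The
survey is constructed, not collected: it exercises the construction
pipeline against a brute-force grid oracle and the one published
worked value, but says nothing about real expert behaviour
(correlated opinions, missing answers, scale-use bias). The RCGA
study recovers a 3-concept sparse matrix from three observed time
points — two transitions, mirroring the published study design, which
also truncates its data to three rows; recovery from longer, fully
determined trajectories is harder at the same budget (population 50,
≤ 2000 generations) and is not claimed. The classifier fixture is a
pair of direction-separated Gaussian clusters; with no bias term in
the output layer, clusters separated only in magnitude along a common
direction are *not* linearly separable, and the fixture deliberately
avoids that degenerate geometry.

## Known limitations

* Continuous-time and asynchronous-random-order FCM variants are out
  of scope, as are interval-valued fuzzy sets and custom implication
  operators.
* If some monitored concepts converge while others oscillate, the
  simulator runs to the iteration cap; no oscillation detection is
  attempted.
* The evolving-weights classifier variant (iteration-dependent
  weights) is not implemented.
* Centroid weights inherit the universe grid resolution (±~1e−3 at
  the default step); tighten the grid for sharper estimates.
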