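"""Real-coded genetic algorithm for learning FCM matrices from data.

Given longitudinal concept observations C(0..T-1), the search looks for
an n x n weight matrix whose simulated trajectory from C(0) reproduces
the remaining rows.  Candidate fitness is

    Error   = alpha * sum_t sum_j |C_j(t) - Chat_j(t)|^p
    Fitness = 1 / (a * Error + 1)

with alpha defaulting to the per-entry mean 1 / ((T-1) * N), the norm
exponent p following the chosen normalisation (L1 -> 1, L2 -> 2; LInf
uses the per-step maximum over concepts) and a = 100.

Both a generational scheme (whole population replaced, elitist) and a
steady-state scheme (two offspring per step, useful-diversity
replacement) are available.  Selection alternates at random between
roulette-wheel and tournament; recombination is one-point crossover;
mutation is random or non-uniform (Michalewicz schedule).  All
chromosomes carry n^2 genes in [-1, 1] -- the diagonal is searched too.

ISE/OSE validate a learned matrix in-sample (trajectory deviation from
the data) and out-of-sample (deviation statistics over random initial
states).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import SimulationConfig, transfer

__all__ = [
    "FitnessConfig",
    "GAConfig",
    "fitness",
    "select",
    "crossover",
    "mutate",
    "rcga_run",
    "RCGAResult",
    "ise",
    "ose",
]

_NORM_P = {"L1": 1, "L2": 2}


@dataclass
class FitnessConfig:
    alpha: float | None = None  # default 1 / ((T-1) * N)
    normalization_type: str = "L1"
    p: int | None = None  # overrides the norm exponent when given
    a: float = 100.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("a must be > 0")
        if self.normalization_type not in ("L1", "L2", "LInf"):
            raise ValueError("normalization_type must be L1, L2 or LInf")
        if self.p is not None and self.p < 1:
            raise ValueError("p must be >= 1")


@dataclass
class GAConfig:
    population_size: int = 100
    ga_type: str = "generational"
    p_recombination: float = 0.9
    p_mutation: float = 0.5
    n_iterations: int = 1000
    threshold: float = 0.99
    tournament_size: int = 2
    mutation_b: float = 5.0  # non-uniform mutation shape
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.ga_type not in ("generational", "ssga"):
            raise ValueError("ga_type must be 'generational' or 'ssga'")
        for p in (self.p_recombination, self.p_mutation):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class RCGAResult:
    solution: pd.DataFrame
    fitness: float
    history: list[float]  # best-ever fitness per generation


def _as_data(data) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), list(data.columns)
    arr = np.asarray(data, dtype=float)
    return arr, [f"C{i + 1}" for i in range(arr.shape[1])]


def _trajectory(w: np.ndarray, start: np.ndarray, steps: int,
                sim: SimulationConfig) -> np.ndarray:
    """Predicted states for `steps` updates from `start` (no stopping).

    A lean numpy replica of :func:`fcmkit.dynamics.infer_step` -- the GA
    evaluates fitness tens of thousands of times, so the per-step pandas
    bookkeeping is skipped here (agreement is covered by a test).
    """
    out = np.empty((steps, len(start)))
    a = np.asarray(start, float)
    for t in range(steps):
        if sim.inference == "kosko":
            x = a @ w
        elif sim.inference == "mKosko":
            x = a + a @ w
        else:  # rescaled
            r = 2.0 * a - 1.0
            x = r + r @ w
        a = transfer(x, sim.transfer, sim.l)
        out[t] = a
    return out


def _error(pred: np.ndarray, obs: np.ndarray, fc: FitnessConfig,
           alpha: float) -> float:
    diff = np.abs(pred - obs)
    if fc.normalization_type == "LInf" and fc.p is None:
        return float(alpha * diff.max(axis=1).sum())
    p = fc.p if fc.p is not None else _NORM_P[fc.normalization_type]
    return float(alpha * (diff**p).sum())


def fitness(candidate, data, sim: SimulationConfig | None = None,
            fc: FitnessConfig | None = None) -> float:
    """Fitness of one candidate matrix against the observed data."""
    sim = sim or SimulationConfig()
    fc = fc or FitnessConfig()
    obs, _ = _as_data(data)
    T, N = obs.shape
    if T < 2:
        raise ValueError("longitudinal data needs at least two rows")
    w = candidate.to_numpy() if isinstance(candidate, pd.DataFrame) else np.asarray(candidate, float)
    if w.shape != (N, N):
        raise ValueError(f"candidate shape {w.shape} does not match {N} concepts")
    alpha = fc.alpha if fc.alpha is not None else 1.0 / ((T - 1) * N)
    pred = _trajectory(w, obs[0], T - 1, sim)
    err = _error(pred, obs[1:], fc, alpha)
    return 1.0 / (fc.a * err + 1.0)


def select(population: np.ndarray, fitnesses: np.ndarray,
           rng: np.random.Generator, n_parents: int = 2,
           strategy: str | None = None,
           tournament_size: int = 2) -> np.ndarray:
    """Draw parents; the strategy itself is picked 50/50 when not given."""
    if strategy is None:
        strategy = rng.choice(["roulette", "tournament"])
    m = len(population)
    if strategy == "roulette":
        total = fitnesses.sum()
        probs = np.full(m, 1.0 / m) if total <= 0 else fitnesses / total
        idx = rng.choice(m, size=n_parents, p=probs)
    elif strategy == "tournament":
        idx = np.empty(n_parents, dtype=int)
        for i in range(n_parents):
            contenders = rng.integers(0, m, size=tournament_size)
            idx[i] = contenders[np.argmax(fitnesses[contenders])]
    else:
        raise ValueError(f"unknown selection strategy {strategy!r}")
    return population[idx]


def crossover(parent_a: np.ndarray, parent_b: np.ndarray,
              p_recombination: float,
              rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One-point crossover on the flattened gene vectors."""
    a, b = parent_a.copy(), parent_b.copy()
    if rng.random() < p_recombination and len(a) > 1:
        cut = int(rng.integers(1, len(a)))
        a[cut:], b[cut:] = parent_b[cut:].copy(), parent_a[cut:].copy()
    return a, b


def mutate(child: np.ndarray, p_mutation: float, rng: np.random.Generator,
           mode: str | None = None, generation: int = 0,
           n_iterations: int = 1, b: float = 5.0) -> np.ndarray:
    """Mutate one gene with probability ``p_mutation``.

    ``random`` resamples the gene uniformly in [-1, 1]; ``non_uniform``
    perturbs it with a magnitude that shrinks to 0 as ``generation``
    approaches ``n_iterations``.  The mode is drawn 50/50 when absent.
    """
    out = child.copy()
    if rng.random() >= p_mutation:
        return out
    if mode is None:
        mode = rng.choice(["random", "non_uniform"])
    g = int(rng.integers(0, len(out)))
    if mode == "random":
        out[g] = rng.uniform(-1.0, 1.0)
    elif mode == "non_uniform":
        frac = min(generation / max(n_iterations, 1), 1.0)
        bound = 1.0 if rng.random() < 0.5 else -1.0
        span = (bound - out[g])
        delta = span * (1.0 - rng.random() ** ((1.0 - frac) ** b))
        out[g] = np.clip(out[g] + delta, -1.0, 1.0)
    else:
        raise ValueError(f"unknown mutation mode {mode!r}")
    return out


def rcga_run(data, ga: GAConfig | None = None,
             sim: SimulationConfig | None = None,
             fc: FitnessConfig | None = None, **kwargs) -> RCGAResult:
    """Search matrix space for the best-fitting FCM.

    Stops when the best fitness reaches ``ga.threshold`` or after
    ``ga.n_iterations`` generations; returns the best-ever candidate.
    The best individual always survives in generational mode, so the
    best fitness is non-decreasing across generations.
    """
    ga = ga or GAConfig(**kwargs)
    sim = sim or SimulationConfig()
    fc = fc or FitnessConfig()
    obs, labels = _as_data(data)
    n = obs.shape[1]
    rng = np.random.default_rng(ga.seed)
    pop = rng.uniform(-1.0, 1.0, size=(ga.population_size, n * n))
    fits = np.array([fitness(ind.reshape(n, n), obs, sim, fc) for ind in pop])
    best_i = int(np.argmax(fits))
    best, best_fit = pop[best_i].copy(), float(fits[best_i])
    history = [best_fit]

    def offspring(generation: int) -> tuple[np.ndarray, np.ndarray]:
        pa, pb = select(pop, fits, rng, 2, tournament_size=ga.tournament_size)
        ca, cb = crossover(pa, pb, ga.p_recombination, rng)
        ca = mutate(ca, ga.p_mutation, rng, None, generation,
                    ga.n_iterations, ga.mutation_b)
        cb = mutate(cb, ga.p_mutation, rng, None, generation,
                    ga.n_iterations, ga.mutation_b)
        return ca, cb

    for gen in range(ga.n_iterations):
        if best_fit >= ga.threshold:
            break
        if ga.ga_type == "generational":
            new = [best.copy()]  # elitism
            while len(new) < ga.population_size:
                ca, cb = offspring(gen)
                new.append(ca)
                if len(new) < ga.population_size:
                    new.append(cb)
            pop = np.array(new)
            fits = np.array(
                [fitness(ind.reshape(n, n), obs, sim, fc) for ind in pop]
            )
        else:  # steady-state with useful-diversity replacement
            for child in offspring(gen):
                f_child = fitness(child.reshape(n, n), obs, sim, fc)
                worst = int(np.argmin(fits))
                if f_child > fits[worst]:
                    pop[worst], fits[worst] = child, f_child
                else:
                    near = int(np.argmin(np.abs(pop - child).sum(axis=1)))
                    if f_child > fits[near]:
                        pop[near], fits[near] = child, f_child
        i = int(np.argmax(fits))
        if fits[i] > best_fit:
            best, best_fit = pop[i].copy(), float(fits[i])
        history.append(best_fit)
    return RCGAResult(
        solution=pd.DataFrame(best.reshape(n, n), index=labels, columns=labels),
        fitness=best_fit,
        history=history,
    )


def ise(initial_state, candidate, data,
        sim: SimulationConfig | None = None,
        normalization_type: str = "L1") -> float:
    """In-sample error: mean per-entry deviation of the simulated
    trajectory from the observed data."""
    sim = sim or SimulationConfig()
    obs, labels = _as_data(data)
    T, N = obs.shape
    w = candidate.to_numpy() if isinstance(candidate, pd.DataFrame) else np.asarray(candidate, float)
    if isinstance(initial_state, dict):
        start = np.array([float(initial_state[c]) for c in labels])
    else:
        start = np.asarray(initial_state, float)
    pred = _trajectory(w, start, T - 1, sim)
    fc = FitnessConfig(normalization_type=normalization_type)
    return _error(pred, obs[1:], fc, 1.0 / ((T - 1) * N))


def ose(candidate, data, low: float = 0.0, high: float = 1.0,
        k_validation: int = 100, sim: SimulationConfig | None = None,
        seed: int | None = None, reference=None,
        normalization_type: str = "L1") -> tuple[float, float]:
    """Out-of-sample error over random initial states.

    Draws ``k_validation`` initial vectors uniformly in [low, high] and
    measures, for each, the trajectory discrepancy of the candidate.
    With a ``reference`` matrix the comparison is candidate-vs-reference
    trajectories (T-1 steps); without one, the candidate's trajectory
    endpoint is compared against the data's final row.  Returns the
    mean and standard deviation over the draws.
    """
    sim = sim or SimulationConfig()
    obs, labels = _as_data(data)
    T, N = obs.shape
    w = candidate.to_numpy() if isinstance(candidate, pd.DataFrame) else np.asarray(candidate, float)
    ref = None
    if reference is not None:
        ref = reference.to_numpy() if isinstance(reference, pd.DataFrame) else np.asarray(reference, float)
    rng = np.random.default_rng(seed)
    fc = FitnessConfig(normalization_type=normalization_type)
    errors = np.empty(k_validation)
    for k in range(k_validation):
        start = rng.uniform(low, high, size=N)
        pred = _trajectory(w, start, T - 1, sim)
        if ref is not None:
            expect = _trajectory(ref, start, T - 1, sim)
            errors[k] = _error(pred, expect, fc, 1.0 / ((T - 1) * N))
        else:
            errors[k] = _error(pred[-1:], obs[-1:], fc, 1.0 / N)
    return float(errors.mean()), float(errors.std())
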