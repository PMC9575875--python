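"""Hebbian adaptation of FCM weight matrices.

Two unsupervised learners tune an expert-built matrix so that chosen
Desired Output Concepts (DOCs) settle inside user-given ranges:

* **NHL** (nonlinear Hebbian learning) updates every nonzero weight
  synchronously at each step with the Oja-normalised Hebbian rule

  ``w_ji <- gamma * w_ji + eta * A_i * (A_j - sgn(w_ji) * w_ji * A_i)``

  so the topology (zero pattern) and edge signs are preserved; states
  then advance one modified-Kosko + sigmoid step using the new weights.

* **AHL** (active Hebbian learning) walks through a user-supplied
  activation pattern: at each step the pattern's position groups are
  visited in order, the activated concepts' states update
  asynchronously, and each activated concept's *outgoing* weights
  update with the decaying Hebbian rule

  ``w_jm <- (1 - gamma) * w_jm + eta * A_j * (A_m - w_jm * A_j)``

  which also grows new connections out of zero entries.

Learning stops when, for every DOC, the distance to its range midpoint
(F1) is non-increasing, the DOC value lies inside its range, and the
step-to-step change (F2) is below the threshold ``e``; otherwise at the
iteration cap.  Reported step numbers count from 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import transfer

__all__ = [
    "DOCSpec",
    "HebbianConfig",
    "TerminationMetrics",
    "HebbianResult",
    "termination_check",
    "nhl_run",
    "ahl_run",
]

DOCSpec = Mapping[str, Sequence[float]]


@dataclass
class HebbianConfig:
    """Hyperparameters shared by the two learners.

    ``learning_rate`` (eta) and ``decay`` (gamma) control the Hebbian
    update; ``l`` is the sigmoid slope used for state updates; ``thresh``
    is the stability threshold e of the F2 criterion (recommended range
    0.001-0.005).  In AHL auto-learn mode the schedules
    ``eta(k) = b1 exp(-lbd1 k)`` and ``gamma(k) = b2 exp(-lbd2 k)``
    replace the fixed values.
    """

    learning_rate: float = 0.01
    decay: float | None = None
    l: float = 1.0
    thresh: float = 0.002
    iterations: int = 100
    auto_learn: bool = False
    b1: float = 0.003
    lbd1: float = 0.1
    b2: float = 0.005
    lbd2: float = 1.0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.thresh <= 0:
            raise ValueError("thresh must be > 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.decay is not None and not 0 <= self.decay <= 1:
            raise ValueError("decay must lie in [0, 1]")


@dataclass
class TerminationMetrics:
    """Per-step F1 (distance to range midpoint) and F2 (step change)."""

    f1: list[dict[str, float]] = field(default_factory=list)
    f2: list[dict[str, float]] = field(default_factory=list)


@dataclass
class HebbianResult:
    weights: pd.DataFrame
    states: pd.Series
    metrics: TerminationMetrics
    converged: bool
    converged_step: int | None


def _validate_docs(spec: DOCSpec, labels: Sequence[str]) -> None:
    if not spec:
        raise ValueError("DOC specification is empty")
    for concept, rng in spec.items():
        if concept not in labels:
            raise ValueError(f"DOC {concept!r} is not a concept of the matrix")
        lo, hi = rng
        if not lo < hi:
            raise ValueError(f"DOC range for {concept!r} must satisfy min < max")


def termination_check(
    doc_values_k: Mapping[str, float],
    doc_values_k1: Mapping[str, float],
    spec: DOCSpec,
    f1_history: Sequence[Mapping[str, float]],
    e: float,
) -> tuple[bool, dict[str, float], dict[str, float]]:
    """Evaluate the two stopping conditions for one step.

    F1 is measured against the midpoint of each DOC range; condition
    (a) holds when F1 has not increased for any DOC *and* every DOC
    value is inside its range, condition (b) when every F2 < ``e``.
    Returns ``(stop, f1, f2)``.
    """
    _validate_docs(spec, list(doc_values_k1))
    f1: dict[str, float] = {}
    f2: dict[str, float] = {}
    in_range = True
    for concept, (lo, hi) in spec.items():
        mid = 0.5 * (lo + hi)
        v1 = doc_values_k1[concept]
        f1[concept] = abs(v1 - mid)
        f2[concept] = abs(v1 - doc_values_k[concept])
        in_range &= lo <= v1 <= hi
    declining = bool(f1_history) and all(
        f1[c] <= f1_history[-1][c] for c in spec
    )
    stop = in_range and declining and all(v < e for v in f2.values())
    return stop, f1, f2


def _prep(state, w) -> tuple[np.ndarray, np.ndarray, list[str]]:
    wm = w.astype(float) if isinstance(w, pd.DataFrame) else pd.DataFrame(
        np.asarray(w, float)
    )
    labels = list(wm.columns)
    a = np.array([float(state[c]) for c in labels])
    return a, wm.to_numpy().copy(), labels


def nhl_run(
    state: Mapping[str, float],
    w: pd.DataFrame,
    spec: DOCSpec,
    config: HebbianConfig | None = None,
    **kwargs,
) -> HebbianResult:
    """Nonlinear Hebbian learning (synchronous).

    Only initially nonzero weights adapt; their signs are preserved and
    values clipped to [-1, 1].  With ``learning_rate=0`` and
    ``decay=1`` the run reduces to a plain simulation.  The default
    decay is 1.0 (no forgetting).
    """
    if config is None:
        config = HebbianConfig(**kwargs)
    A, W, labels = _prep(state, w)
    _validate_docs(spec, labels)
    gamma = 1.0 if config.decay is None else config.decay
    eta = config.learning_rate
    mask = W != 0
    sign = np.sign(W)
    metrics = TerminationMetrics()
    prev_doc = {c: A[labels.index(c)] for c in spec}
    for k in range(config.iterations):
        # weights first (from current states), then states with new weights
        J = A[:, None]
        I = A[None, :]
        Wn = gamma * W + eta * I * (J - sign * W * I)
        Wn = np.where(mask, Wn, 0.0)
        # sign-preserving clip: positive edges stay in [0,1], negative in [-1,0]
        W = np.clip(Wn, np.where(sign < 0, -1.0, 0.0),
                    np.where(sign > 0, 1.0, 0.0))
        A = transfer(A + A @ W, "sigmoid", config.l)
        doc_now = {c: A[labels.index(c)] for c in spec}
        stop, f1, f2 = termination_check(
            prev_doc, doc_now, spec, metrics.f1, config.thresh
        )
        metrics.f1.append(f1)
        metrics.f2.append(f2)
        prev_doc = doc_now
        if stop:
            return HebbianResult(
                pd.DataFrame(W, index=labels, columns=labels),
                pd.Series(A, index=labels),
                metrics,
                True,
                k,
            )
    return HebbianResult(
        pd.DataFrame(W, index=labels, columns=labels),
        pd.Series(A, index=labels),
        metrics,
        False,
        None,
    )


def ahl_run(
    state: Mapping[str, float],
    w: pd.DataFrame,
    pattern: Mapping[int, Sequence[str]],
    spec: DOCSpec,
    config: HebbianConfig | None = None,
    **kwargs,
) -> HebbianResult:
    """Active Hebbian learning (asynchronous, pattern-driven).

    At each step the position groups of ``pattern`` are visited in key
    order; the activated concepts update their own state (modified
    Kosko + sigmoid) and then their outgoing weights, which may create
    connections absent from the initial matrix.  Termination is checked
    after every position group, so a run can stop mid-pattern.  AHL has
    no default decay: supply ``decay`` or enable ``auto_learn``.
    """
    if config is None:
        config = HebbianConfig(**kwargs)
    if config.decay is None and not config.auto_learn:
        raise ValueError("AHL requires an explicit decay or auto_learn=True")
    A, W, labels = _prep(state, w)
    _validate_docs(spec, labels)
    index = {c: i for i, c in enumerate(labels)}
    groups = [list(pattern[key]) for key in sorted(pattern)]
    for grp in groups:
        for c in grp:
            if c not in index:
                raise ValueError(f"pattern concept {c!r} not in matrix")
    metrics = TerminationMetrics()
    prev_doc = {c: A[index[c]] for c in spec}
    for k in range(config.iterations):
        if config.auto_learn:
            eta = config.b1 * np.exp(-config.lbd1 * k)
            gamma = config.b2 * np.exp(-config.lbd2 * k)
        else:
            eta = config.learning_rate
            gamma = config.decay
        for grp in groups:
            gidx = [index[c] for c in grp]
            for j in gidx:  # asynchronous state updates
                A[j] = transfer(A[j] + A @ W[:, j], "sigmoid", config.l)
            for j in gidx:  # outgoing-edge updates of the activated nodes
                wn = (1.0 - gamma) * W[j, :] + eta * A[j] * (A - W[j, :] * A[j])
                wn[j] = 0.0
                W[j, :] = np.clip(wn, -1.0, 1.0)
            doc_now = {c: A[index[c]] for c in spec}
            stop, f1, f2 = termination_check(
                prev_doc, doc_now, spec, metrics.f1, config.thresh
            )
            metrics.f1.append(f1)
            metrics.f2.append(f2)
            prev_doc = doc_now
            if stop:
                return HebbianResult(
                    pd.DataFrame(W, index=labels, columns=labels),
                    pd.Series(A, index=labels),
                    metrics,
                    True,
                    k,
                )
    return HebbianResult(
        pd.DataFrame(W, index=labels, columns=labels),
        pd.Series(A, index=labels),
        metrics,
        False,
        None,
    )
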