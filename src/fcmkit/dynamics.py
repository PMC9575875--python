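"""Discrete-time simulation of fuzzy cognitive maps.

A fuzzy cognitive map (FCM) is a signed, weighted, directed graph whose
nodes ("concepts") carry an activation value.  The system evolves in
discrete steps: each concept aggregates the weighted activations of its
causal parents and passes the result through a squashing (transfer)
function.  This module implements the three standard inference rules

* ``kosko``     -- ``A_i(t+1) = f( sum_j A_j(t) * w_ji )``
* ``mKosko``    -- modified Kosko, adds the concept's own memory:
  ``A_i(t+1) = f( A_i(t) + sum_j A_j(t) * w_ji )``
* ``rescaled``  -- recenters activations onto [-1, 1] before the sum:
  ``A_i(t+1) = f( (2 A_i(t) - 1) + sum_j (2 A_j(t) - 1) * w_ji )``

and four transfer functions (sigmoid, hyperbolic tangent, bivalent,
trivalent).  Weight matrices follow the row=source / column=target
convention: ``w.loc[j, i]`` is the causal impact of concept *j* on
concept *i*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRANSFER_RANGES",
    "SimulationConfig",
    "SimulationTrace",
    "transfer",
    "infer_step",
    "simulate",
]

#: Range of each transfer function (closed interval or discrete set).
TRANSFER_RANGES = {
    "sigmoid": (0.0, 1.0),
    "tanh": (-1.0, 1.0),
    "bivalent": (0.0, 1.0),
    "trivalent": (-1.0, 1.0),
}

_INFERENCE_METHODS = ("kosko", "mKosko", "rescaled")


@dataclass
class SimulationConfig:
    """Settings for an FCM simulation run.

    Parameters
    ----------
    inference : {"kosko", "mKosko", "rescaled"}
        State-update rule.
    transfer : {"sigmoid", "tanh", "bivalent", "trivalent"}
        Squashing function applied after aggregation.
    l : float
        Steepness of the sigmoid, ``f(x) = 1 / (1 + exp(-l x))``.
        Ignored by the other transfer functions.
    thresh : float
        Convergence threshold: the run stops once every monitored
        concept changes by less than ``thresh`` between two
        consecutive steps.
    iterations : int
        Maximum number of update steps.
    output_concepts : sequence of str, optional
        Concepts monitored for convergence.  ``None`` monitors all.
    """

    inference: str = "mKosko"
    transfer: str = "sigmoid"
    l: float = 1.0
    thresh: float = 0.001
    iterations: int = 50
    output_concepts: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.inference not in _INFERENCE_METHODS:
            raise ValueError(
                f"unknown inference method {self.inference!r}; "
                f"choose from {_INFERENCE_METHODS}"
            )
        if self.transfer not in TRANSFER_RANGES:
            raise ValueError(
                f"unknown transfer function {self.transfer!r}; "
                f"choose from {tuple(TRANSFER_RANGES)}"
            )
        if self.transfer == "sigmoid" and self.l <= 0:
            raise ValueError("sigmoid steepness l must be > 0")
        if self.thresh <= 0:
            raise ValueError("thresh must be > 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class SimulationTrace:
    """Result of :func:`simulate`.

    ``states`` holds one row per state, row 0 being the initial state.
    ``convergence_state`` is the 1-based count of states at the moment
    convergence was detected (the paper-style "converged in the K
    state" number); it equals ``len(states)`` when ``converged``.
    """

    states: pd.DataFrame
    converged: bool
    convergence_state: int | None = None
    monitored: list[str] = field(default_factory=list)

    @property
    def final_state(self) -> pd.Series:
        return self.states.iloc[-1]

    def __len__(self) -> int:
        return len(self.states)


def transfer(x, method: str = "sigmoid", l: float = 1.0):
    """Apply a transfer (squashing) function elementwise.

    ``sigmoid`` maps onto [0,1]; ``tanh`` onto [-1,1]; ``bivalent``
    onto {0,1} with f(0)=0; ``trivalent`` is the sign function.
    """
    x = np.asarray(x, dtype=float)
    if method == "sigmoid":
        if l <= 0:
            raise ValueError("sigmoid steepness l must be > 0")
        out = 1.0 / (1.0 + np.exp(-l * x))
    elif method == "tanh":
        out = np.tanh(x)
    elif method == "bivalent":
        out = np.where(x > 0, 1.0, 0.0)
    elif method == "trivalent":
        out = np.sign(x)
    else:
        raise ValueError(f"unknown transfer function {method!r}")
    return out if out.ndim else float(out)


def _as_series(state, labels: Sequence[str]) -> pd.Series:
    if isinstance(state, pd.Series):
        s = state.astype(float)
    elif isinstance(state, Mapping):
        s = pd.Series({k: float(v) for k, v in state.items()})
    else:
        s = pd.Series(np.asarray(state, dtype=float), index=list(labels))
    if set(s.index) != set(labels):
        raise ValueError(
            f"state labels {sorted(s.index)} do not match matrix labels "
            f"{sorted(labels)}"
        )
    return s.reindex(labels)


def _as_matrix(w) -> pd.DataFrame:
    if isinstance(w, pd.DataFrame):
        m = w.astype(float)
        if list(m.index) != list(m.columns):
            # allow plain integer index when columns are labeled
            if m.shape[0] == m.shape[1]:
                m.index = m.columns
            else:
                raise ValueError("weight matrix must be square")
        return m
    arr = np.asarray(w, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("weight matrix must be square")
    labels = [f"C{i + 1}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=labels, columns=labels)


def infer_step(state, w, config: SimulationConfig) -> pd.Series:
    """Advance the FCM one step.

    Aggregates parent activations per the configured inference rule and
    squashes with the transfer function.  ``state`` may be a dict,
    Series or array; the returned Series is ordered like the matrix.
    """
    wm = _as_matrix(w)
    a = _as_series(state, list(wm.columns)).to_numpy()
    mat = wm.to_numpy()
    if config.inference == "kosko":
        x = a @ mat
    elif config.inference == "mKosko":
        x = a + a @ mat
    else:  # rescaled
        r = 2.0 * a - 1.0
        x = r + r @ mat
    new = transfer(x, config.transfer, config.l)
    return pd.Series(new, index=wm.columns)


def simulate(initial_state, w, config: SimulationConfig | None = None,
             **kwargs) -> SimulationTrace:
    """Run an FCM simulation until convergence or the iteration cap.

    Convergence requires *every* monitored concept to change by less
    than ``config.thresh`` between two consecutive states.  Keyword
    arguments are forwarded to :class:`SimulationConfig` when no config
    object is given.

    Raises
    ------
    FloatingPointError
        If the trajectory leaves the finite range (diverging input).
    """
    if config is None:
        config = SimulationConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a SimulationConfig or keyword options")
    wm = _as_matrix(w)
    labels = list(wm.columns)
    monitored = list(config.output_concepts) if config.output_concepts else labels
    unknown = set(monitored) - set(labels)
    if unknown:
        raise ValueError(f"output_concepts not in matrix: {sorted(unknown)}")

    states = [_as_series(initial_state, labels)]
    converged = False
    conv_state: int | None = None
    for _ in range(config.iterations):
        nxt = infer_step(states[-1], wm, config)
        if not np.isfinite(nxt.to_numpy()).all():
            raise FloatingPointError(
                "non-finite state encountered during simulation"
            )
        states.append(nxt)
        delta = (states[-1][monitored] - states[-2][monitored]).abs().max()
        if delta < config.thresh:
            converged = True
            conv_state = len(states)
            break
    trace = pd.DataFrame(states).reset_index(drop=True)
    return SimulationTrace(
        states=trace,
        converged=converged,
        convergence_state=conv_state,
        monitored=monitored,
    )
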