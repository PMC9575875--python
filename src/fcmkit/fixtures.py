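"""Built-in example systems.

Two small FCMs used throughout the documentation and test suite:

* ``eight_concept`` -- an 8-node map with mixed positive and negative
  causal edges, used for simulation and intervention examples.
* ``water_tank``    -- the classic 5-node water-tank control system
  used in the Hebbian-learning literature, together with its desired
  output concept (DOC) ranges and an activation pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Fixture", "load_fixture"]


@dataclass
class Fixture:
    name: str
    weight_matrix: pd.DataFrame
    initial_state: dict[str, float]
    doc_values: dict[str, list[float]] = field(default_factory=dict)
    activation_pattern: dict[int, list[str]] = field(default_factory=dict)


def _eight_concept() -> Fixture:
    labels = [f"C{i}" for i in range(1, 9)]
    w = np.array(
        [
            [0.0, 0.0, 0.6, 0.9, 0.0, 0.0, 0.0, 0.8],
            [0.1, 0.0, 0.0, 0.0, 0.0, 0.0, 0.2, 0.5],
            [0.0, 0.7, 0.0, 0.0, 0.9, 0.0, 0.4, 0.1],
            [0.4, 0.0, 0.0, 0.0, 0.0, 0.9, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0, 0.0, -0.9, 0.0, 0.3],
            [-0.3, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0, 0.0, 0.8, 0.4, 0.9],
            [0.1, 0.0, 0.0, 0.0, 0.0, 0.1, 0.6, 0.0],
        ]
    )
    init = {"C1": 1.0, "C2": 1.0, "C3": 0.0, "C4": 0.0,
            "C5": 0.0, "C6": 0.0, "C7": 0.0, "C8": 0.0}
    return Fixture(
        name="eight_concept",
        weight_matrix=pd.DataFrame(w, index=labels, columns=labels),
        initial_state=init,
    )


def _water_tank() -> Fixture:
    labels = ["C1", "C2", "C3", "C4", "C5"]
    w = np.array(
        [
            [0.0, -0.4, -0.25, 0.0, 0.3],
            [0.36, 0.0, 0.0, 0.0, 0.0],
            [0.45, 0.0, 0.0, 0.0, 0.0],
            [-0.9, 0.0, 0.0, 0.0, 0.0],
            [0.0, 0.6, 0.0, 0.3, 0.0],
        ]
    )
    init = {"C1": 0.40, "C2": 0.7077, "C3": 0.612, "C4": 0.717, "C5": 0.30}
    return Fixture(
        name="water_tank",
        weight_matrix=pd.DataFrame(w, index=labels, columns=labels),
        initial_state=init,
        doc_values={"C1": [0.68, 0.74], "C5": [0.74, 0.8]},
        activation_pattern={0: ["C1"], 1: ["C2", "C3"], 2: ["C5"], 3: ["C4"]},
    )


_FIXTURES = {"eight_concept": _eight_concept, "water_tank": _water_tank}


def load_fixture(name: str) -> Fixture:
    """Return a fresh copy of a named example system."""
    try:
        return _FIXTURES[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
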