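import numpy as np
import pandas as pd
import pytest

from fcmkit.fuzzy import LinguisticTermSet


@pytest.fixture
def term_set() -> LinguisticTermSet:
    return LinguisticTermSet()


def _table(rows):
    return pd.DataFrame(rows, columns=["source", "target", "term"])


@pytest.fixture
def survey():
    """Synthetic six-expert survey over four concepts.

    Edge (C1, C2) carries the canonical worked distribution: half the
    experts rate "+h", a third "+vh" and a sixth "+m".  The other edges
    cover unanimity, a partially rated edge and an all-"na" edge.
    """
    experts = {}
    c12 = ["+h", "+h", "+h", "+vh", "+vh", "+m"]
    c21 = ["+m"] * 6
    c34 = ["+l", "+l", "+l", "na", "na", "na"]
    for i in range(6):
        rows = [
            ("C1", "C2", c12[i]),
            ("C2", "C1", c21[i]),
            ("C3", "C4", c34[i]),
        ]
        if i < 2:  # only two experts rated this edge
            rows.append(("C4", "C2", "+vl"))
        if True:
            rows.append(("C3", "C1", "na"))
        experts[f"E{i + 1}"] = _table(rows)
    return experts


@pytest.fixture
def inconsistent_survey():
    return {
        "A": _table([("C1", "C2", "+h"), ("C2", "C3", "+l")]),
        "B": _table([("C1", "C2", "-l"), ("C2", "C3", "+vl")]),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
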