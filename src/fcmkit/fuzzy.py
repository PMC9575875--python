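"""Fuzzy-logic primitives for expert-based FCM construction.

Linguistic causal ratings (e.g. "positive high") are mapped onto the
universe of discourse -- by default the interval [-1, 1] sampled at
0.001 -- through membership functions.  An edge's distribution of
endorsed terms then drives a classic Mamdani/Larsen inference pipeline:
each term's membership function is *activated* (implication) at the
proportion of experts endorsing it, the activated functions are
*aggregated* pointwise, and the aggregate is *defuzzified* to a single
crisp weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_TERMS",
    "LinguisticTermSet",
    "MembershipFunction",
    "generate_memberships",
    "implication",
    "aggregate",
    "defuzz",
]

#: The 11-term dictionary commonly used for causal ratings: five grades
#: of negative causality, "na" (no causality), and five positive grades.
#: Values are triangular membership parameters [lower, center, upper].
DEFAULT_TERMS: dict[str, list[float]] = {
    "-vh": [-1, -1, -0.75],
    "-h": [-1, -0.75, -0.50],
    "-m": [-0.75, -0.5, -0.25],
    "-l": [-0.5, -0.25, 0],
    "-vl": [-0.25, 0, 0],
    "na": [-0.001, 0, 0.001],
    "+vl": [0, 0, 0.25],
    "+l": [0, 0.25, 0.50],
    "+m": [0.25, 0.5, 0.75],
    "+h": [0.5, 0.75, 1],
    "+vh": [0.75, 1, 1],
}

_MF_ARITY = {"trimf": 3, "trapmf": 4, "gaussmf": 2}


@dataclass(frozen=True)
class MembershipFunction:
    """A sampled membership function mu(x) on a shared universe grid."""

    term: str
    x: np.ndarray
    mu: np.ndarray

    def __post_init__(self) -> None:
        if len(self.x) != len(self.mu):
            raise ValueError("x and mu must have the same length")
        if np.any(self.mu < -1e-12) or np.any(self.mu > 1 + 1e-12):
            raise ValueError(f"membership values of {self.term!r} outside [0,1]")


@dataclass
class LinguisticTermSet:
    """Ordered linguistic terms with membership parameters.

    Parameters
    ----------
    params : dict
        Term label -> parameter list.  Triangular functions take
        ``[lower, center, upper]``, trapezoidal four abscissae, and
        gaussian ``[mean, sigma]``.
    universe : tuple
        ``(lo, hi, step)`` sampling of the real line; both endpoints
        are included in the grid.
    """

    params: dict[str, list[float]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_TERMS.items()}
    )
    universe: tuple[float, float, float] = (-1.0, 1.0, 0.001)

    def __post_init__(self) -> None:
        lo, hi, step = self.universe
        if not (lo < hi and step > 0):
            raise ValueError("universe must satisfy lo < hi and step > 0")
        for term, p in self.params.items():
            if len(p) == 3 and not (p[0] <= p[1] <= p[2]):
                raise ValueError(
                    f"triangular parameters of {term!r} must be ordered "
                    f"lower <= center <= upper, got {p}"
                )

    @property
    def terms(self) -> list[str]:
        return list(self.params)

    @property
    def grid(self) -> np.ndarray:
        lo, hi, step = self.universe
        n = int(round((hi - lo) / step))
        return lo + step * np.arange(n + 1)

    def center(self, term: str) -> float:
        """Representative (peak) value of a term, used for valence."""
        p = self.params[term]
        if len(p) == 3:  # triangular
            return p[1]
        if len(p) == 2:  # gaussian
            return p[0]
        return 0.5 * (p[1] + p[2])  # trapezoidal plateau midpoint

    def valence(self, term: str) -> int:
        """Sign of a term's center; 0 marks valence-neutral terms."""
        c = self.center(term)
        return 0 if c == 0 else (1 if c > 0 else -1)


def _trimf(x: np.ndarray, p) -> np.ndarray:
    a, b, c = p
    y = np.zeros_like(x)
    if a != b:
        left = (x > a) & (x < b)
        y[left] = (x[left] - a) / (b - a)
    if b != c:
        right = (x > b) & (x < c)
        y[right] = (c - x[right]) / (c - b)
    y[x == b] = 1.0
    return y


def _trapmf(x: np.ndarray, p) -> np.ndarray:
    a, b, c, d = p
    y = np.zeros_like(x)
    if a != b:
        left = (x > a) & (x < b)
        y[left] = (x[left] - a) / (b - a)
    if c != d:
        right = (x > c) & (x < d)
        y[right] = (d - x[right]) / (d - c)
    y[(x >= b) & (x <= c)] = 1.0
    return y


def _gaussmf(x: np.ndarray, p) -> np.ndarray:
    mean, sigma = p
    return np.exp(-((x - mean) ** 2) / (2.0 * sigma**2))


_MF_FUNCS = {"trimf": _trimf, "trapmf": _trapmf, "gaussmf": _gaussmf}


def generate_memberships(
    term_set: LinguisticTermSet, method: str = "trimf"
) -> dict[str, MembershipFunction]:
    """Generate one membership function per term on the shared grid."""
    if method not in _MF_FUNCS:
        raise ValueError(f"unknown membership method {method!r}")
    x = term_set.grid
    out = {}
    for term, p in term_set.params.items():
        if len(p) != _MF_ARITY[method]:
            raise ValueError(
                f"term {term!r} has {len(p)} parameters but method "
                f"{method!r} requires {_MF_ARITY[method]}"
            )
        out[term] = MembershipFunction(term, x, _MF_FUNCS[method](x, p))
    return out


def implication(
    mf: MembershipFunction, weight: float, method: str = "Mamdani"
) -> MembershipFunction:
    """Activate a membership function at an endorsement level.

    Mamdani clips (pointwise minimum with ``weight``); Larsen scales
    (pointwise product).  ``weight`` is the proportion of experts
    endorsing the term and must lie in [0, 1].
    """
    if not 0.0 <= weight <= 1.0:
        raise ValueError(f"implication weight must be in [0,1], got {weight}")
    m = method.lower()
    if m == "mamdani":
        mu = np.minimum(mf.mu, weight)
    elif m == "larsen":
        mu = mf.mu * weight
    else:
        raise ValueError(f"unknown implication method {method!r}")
    return MembershipFunction(mf.term, mf.x, mu)


def aggregate(
    a: MembershipFunction, b: MembershipFunction, method: str = "fMax"
) -> MembershipFunction:
    """Combine two activated membership functions pointwise.

    ``fMax`` is the family maximum; ``algSum`` the algebraic sum
    ``x + y - xy``; ``eSum`` the Einstein sum ``(x+y)/(1+xy)``; and
    ``hSum`` the Hamacher sum ``(x+y-2xy)/(1-xy)``.
    """
    if len(a.x) != len(b.x) or not np.array_equal(a.x, b.x):
        raise ValueError("membership functions live on different grids")
    x, y = a.mu, b.mu
    m = method.lower()
    if m == "fmax":
        mu = np.maximum(x, y)
    elif m == "algsum":
        mu = x + y - x * y
    elif m == "esum":
        mu = (x + y) / (1.0 + x * y)
    elif m == "hsum":
        xy = x * y
        # the operator's singularity at x*y -> 1 has limit 1; evaluating
        # the ratio there would divide catastrophically-cancelled floats
        near_one = xy > 1.0 - 1e-9
        safe = np.where(near_one, 0.5, xy)
        mu = np.where(near_one, np.maximum(x, y),
                      (x + y - 2 * xy) / (1.0 - safe))
    else:
        raise ValueError(f"unknown aggregation method {method!r}")
    label = a.term if a.term == b.term else f"{a.term}|{b.term}"
    return MembershipFunction(label, a.x, np.clip(mu, 0.0, 1.0))


def defuzz(x: np.ndarray, mfx: np.ndarray | MembershipFunction,
           method: str = "centroid") -> float:
    """Collapse an aggregated membership function to a crisp value.

    ``centroid`` is the center of gravity over the sampled grid; the
    maxima-based variants return the mean (``mom``), smallest (``som``)
    or largest (``lom``) abscissa of the argmax set.  An identically
    zero function defuzzifies to 0 (the no-causality convention).
    """
    mu = mfx.mu if isinstance(mfx, MembershipFunction) else np.asarray(mfx, float)
    x = np.asarray(x, float)
    if len(x) != len(mu):
        raise ValueError("grid and membership function differ in length")
    total = mu.sum()
    if total == 0.0:
        return 0.0
    m = method.lower()
    if m == "centroid":
        return float((x * mu).sum() / total)
    peak = x[mu == mu.max()]
    if m == "mom":
        return float(peak.mean())
    if m == "som":
        return float(peak.min())
    if m == "lom":
        return float(peak.max())
    raise ValueError(f"unknown defuzzification method {method!r}")
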