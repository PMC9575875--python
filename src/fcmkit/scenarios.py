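"""What-if intervention analysis on a converged FCM.

The workflow mirrors how intervention studies are run on causal maps:
first :meth:`Intervention.initialize` simulates the untouched system to
its attractor (the *baseline equilibrium*); then named scenarios are
registered and tested.

* A **single-shot** intervention perturbs the settled system once: the
  listed concepts are overridden and the simulation restarts from the
  baseline equilibrium.
* A **continuous** intervention wires a new, permanently clamped
  intervention node into the map whose outgoing weights are
  ``impact x effectiveness``; the augmented system is simulated from
  the baseline equilibrium with the node held at 1.

Results are collected in two tables: ``equilibriums`` (final state per
scenario) and ``comparison`` (percent change versus baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import SimulationConfig, SimulationTrace, simulate

__all__ = ["InterventionSpec", "Intervention"]

_NODE = "intervention"


@dataclass
class InterventionSpec:
    name: str
    kind: str  # "single_shot" | "continuous"
    overrides: dict[str, float] = field(default_factory=dict)
    impact: dict[str, float] = field(default_factory=dict)
    effectiveness: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("single_shot", "continuous"):
            raise ValueError(f"unknown intervention kind {self.kind!r}")
        if not 0.0 <= self.effectiveness <= 1.0:
            raise ValueError("effectiveness must lie in [0, 1]")
        if self.kind == "continuous":
            for v in self.impact.values():
                if not -1.0 <= v <= 1.0:
                    raise ValueError("impact strengths must lie in [-1, 1]")


class Intervention:
    """Scenario manager around a weight matrix and simulation config."""

    def __init__(self) -> None:
        self._w: pd.DataFrame | None = None
        self._config: SimulationConfig | None = None
        self._baseline: SimulationTrace | None = None
        self._specs: dict[str, InterventionSpec] = {}
        self.test_results: dict[str, SimulationTrace] = {}

    # -- baseline ----------------------------------------------------
    def initialize(self, initial_state, weight_matrix: pd.DataFrame,
                   config: SimulationConfig | None = None, **kwargs) -> SimulationTrace:
        """Simulate the baseline and store its final state as reference."""
        if config is None:
            config = SimulationConfig(**kwargs)
        self._w = weight_matrix.astype(float)
        self._config = config
        self._baseline = simulate(initial_state, self._w, config)
        self.test_results = {"baseline": self._baseline}
        self._specs = {}
        return self._baseline

    @property
    def baseline_equilibrium(self) -> pd.Series:
        self._require_init()
        return self._baseline.final_state

    def _require_init(self) -> None:
        if self._baseline is None:
            raise RuntimeError("call initialize() before registering scenarios")

    # -- scenarios ---------------------------------------------------
    def add_intervention(self, name: str, kind: str, *,
                         initial_state: dict[str, float] | None = None,
                         impact: dict[str, float] | None = None,
                         effectiveness: float = 1.0) -> InterventionSpec:
        self._require_init()
        if name in self._specs or name == "baseline":
            raise ValueError(f"intervention name {name!r} already in use")
        spec = InterventionSpec(
            name=name,
            kind=kind,
            overrides=dict(initial_state or {}),
            impact=dict(impact or {}),
            effectiveness=effectiveness,
        )
        known = set(self._w.columns)
        unknown = (set(spec.overrides) | set(spec.impact)) - known
        if unknown:
            raise ValueError(f"unknown concept(s) {sorted(unknown)}")
        self._specs[name] = spec
        return spec

    def augmented_matrix(self, name: str) -> pd.DataFrame:
        """(n+1)x(n+1) matrix with the clamped intervention node appended."""
        spec = self._specs[name]
        if spec.kind != "continuous":
            raise ValueError(f"{name!r} is not a continuous intervention")
        labels = list(self._w.columns)
        aug = pd.DataFrame(
            0.0, index=labels + [_NODE], columns=labels + [_NODE]
        )
        aug.loc[labels, labels] = self._w.to_numpy()
        for concept, strength in spec.impact.items():
            aug.loc[_NODE, concept] = strength * spec.effectiveness
        return aug

    def test_intervention(self, name: str,
                          iterations: int | None = None) -> SimulationTrace:
        """Simulate one scenario from the baseline equilibrium."""
        self._require_init()
        if name not in self._specs:
            raise KeyError(f"unknown intervention {name!r}")
        spec = self._specs[name]
        cfg = self._config
        if iterations is not None:
            cfg = SimulationConfig(
                inference=cfg.inference, transfer=cfg.transfer, l=cfg.l,
                thresh=cfg.thresh, iterations=iterations,
                output_concepts=cfg.output_concepts,
            )
        start = self.baseline_equilibrium.copy()
        if spec.kind == "single_shot":
            for concept, value in spec.overrides.items():
                start[concept] = value
            trace = simulate(start, self._w, cfg)
        else:
            aug = self.augmented_matrix(name)
            labels = list(self._w.columns)
            init = dict(start)
            init[_NODE] = 1.0
            # the clamp is enforced by monitoring only the original
            # concepts and re-pinning the node after every step
            cfg_aug = SimulationConfig(
                inference=cfg.inference, transfer=cfg.transfer, l=cfg.l,
                thresh=cfg.thresh, iterations=cfg.iterations,
                output_concepts=labels,
            )
            trace = _simulate_clamped(init, aug, cfg_aug, clamp={_NODE: 1.0})
            trace.states = trace.states[labels]
        self.test_results[name] = trace
        return trace

    # -- reporting ---------------------------------------------------
    @property
    def equilibriums(self) -> pd.DataFrame:
        """Concepts x scenarios table of final states."""
        self._require_init()
        cols = {}
        for name, trace in self.test_results.items():
            cols[name] = trace.final_state.reindex(self._w.columns)
        return pd.DataFrame(cols)

    @property
    def comparison_table(self) -> pd.DataFrame:
        """Percent change of each scenario equilibrium versus baseline.

        Concepts whose baseline equilibrium is exactly 0 report NaN
        rather than an infinite percent change.
        """
        eq = self.equilibriums
        base = eq["baseline"]
        out = {}
        for name in eq.columns:
            with np.errstate(divide="ignore", invalid="ignore"):
                pct = (eq[name] - base) / base * 100.0
            out[name] = pct.where(base != 0, np.nan)
        table = pd.DataFrame(out)
        table["baseline"] = 0.0
        return table


def _simulate_clamped(initial_state, w, config, clamp) -> SimulationTrace:
    """Simulate while pinning selected concepts after every step."""
    from .dynamics import infer_step, _as_series, _as_matrix

    wm = _as_matrix(w)
    labels = list(wm.columns)
    monitored = list(config.output_concepts) if config.output_concepts else labels
    states = [_as_series(initial_state, labels)]
    for name, value in clamp.items():
        states[0][name] = value
    converged, conv_state = False, None
    for _ in range(config.iterations):
        nxt = infer_step(states[-1], wm, config)
        for name, value in clamp.items():
            nxt[name] = value
        states.append(nxt)
        delta = (states[-1][monitored] - states[-2][monitored]).abs().max()
        if delta < config.thresh:
            converged, conv_state = True, len(states)
            break
    return SimulationTrace(
        states=pd.DataFrame(states).reset_index(drop=True),
        converged=converged,
        convergence_state=conv_state,
        monitored=monitored,
    )
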