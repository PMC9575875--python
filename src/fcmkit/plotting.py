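"""Minimal plotting helpers (simulation traces, scenario equilibria,
feature importances)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_trace", "plot_equilibriums", "plot_importance"]


def plot_trace(trace, ax=None):
    """Line plot of concept activations over simulation steps."""
    if ax is None:
        _, ax = plt.subplots()
    states = trace.states if hasattr(trace, "states") else trace
    for col in states.columns:
        ax.plot(states.index, states[col], label=col)
    ax.set_xlabel("step")
    ax.set_ylabel("activation")
    ax.legend(fontsize="small", ncol=2)
    return ax


def plot_equilibriums(equilibriums: pd.DataFrame, ax=None):
    """Grouped bar chart of scenario equilibria per concept."""
    if ax is None:
        _, ax = plt.subplots()
    equilibriums.plot.bar(ax=ax)
    ax.set_ylabel("equilibrium activation")
    return ax


def plot_importance(importance, feature_names=None, ax=None):
    if ax is None:
        _, ax = plt.subplots()
    names = feature_names or [f"feature {i}" for i in range(len(importance))]
    ax.bar(names, importance)
    ax.set_ylabel("importance")
    return ax
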