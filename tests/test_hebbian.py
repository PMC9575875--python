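"""Hebbian learners: termination logic, water-tank oracles, invariants."""

import numpy as np
import pandas as pd
import pytest

from fcmkit.dynamics import simulate
from fcmkit.fixtures import load_fixture
from fcmkit.hebbian import HebbianConfig, ahl_run, nhl_run, termination_check


@pytest.fixture
def water_tank():
    return load_fixture("water_tank")


# -- termination ----------------------------------------------------------

def test_f1_zero_at_range_midpoint():
    spec = {"C1": [0.68, 0.74]}
    stop, f1, f2 = termination_check({"C1": 0.71}, {"C1": 0.71}, spec, [], 0.002)
    assert f1["C1"] == pytest.approx(0.0, abs=1e-12)


def test_f2_is_consecutive_difference():
    spec = {"C1": [0.6, 0.8]}
    _, _, f2 = termination_check({"C1": 0.70}, {"C1": 0.7005}, spec, [], 0.002)
    assert f2["C1"] == pytest.approx(0.0005, abs=1e-12)


def test_no_stop_when_doc_outside_range():
    spec = {"C1": [0.68, 0.74]}
    history = [{"C1": 0.5}]
    stop, _, _ = termination_check({"C1": 0.60}, {"C1": 0.6001}, spec,
                                   history, 0.002)
    assert not stop


def test_stop_requires_all_three_conditions():
    spec = {"C1": [0.68, 0.74]}
    history = [{"C1": 0.05}]
    stop, _, _ = termination_check({"C1": 0.70}, {"C1": 0.7005}, spec,
                                   history, 0.002)
    assert stop
    # same values but F2 above the threshold
    stop2, _, _ = termination_check({"C1": 0.70}, {"C1": 0.71}, spec,
                                    [{"C1": 0.05}], 0.002)
    assert not stop2


def test_invalid_doc_spec_rejected(water_tank):
    with pytest.raises(ValueError, match="min < max"):
        nhl_run(water_tank.initial_state, water_tank.weight_matrix,
                {"C1": [0.74, 0.68]})
    with pytest.raises(ValueError, match="not a concept"):
        nhl_run(water_tank.initial_state, water_tank.weight_matrix,
                {"C9": [0.1, 0.2]})


# -- NHL ------------------------------------------------------------------

def test_nhl_water_tank_reproduces_reference_run(water_tank):
    res = nhl_run(water_tank.initial_state, water_tank.weight_matrix,
                  water_tank.doc_values,
                  learning_rate=0.01, l=0.98, decay=1.0, iterations=100)
    assert res.converged
    assert res.converged_step == 63
    w = res.weights
    assert w.loc["C1", "C5"] == pytest.approx(0.472687, abs=1e-4)
    assert w.loc["C4", "C1"] == pytest.approx(-0.832174, abs=1e-4)
    assert w.loc["C2", "C1"] == pytest.approx(0.539068, abs=1e-4)
    assert w.loc["C5", "C2"] == pytest.approx(0.710523, abs=1e-4)
    assert w.loc["C1", "C2"] == pytest.approx(-0.200310, abs=1e-4)
    # DOCs ended inside their target ranges
    for c, (lo, hi) in water_tank.doc_values.items():
        assert lo <= res.states[c] <= hi


def test_nhl_zero_learning_rate_is_pure_simulation(water_tank):
    res = nhl_run(water_tank.initial_state, water_tank.weight_matrix,
                  water_tank.doc_values,
                  learning_rate=0.0, decay=1.0, l=0.98, iterations=7)
    pd.testing.assert_frame_equal(res.weights, water_tank.weight_matrix)
    trace = simulate(water_tank.initial_state, water_tank.weight_matrix,
                     inference="mKosko", transfer="sigmoid", l=0.98,
                     thresh=1e-12, iterations=7)
    np.testing.assert_allclose(res.states.to_numpy(),
                               trace.states.iloc[7].to_numpy(), atol=1e-12)


def test_nhl_single_step_matches_hand_computation():
    """Two-concept chain, one iteration, against a scalar transcription
    of the update rule."""
    labels = ["A", "B"]
    w0 = 0.5
    w = pd.DataFrame([[0.0, w0], [0.0, 0.0]], index=labels, columns=labels)
    state = {"A": 0.6, "B": 0.4}
    res = nhl_run(state, w, {"B": [0.1, 0.9]}, learning_rate=0.1, decay=1.0,
                  l=1.0, iterations=1)
    expected_w = 1.0 * w0 + 0.1 * 0.4 * (0.6 - np.sign(w0) * w0 * 0.4)
    assert res.weights.loc["A", "B"] == pytest.approx(expected_w, abs=1e-12)
    a_new = 1 / (1 + np.exp(-(0.6 + 0.0)))
    b_new = 1 / (1 + np.exp(-(0.4 + 0.6 * expected_w)))
    assert res.states["A"] == pytest.approx(a_new, abs=1e-12)
    assert res.states["B"] == pytest.approx(b_new, abs=1e-12)


def test_nhl_preserves_zeros_signs_and_bounds(rng):
    n = 6
    labels = [f"C{i}" for i in range(n)]
    w = rng.uniform(-1, 1, (n, n)) * (rng.random((n, n)) < 0.4)
    np.fill_diagonal(w, 0.0)
    wdf = pd.DataFrame(w, index=labels, columns=labels)
    state = dict(zip(labels, rng.uniform(0.2, 0.8, n)))
    res = nhl_run(state, wdf, {labels[0]: [0.4, 0.6]},
                  learning_rate=0.05, decay=0.99, l=1.0, iterations=40)
    learned = res.weights.to_numpy()
    assert np.all(learned[w == 0] == 0.0)
    nz = w != 0
    # an edge may decay to exactly 0 but can never flip sign
    assert np.all(learned[nz] * np.sign(w[nz]) >= 0.0)
    assert np.all(np.abs(learned) <= 1.0)


def test_nhl_nonconvergence_reported(water_tank):
    res = nhl_run(water_tank.initial_state, water_tank.weight_matrix,
                  water_tank.doc_values,
                  learning_rate=0.01, l=0.98, decay=1.0, iterations=10)
    assert not res.converged and res.converged_step is None
    assert len(res.metrics.f1) == 10


# -- AHL ------------------------------------------------------------------

def test_ahl_water_tank_reproduces_reference_run(water_tank):
    res = ahl_run(water_tank.initial_state, water_tank.weight_matrix,
                  water_tank.activation_pattern, water_tank.doc_values,
                  decay=0.03, learning_rate=0.01, l=1.0, thresh=0.002,
                  iterations=100)
    assert res.converged
    assert res.converged_step == 19
    w = res.weights
    assert w.loc["C5", "C2"] == pytest.approx(0.368913, abs=1e-4)
    assert w.loc["C1", "C5"] == pytest.approx(0.218170, abs=1e-4)
    assert w.loc["C4", "C1"] == pytest.approx(-0.386349, abs=1e-4)
    # AHL grows connections that were absent from the expert matrix
    assert w.loc["C3", "C2"] == pytest.approx(0.069457, abs=1e-4)
    assert np.all(np.diag(w.to_numpy()) == 0.0)


def test_ahl_locality_only_activated_rows_change(water_tank):
    """With a pattern that activates only C1, every other concept's
    outgoing weights and state stay bit-identical."""
    res = ahl_run(water_tank.initial_state, water_tank.weight_matrix,
                  {0: ["C1"]}, water_tank.doc_values,
                  decay=0.03, learning_rate=0.01, l=1.0, iterations=5)
    w0 = water_tank.weight_matrix
    for c in ["C2", "C3", "C4", "C5"]:
        np.testing.assert_array_equal(res.weights.loc[c].to_numpy(),
                                      w0.loc[c].to_numpy())
        assert res.states[c] == water_tank.initial_state[c]
    assert not np.array_equal(res.weights.loc["C1"].to_numpy(),
                              w0.loc["C1"].to_numpy())


def test_ahl_zero_learning_rate_zero_decay_keeps_weights(water_tank):
    res = ahl_run(water_tank.initial_state, water_tank.weight_matrix,
                  water_tank.activation_pattern, water_tank.doc_values,
                  decay=0.0, learning_rate=0.0, l=1.0, iterations=5)
    pd.testing.assert_frame_equal(res.weights, water_tank.weight_matrix)


def test_ahl_requires_decay_or_auto_learn(water_tank):
    with pytest.raises(ValueError, match="decay"):
        ahl_run(water_tank.initial_state, water_tank.weight_matrix,
                water_tank.activation_pattern, water_tank.doc_values,
                learning_rate=0.01)


def test_ahl_auto_learn_schedule_converges(water_tank):
    res = ahl_run(water_tank.initial_state, water_tank.weight_matrix,
                  water_tank.activation_pattern, water_tank.doc_values,
                  auto_learn=True, l=1.0, thresh=0.002, iterations=100)
    assert np.all(np.abs(res.weights.to_numpy()) <= 1.0)


def test_ahl_weights_stay_bounded(rng, water_tank):
    res = ahl_run(water_tank.initial_state, water_tank.weight_matrix,
                  water_tank.activation_pattern, water_tank.doc_values,
                  decay=0.01, learning_rate=0.5, l=1.0, iterations=50)
    assert np.all(np.abs(res.weights.to_numpy()) <= 1.0)


def test_hebbian_config_validation():
    with pytest.raises(ValueError):
        HebbianConfig(learning_rate=-0.1)
    with pytest.raises(ValueError):
        HebbianConfig(thresh=0.0)
    with pytest.raises(ValueError):
        HebbianConfig(decay=1.5)
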