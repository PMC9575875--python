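"""Expert construction: survey IO, consistency, entropy, the build pipeline."""

import json

import numpy as np
import pandas as pd
import pytest

from fcmkit.expert import (
    build,
    check_consistency,
    entropy,
    rating_distribution,
    read_ratings,
)
from fcmkit.fuzzy import DEFAULT_TERMS, LinguisticTermSet


def _write_survey_files(survey, tmp_path):
    rows = []
    for expert, table in survey.items():
        for _, r in table.iterrows():
            rows.append({"expert": expert, **r.to_dict()})
    csv = tmp_path / "survey.csv"
    pd.DataFrame(rows).to_csv(csv, index=False)
    js = tmp_path / "survey.json"
    with open(js, "w") as fh:
        json.dump(
            {e: t.values.tolist() for e, t in survey.items()}, fh
        )
    xlsx = tmp_path / "survey.xlsx"
    with pd.ExcelWriter(xlsx, engine="openpyxl") as writer:
        for expert, table in survey.items():
            table.to_excel(writer, sheet_name=expert, index=False)
    return csv, js, xlsx


def test_read_ratings_all_formats_agree(survey, term_set, tmp_path):
    csv, js, xlsx = _write_survey_files(survey, tmp_path)
    from_csv = read_ratings(csv, term_set)
    from_json = read_ratings(js, term_set)
    from_xlsx = read_ratings(xlsx, term_set)
    assert set(from_csv) == set(from_json) == set(from_xlsx) == set(survey)
    for expert in survey:
        pd.testing.assert_frame_equal(from_csv[expert], from_json[expert])
        pd.testing.assert_frame_equal(from_csv[expert], from_xlsx[expert])


def test_minimal_json_survey(term_set, tmp_path):
    path = tmp_path / "two.json"
    with open(path, "w") as fh:
        json.dump({"e1": [["C1", "C2", "+h"]], "e2": [["C1", "C2", "+h"]]}, fh)
    ratings = read_ratings(path, term_set)
    assert len(ratings) == 2
    assert all(len(t) == 1 for t in ratings.values())


def test_unknown_term_is_named_in_error(term_set, tmp_path):
    path = tmp_path / "bad.json"
    with open(path, "w") as fh:
        json.dump({"e1": [["C1", "C2", "++h"]]}, fh)
    with pytest.raises(ValueError, match=r"\+\+h"):
        read_ratings(path, term_set)


def test_duplicate_edge_rating_rejected(term_set, tmp_path):
    path = tmp_path / "dup.json"
    with open(path, "w") as fh:
        json.dump({"e1": [["C1", "C2", "+h"], ["C1", "C2", "+l"]]}, fh)
    with pytest.raises(ValueError, match="more than once"):
        read_ratings(path, term_set)


def test_missing_file_and_bad_format(term_set, tmp_path):
    with pytest.raises(FileNotFoundError):
        read_ratings(tmp_path / "nope.csv", term_set)
    p = tmp_path / "x.tsv"
    p.write_text("hi")
    with pytest.raises(ValueError, match="tsv"):
        read_ratings(p, term_set)


def test_consistency_flags_opposite_valences(inconsistent_survey, term_set):
    records = check_consistency(inconsistent_survey, term_set)
    edges = {(r["edge_source"], r["edge_target"]) for r in records}
    assert edges == {("C1", "C2")}
    experts = {r["expert_id"] for r in records}
    assert experts == {"A", "B"}


def test_consistency_same_valence_and_neutral_terms_pass(term_set):
    ok = {
        "A": pd.DataFrame([("C1", "C2", "+h"), ("C3", "C4", "na")],
                          columns=["source", "target", "term"]),
        "B": pd.DataFrame([("C1", "C2", "+vl"), ("C3", "C4", "-m")],
                          columns=["source", "target", "term"]),
    }
    # +vl has center 0 (valence-neutral) and na never conflicts
    assert check_consistency(ok, term_set) == []


def test_consistency_report_written(inconsistent_survey, term_set, tmp_path):
    path = tmp_path / "s.json"
    with open(path, "w") as fh:
        json.dump({e: t.values.tolist() for e, t in inconsistent_survey.items()}, fh)
    read_ratings(path, term_set, check_consistency=True)
    report = pd.read_csv(tmp_path / "s_consistency.csv")
    assert set(report.columns) == {"edge_source", "edge_target", "expert_id",
                                   "term", "valence"}
    assert len(report) == 2


def test_entropy_of_survey(survey):
    table = entropy(survey).set_index(["source", "target"])["entropy"]
    assert table[("C2", "C1")] == pytest.approx(0.0, abs=1e-12)  # unanimous
    # worked distribution {1/2, 1/3, 1/6}
    assert table[("C1", "C2")] == pytest.approx(1.459148, abs=1e-6)
    # split half/half over two terms
    assert table[("C3", "C4")] == pytest.approx(1.0, abs=1e-12)
    # partially rated edge: both raters agree
    assert table[("C4", "C2")] == pytest.approx(0.0, abs=1e-12)


def test_entropy_bound_and_relabel_invariance(survey):
    table = entropy(survey).set_index(["source", "target"])["entropy"]
    dist = rating_distribution(survey)
    for (s, t), props in dist.items():
        assert table[(s, t)] <= np.log2(len(props)) + 1e-12
    # relabeling terms leaves entropy untouched (it only sees proportions)
    relabeled = {
        e: t.assign(term=t["term"].map(lambda x: {"+h": "-h", "-h": "+h"}.get(x, x)))
        for e, t in survey.items()
    }
    t2 = entropy(relabeled).set_index(["source", "target"])["entropy"]
    assert t2[("C1", "C2")] == pytest.approx(table[("C1", "C2")], abs=1e-12)


def test_proportions_sum_to_one(survey):
    for props in rating_distribution(survey).values():
        assert sum(props.values()) == pytest.approx(1.0, abs=1e-9)


def _oracle_build(survey, implication="mamdani", aggregation="fmax"):
    """Brute-force reimplementation: np.interp triangles, explicit loops."""
    x = np.arange(-1000, 1001) / 1000.0
    counts = {}
    for table in survey.values():
        for _, r in table.iterrows():
            key = (r["source"], r["target"])
            counts.setdefault(key, []).append(r["term"])
    weights = {}
    for edge, terms in counts.items():
        agg = np.zeros_like(x)
        for term in sorted(set(terms)):
            a, b, c = DEFAULT_TERMS[term]
            xp = [a, b, c] if a < b < c else None
            if xp is None:  # degenerate shoulders
                if a == b:
                    mu = np.where(x <= b, np.where(x >= a, 1.0, 0.0),
                                  np.clip((c - x) / (c - b), 0, 1) * (x <= c))
                else:
                    mu = np.where(x >= b, np.where(x <= c, 1.0, 0.0),
                                  np.clip((x - a) / (b - a), 0, 1) * (x >= a))
            else:
                mu = np.interp(x, [a, b, c], [0.0, 1.0, 0.0])
            p = terms.count(term) / len(terms)
            act = np.minimum(mu, p) if implication == "mamdani" else mu * p
            if aggregation == "fmax":
                agg = np.maximum(agg, act)
            else:  # algebraic sum
                agg = agg + act - agg * act
        weights[edge] = 0.0 if agg.sum() == 0 else float((x * agg).sum() / agg.sum())
    return weights


@pytest.mark.parametrize("impl, agg", [("Mamdani", "fMax"), ("Larsen", "algSum")])
def test_build_matches_bruteforce_oracle(survey, term_set, impl, agg):
    w = build(survey, term_set, impl, agg, "centroid")
    oracle = _oracle_build(survey, impl.lower(), agg.lower())
    for (src, tgt), expected in oracle.items():
        assert w.loc[src, tgt] == pytest.approx(expected, abs=1e-9), (src, tgt)


def test_build_reproduces_worked_example_weight(survey, term_set):
    """Half "+h", a third "+vh", a sixth "+m" under Mamdani/fMax/centroid
    lands near 0.70 (grid-resolution dependent)."""
    w = build(survey, term_set)
    assert w.loc["C1", "C2"] == pytest.approx(0.702032, abs=1e-2)


def test_build_single_expert_vh_near_upper_band(term_set):
    survey = {"e1": pd.DataFrame([("A", "B", "+vh")],
                                 columns=["source", "target", "term"])}
    w = build(survey, term_set)
    # full triangle [0.75, 1, 1]: centroid must sit in its support
    assert 0.75 <= w.loc["A", "B"] <= 1.0


def test_build_all_na_edge_is_zero(term_set):
    survey = {
        "e1": pd.DataFrame([("A", "B", "na")], columns=["source", "target", "term"]),
        "e2": pd.DataFrame([("A", "B", "na")], columns=["source", "target", "term"]),
    }
    w = build(survey, term_set)
    assert w.loc["A", "B"] == pytest.approx(0.0, abs=1e-9)


def test_build_unrated_edges_zero_and_bounded(survey, term_set):
    w = build(survey, term_set)
    assert w.loc["C4", "C3"] == 0.0
    assert (w.abs() <= 1.0).all().all()


def test_build_invariant_to_expert_ordering(survey, term_set):
    w1 = build(survey, term_set)
    reordered = dict(reversed(list(survey.items())))
    w2 = build(reordered, term_set)
    pd.testing.assert_frame_equal(w1, w2)
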