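"""Build FCM weight matrices from expert linguistic surveys.

Experts rate each causal edge (source concept, target concept) with one
linguistic term.  Per edge, the proportion of experts endorsing each
term activates that term's membership function; the activated functions
are aggregated and defuzzified to the crisp weight w_ji.  The module
also provides agreement diagnostics (Shannon entropy of the rating
distribution) and a valence-consistency check.

Ratings are read from CSV (long format: expert, source, target, term),
JSON (expert id -> list of {source, target, term}) or XLSX (one sheet
per expert with source/target/term columns).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fuzzy import (
    LinguisticTermSet,
    aggregate,
    defuzz,
    generate_memberships,
    implication,
)

__all__ = [
    "ExpertRatings",
    "read_ratings",
    "check_consistency",
    "entropy",
    "rating_distribution",
    "build",
]

#: expert id -> table with columns (source, target, term)
ExpertRatings = dict[str, pd.DataFrame]

_COLUMNS = ["source", "target", "term"]


def _validate(ratings: ExpertRatings, term_set: LinguisticTermSet) -> None:
    known = set(term_set.terms)
    for expert, table in ratings.items():
        missing = [c for c in _COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"expert {expert!r} table lacks columns {missing}")
        bad = set(table["term"]) - known
        if bad:
            raise ValueError(
                f"unknown linguistic term(s) {sorted(bad)} for expert {expert!r}"
            )
        dup = table.duplicated(subset=["source", "target"])
        if dup.any():
            pair = table.loc[dup.idxmax(), ["source", "target"]].tolist()
            raise ValueError(
                f"expert {expert!r} rated edge {tuple(pair)} more than once"
            )


def read_ratings(
    path: str | Path,
    term_set: LinguisticTermSet,
    format: str | None = None,
    check_consistency: bool = False,
    report_path: str | Path | None = None,
) -> ExpertRatings:
    """Read per-expert edge ratings from CSV, JSON or XLSX.

    Expert keys are the JSON top-level keys, the XLSX sheet names, or
    the values of the ``expert`` column for CSV.  With
    ``check_consistency`` a valence-conflict report is written next to
    the input (or to ``report_path``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        table = pd.read_csv(path)
        if "expert" not in table.columns:
            raise ValueError("CSV ratings need an 'expert' column")
        ratings = {
            str(expert): sub[_COLUMNS].reset_index(drop=True)
            for expert, sub in table.groupby("expert", sort=False)
        }
    elif fmt == "json":
        with open(path) as fh:
            raw = json.load(fh)
        ratings = {
            str(expert): pd.DataFrame(rows, columns=_COLUMNS)
            for expert, rows in raw.items()
        }
    elif fmt == "xlsx":
        sheets = pd.read_excel(path, sheet_name=None, engine="openpyxl")
        ratings = {
            str(name): sheet[_COLUMNS].reset_index(drop=True)
            for name, sheet in sheets.items()
        }
    else:
        raise ValueError(f"unsupported ratings format {fmt!r}")
    _validate(ratings, term_set)
    if check_consistency:
        records = globals()["check_consistency"](ratings, term_set)
        report = pd.DataFrame(
            records,
            columns=["edge_source", "edge_target", "expert_id", "term", "valence"],
        )
        out = Path(report_path) if report_path else path.with_name(
            path.stem + "_consistency.csv"
        )
        report.to_csv(out, index=False)
    return ratings


def check_consistency(
    ratings: ExpertRatings, term_set: LinguisticTermSet
) -> list[dict]:
    """Find edges rated with conflicting valence.

    Returns one record per (expert, term) participating in an edge for
    which at least one expert endorsed a positive term and another a
    negative one.  Valence-neutral terms (center 0, e.g. "na") never
    trigger conflicts.  An empty list means the survey is consistent.
    """
    if not ratings:
        raise ValueError("ratings are empty")
    per_edge: dict[tuple, list[tuple]] = {}
    for expert, table in ratings.items():
        for _, row in table.iterrows():
            per_edge.setdefault((row["source"], row["target"]), []).append(
                (expert, row["term"], term_set.valence(row["term"]))
            )
    records = []
    for (src, tgt), entries in per_edge.items():
        signs = {v for _, _, v in entries if v != 0}
        if len(signs) == 2:
            for expert, term, val in entries:
                if val != 0:
                    records.append(
                        {
                            "edge_source": src,
                            "edge_target": tgt,
                            "expert_id": expert,
                            "term": term,
                            "valence": val,
                        }
                    )
    return records


def rating_distribution(ratings: ExpertRatings) -> dict[tuple, dict[str, float]]:
    """Per-edge proportion of experts endorsing each term.

    Experts who did not rate an edge are excluded from that edge's
    denominator, so the proportions of rated terms sum to 1.
    """
    counts: dict[tuple, dict[str, int]] = {}
    for table in ratings.values():
        for _, row in table.iterrows():
            edge = (row["source"], row["target"])
            counts.setdefault(edge, {})
            counts[edge][row["term"]] = counts[edge].get(row["term"], 0) + 1
    return {
        edge: {t: c / sum(cnt.values()) for t, c in cnt.items()}
        for edge, cnt in counts.items()
    }


def entropy(ratings: ExpertRatings) -> pd.DataFrame:
    """Shannon entropy R = -sum p_i log2 p_i of each edge's ratings.

    R is 0 when all experts agree and grows with disagreement, bounded
    by log2 of the number of endorsed terms.
    """
    dist = rating_distribution(ratings)
    rows = [
        {
            "source": src,
            "target": tgt,
            "entropy": float(-sum(p * np.log2(p) for p in props.values() if p > 0)),
        }
        for (src, tgt), props in dist.items()
    ]
    return pd.DataFrame(rows, columns=["source", "target", "entropy"])


def build(
    ratings: ExpertRatings,
    term_set: LinguisticTermSet,
    implication_method: str = "Mamdani",
    aggregation_method: str = "fMax",
    defuzz_method: str = "centroid",
    membership_method: str = "trimf",
    concepts: list[str] | None = None,
) -> pd.DataFrame:
    """Run the four-step fuzzy pipeline for every rated edge.

    Returns the weight matrix as a DataFrame (rows = source concepts,
    columns = target concepts); unrated edges are 0.  The expert
    ordering does not influence the result, only the per-edge rating
    distribution does.
    """
    _validate(ratings, term_set)
    mfs = generate_memberships(term_set, membership_method)
    dist = rating_distribution(ratings)
    if concepts is None:
        names: list[str] = []
        for src, tgt in dist:
            for c in (src, tgt):
                if c not in names:
                    names.append(c)
        concepts = sorted(names)
    w = pd.DataFrame(0.0, index=concepts, columns=concepts)
    for (src, tgt), props in dist.items():
        activated = [
            implication(mfs[t], p, implication_method)
            for t, p in ((t, props[t]) for t in term_set.terms if t in props)
        ]
        agg = activated[0]
        for mf in activated[1:]:
            agg = aggregate(agg, mf, aggregation_method)
        w.loc[src, tgt] = defuzz(agg.x, agg, defuzz_method)
    return w
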