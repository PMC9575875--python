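"""File IO: format-dispatching reader registry and matrix/state helpers.

The registry maps file extensions to reader callables so new formats
can be plugged in without touching calling code::

    from fcmkit.io import register_reader, get_reader
    register_reader("txt", my_txt_reader)
    ratings = get_reader("txt")(path, term_set=ts)
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Callable

import pandas as pd

from . import expert

__all__ = [
    "register_reader",
    "get_reader",
    "supported_formats",
    "read_matrix",
    "write_matrix",
    "read_state",
    "write_state",
]

_READERS: dict[str, Callable] = {}


def register_reader(extension: str, reader: Callable) -> None:
    """Register (or replace) the reader for a file extension."""
    if not extension:
        raise ValueError("extension must be a nonempty string")
    _READERS[extension.lstrip(".").lower()] = reader


def get_reader(extension: str) -> Callable:
    ext = extension.lstrip(".").lower()
    if ext not in _READERS:
        raise KeyError(
            f"no reader registered for {extension!r}; supported formats: "
            f"{supported_formats()}"
        )
    return _READERS[ext]


def supported_formats() -> list[str]:
    return sorted(_READERS)


for _ext in ("csv", "json", "xlsx"):
    register_reader(
        _ext,
        lambda path, term_set, _f=_ext, **kw: expert.read_ratings(
            path, term_set, format=_f, **kw
        ),
    )


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Weight matrix CSV with concept labels as header and index."""
    m = pd.read_csv(path, index_col=0)
    m.index = m.index.astype(str)
    m.columns = m.columns.astype(str)
    return m.astype(float)


def write_matrix(w: pd.DataFrame, path: str | Path) -> None:
    w.to_csv(path)


def read_state(path: str | Path) -> dict[str, float]:
    """Initial state from JSON ({concept: value}) or two-column CSV."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            return {str(k): float(v) for k, v in json.load(fh).items()}
    table = pd.read_csv(path)
    return dict(zip(table.iloc[:, 0].astype(str), table.iloc[:, 1].astype(float)))


def write_state(state, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({k: float(v) for k, v in dict(state).items()}, fh, indent=1)
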