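"""CSV (and optional XLSX) interchange for trial tables and summary curves.

Trial tables travel as RFC-4180 CSV with a header row and columns
``trial_id, n_left, n_right``; curves as ``x_mean_n, y, spread, window``.
XLSX import exists only so a spreadsheet of the same three columns can be
read directly; all output is CSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .analysis import CurvePoint, TrialTable
from .stats import EscapeCount

__all__ = ["read_trial_table", "write_trial_table", "write_curve", "read_curve"]

_TRIAL_COLUMNS = ["trial_id", "n_left", "n_right"]


def _table_from_frame(df: pd.DataFrame, source: str) -> TrialTable:
    missing = [c for c in _TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing column(s) {missing}")
    trials = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            n_left, n_right = row.n_left, row.n_right
            for v in (n_left, n_right):
                if float(v) != int(v):
                    raise ValueError(f"non-integer count {v!r}")
            count = EscapeCount(int(n_left), int(n_right))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{source}: bad trial in data row {i + 1}: {exc}") from exc
        trials.append((str(row.trial_id), count))
    return TrialTable(trials)


def read_trial_table(path: str | Path, fmt: str | None = None) -> TrialTable:
    """Read a trial table from CSV or XLSX (format inferred from the suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if fmt == "csv":
        df = pd.read_csv(path)
    elif fmt == "xlsx":
        df = pd.read_excel(path)
    else:
        raise ValueError(f"unknown trial-table format {fmt!r}")
    return _table_from_frame(df, str(path))


def write_trial_table(table: TrialTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, index=False)


def write_curve(points: Iterable[CurvePoint], path: str | Path) -> None:
    df = pd.DataFrame(
        [(p.x, p.y, p.spread, p.window_size) for p in points],
        columns=["x_mean_n", "y", "spread", "window"],
    )
    df.to_csv(path, index=False)


def read_curve(path: str | Path) -> list[CurvePoint]:
    df = pd.read_csv(path)
    return [
        CurvePoint(float(r.x_mean_n), float(r.y), float(r.spread), int(r.window))
        for r in df.itertuples(index=False)
    ]
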