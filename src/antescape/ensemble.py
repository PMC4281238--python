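"""Glue between simulator run tables and the escape statistics.

Both simulators emit one row per run with left/right counts; these helpers
compute per-run collective asymmetry and ensemble summaries, and convert a
run table into a TrialTable so the windowed-curve machinery applies to
simulated data exactly as to experimental data.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
import pandas as pd

from .analysis import TrialTable
from .stats import EscapeCount, collective_asymmetry, random_difference_mean

__all__ = ["EnsembleSummary", "delta_c_of_runs", "summarise_runs", "runs_to_trial_table"]


class EnsembleSummary(NamedTuple):
    mean_delta_c: float
    se: float
    runs_used: int


def _usable(df: pd.DataFrame, include_truncated: bool) -> pd.DataFrame:
    keep = df.n_escaped > 0
    if not include_truncated:
        keep &= ~df.truncated
    return df[keep]


def delta_c_of_runs(df: pd.DataFrame, include_truncated: bool = False) -> np.ndarray:
    """Per-run collective asymmetry; truncated or zero-escape runs dropped.

    The null mean is cached per distinct N, so large homogeneous ensembles
    cost one exact binomial sum each.
    """
    df = _usable(df, include_truncated)
    null_mean = {n: random_difference_mean(int(n)) for n in df.n_escaped.unique()}
    diff = 100.0 * (df.n_left - df.n_right).abs() / df.n_escaped
    return (diff - df.n_escaped.map(null_mean)).to_numpy(dtype=float)


def summarise_runs(df: pd.DataFrame, include_truncated: bool = False) -> EnsembleSummary:
    """Ensemble mean collective asymmetry with its standard error."""
    dc = delta_c_of_runs(df, include_truncated)
    if len(dc) == 0:
        return EnsembleSummary(float("nan"), float("nan"), 0)
    se = float(dc.std(ddof=1) / math.sqrt(len(dc))) if len(dc) > 1 else float("nan")
    return EnsembleSummary(float(dc.mean()), se, len(dc))


def runs_to_trial_table(
    df: pd.DataFrame, include_truncated: bool = False, prefix: str = "run"
) -> TrialTable:
    """Treat each usable run as one trial, keyed by its run_id."""
    df = _usable(df, include_truncated)
    trials = [
        (f"{prefix}{int(r.run_id):06d}", EscapeCount(int(r.n_left), int(r.n_right)))
        for r in df.itertuples(index=False)
    ]
    return TrialTable(trials)
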