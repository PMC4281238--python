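"""Summaries of a table of escape trials.

The experimental design cannot fix the group size N: each repetition escapes
however many ants it escapes.  The density dependence of the collective
asymmetry is therefore estimated by sorting trials by N and sliding a
fixed-width window across them, yielding a moving-average curve of the
statistic with a standard-error band, plus a windowed-SD curve for the
fluctuation and simple left/right majority counts as a bias check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, NamedTuple

import numpy as np
import pandas as pd

from .stats import EscapeCount, collective_asymmetry

__all__ = [
    "TrialTable",
    "CurvePoint",
    "SignCounts",
    "sign_counts",
    "moving_average_curve",
    "sd_curve",
]


@dataclass
class TrialTable:
    """Ordered collection of (trial_id, EscapeCount) pairs with unique ids."""

    trials: list[tuple[str, EscapeCount]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [tid for tid, _ in self.trials]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(t for t in ids if t in seen or seen.add(t))
            raise ValueError(f"duplicate trial_id {dup!r}")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[tuple[str, EscapeCount]]:
        return iter(self.trials)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialTable):
            return NotImplemented
        return self.trials == other.trials

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(tid, c.n_left, c.n_right) for tid, c in self.trials],
            columns=["trial_id", "n_left", "n_right"],
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TrialTable":
        trials = [
            (str(row.trial_id), EscapeCount(int(row.n_left), int(row.n_right)))
            for row in df.itertuples(index=False)
        ]
        return cls(trials)


@dataclass(frozen=True)
class CurvePoint:
    """One point of a windowed summary curve.

    ``x`` is the mean total-escaped N in the window, ``y`` the windowed
    statistic, ``spread`` its dispersion (SEM for the moving average, unused
    for the SD curve).
    """

    x: float
    y: float
    spread: float
    window_size: int


class SignCounts(NamedTuple):
    left_majority: int
    right_majority: int
    tie: int


def sign_counts(table: TrialTable) -> SignCounts:
    """Count trials with a left majority, a right majority, and exact ties."""
    if len(table) == 0:
        raise ValueError("trial table is empty")
    left = sum(1 for _, c in table if c.n_left > c.n_right)
    right = sum(1 for _, c in table if c.n_left < c.n_right)
    tie = len(table) - left - right
    return SignCounts(left, right, tie)


def _sorted_stats(
    table: TrialTable, statistic: Callable[[EscapeCount], float]
) -> tuple[np.ndarray, np.ndarray]:
    """Trials sorted ascending by N, ties broken by trial_id for stable output."""
    ordered = sorted(table, key=lambda t: (t[1].n, t[0]))
    ns = np.array([c.n for _, c in ordered], dtype=float)
    ys = np.array([statistic(c) for _, c in ordered], dtype=float)
    return ns, ys


def _check_window(window: int, n_trials: int) -> int:
    if not isinstance(window, (int, np.integer)) or isinstance(window, bool):
        raise ValueError(f"window must be an integer, got {window!r}")
    if window < 2:
        raise ValueError(f"window must be >= 2, got {window}")
    if window > n_trials:
        raise ValueError(f"window {window} exceeds the {n_trials} trials available")
    return int(window)


def moving_average_curve(
    table: TrialTable,
    statistic: Callable[[EscapeCount], float] = collective_asymmetry,
    window: int = 31,
) -> list[CurvePoint]:
    """Moving average of a per-trial statistic over N-sorted trials.

    Only full windows are emitted, so the curve has ``len(table) - window + 1``
    points; ``spread`` is the standard error of the mean (sample SD with
    window-1 denominator, over sqrt(window)).
    """
    window = _check_window(window, len(table))
    ns, ys = _sorted_stats(table, statistic)
    nwin = np.lib.stride_tricks.sliding_window_view(ns, window)
    ywin = np.lib.stride_tricks.sliding_window_view(ys, window)
    x = nwin.mean(axis=1)
    y = ywin.mean(axis=1)
    sem = ywin.std(axis=1, ddof=1) / np.sqrt(window)
    return [
        CurvePoint(float(xi), float(yi), float(si), window)
        for xi, yi, si in zip(x, y, sem)
    ]


def sd_curve(
    table: TrialTable,
    window: int,
    statistic: Callable[[EscapeCount], float] = collective_asymmetry,
) -> list[CurvePoint]:
    """Windowed sample SD of the statistic: the fluctuation of the asymmetry."""
    window = _check_window(window, len(table))
    ns, ys = _sorted_stats(table, statistic)
    nwin = np.lib.stride_tricks.sliding_window_view(ns, window)
    ywin = np.lib.stride_tricks.sliding_window_view(ys, window)
    x = nwin.mean(axis=1)
    y = ywin.std(axis=1, ddof=1)
    return [CurvePoint(float(xi), float(yi), 0.0, window) for xi, yi in zip(x, y)]
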