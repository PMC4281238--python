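"""Synthetic trial tables shaped like the two-exit escape experiment.

The experimental dataset is 291 repetitions with total escape counts between
6 and 269.  This module draws tables of that shape under a controllable
left/right law:

* ``rho = 0`` — every ant chooses a door independently at fair-coin odds,
  the null the collective-asymmetry correction is built against;
* ``rho > 0`` — a per-trial door preference p ~ Beta(a, a) with
  a = (1 - rho)/(2 rho) is drawn first, then the left count is
  Binomial(N, p).  Marginally this is the symmetric beta-binomial with
  intra-class correlation rho: left and right stay exchangeable (no hidden
  side bias) but the split is over-dispersed, the statistical signature of
  collective escape.

A ``rho_profile`` mapping N to rho produces density-dependent correlation,
e.g. a profile peaked at intermediate N yields the rise-then-fall asymmetry
curve, for end-to-end pipeline checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .analysis import TrialTable
from .stats import EscapeCount

__all__ = [
    "SyntheticConfig",
    "generate_trials",
    "generate_rise_fall_table",
    "peaked_rho_profile",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Shape and law of a synthetic trial table."""

    n_trials: int = 291
    n_range: tuple[int, int] = (6, 269)
    n_distribution: str = "uniform"  # or "log-uniform"
    rho: float = 0.0
    rho_profile: Callable[[int], float] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError(f"n_trials must be >= 1, got {self.n_trials}")
        lo, hi = self.n_range
        if lo < 1 or hi < lo:
            raise ValueError(f"n_range must be an interval within [1, inf), got {self.n_range}")
        if self.n_distribution not in ("uniform", "log-uniform"):
            raise ValueError(f"unknown n_distribution {self.n_distribution!r}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")


def _draw_n(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.n_range
    if config.n_distribution == "uniform":
        return rng.integers(lo, hi + 1, size=config.n_trials)
    logs = rng.uniform(np.log(lo), np.log(hi + 1), size=config.n_trials)
    return np.minimum(np.exp(logs).astype(np.int64), hi)


def _draw_left(n: int, rho: float, rng: np.random.Generator) -> int:
    if rho == 0.0:
        return int(rng.binomial(n, 0.5))
    a = (1.0 - rho) / (2.0 * rho)
    p = rng.beta(a, a)
    return int(rng.binomial(n, p))


def generate_trials(config: SyntheticConfig, rng: np.random.Generator | None = None) -> TrialTable:
    """Draw a trial table; deterministic for a given seed.

    Per trial: N from the configured size distribution, then the left count
    from the fair binomial (rho = 0) or the symmetric beta-binomial compound
    (rho > 0, or rho_profile(N) when a profile is set).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ns = _draw_n(config, rng)
    trials = []
    for i, n in enumerate(ns):
        n = int(n)
        rho = config.rho_profile(n) if config.rho_profile is not None else config.rho
        if not 0.0 <= rho < 1.0:
            raise ValueError(f"rho_profile({n}) = {rho} outside [0, 1)")
        n_left = _draw_left(n, float(rho), rng)
        trials.append((f"synth{i:04d}", EscapeCount(n_left, n - n_left)))
    return TrialTable(trials)


def generate_rise_fall_table(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> TrialTable:
    """Trial table whose windowed asymmetry curve is non-monotone in N.

    Requires a rho_profile (typically peaked at intermediate N); everything
    else behaves as generate_trials.
    """
    if config.rho_profile is None:
        raise ValueError("generate_rise_fall_table requires config.rho_profile")
    return generate_trials(config, rng)


def peaked_rho_profile(
    center: float = 60.0, width: float = 40.0, rho_max: float = 0.3
) -> Callable[[int], float]:
    """Gaussian-bump correlation profile rho(N), peaking at ``center``.

    A convenient source of rise-then-fall tables: correlation (hence excess
    asymmetry) is strongest near the centre and fades toward both ends of the
    N range.
    """
    if not 0.0 < rho_max < 1.0:
        raise ValueError(f"rho_max must be in (0, 1), got {rho_max}")

    def profile(n: int) -> float:
        return rho_max * float(np.exp(-0.5 * ((n - center) / width) ** 2))

    return profile
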