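"""Exact statistics of two-exit escape under the fair-coin null.

A group of ``n`` independent escapers, each leaving through the left or the
right exit with probability 1/2, still produces a non-zero *percentage
difference in door use*

    Delta = 100 * |L - R| / n ,

because ``|L - R|`` follows a folded binomial law.  This module computes that
null law exactly: the expected difference ``E[Delta]``, its standard
deviation, and the *collective asymmetry*

    Delta_C = Delta_observed - E[Delta | n] ,

which removes the randomness-induced part so that genuinely collective escape
shows up as a positive excess while independent escapers average to zero.

All percentages are on the 0-100 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "EscapeCount",
    "NullMoments",
    "percentage_difference",
    "random_difference_mean",
    "random_difference_sd",
    "collective_asymmetry",
    "null_distribution",
    "null_moments",
]

_LOG2 = math.log(2.0)


@dataclass(frozen=True)
class EscapeCount:
    """Outcome of one escape repetition: ants out the left and right exits."""

    n_left: int
    n_right: int

    def __post_init__(self) -> None:
        for name in ("n_left", "n_right"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise ValueError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.n_left + self.n_right < 1:
            raise ValueError("at least one ant must have escaped (N >= 1)")

    @property
    def n(self) -> int:
        """Total number of escaped ants."""
        return int(self.n_left) + int(self.n_right)


@dataclass(frozen=True)
class NullMoments:
    """Fair-coin null mean and SD of the percentage difference at group size n."""

    n: int
    mean_difference: float
    sd_difference: float


def _validate_n(n: int) -> int:
    if not isinstance(n, (int, np.integer)) or isinstance(n, bool):
        raise ValueError(f"group size must be an integer, got {n!r}")
    if n < 1:
        raise ValueError(f"group size must be >= 1, got {n}")
    return int(n)


def percentage_difference(count: EscapeCount) -> float:
    """Percentage difference in door use, 100*|L-R|/N, in [0, 100]."""
    return 100.0 * abs(count.n_left - count.n_right) / count.n


def _null_pk_dk(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Binomial(n, 1/2) probabilities P_k and differences Delta_k for k=0..n.

    Log-domain binomial coefficients keep the terms finite up to n far beyond
    1000, where C(n, k) itself overflows a double.
    """
    k = np.arange(n + 1)
    log_p = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1) - n * _LOG2
    delta = 100.0 * np.abs(2 * k - n) / n
    return np.exp(log_p), delta


def random_difference_mean(n: int) -> float:
    """Exact E[100*|L-R|/n] for n independent fair-coin escapers.

    Evaluates the full binomial sum sum_k P_k * Delta_k, accumulating terms in
    descending probability order so that tiny tail terms are not swamped.
    """
    n = _validate_n(n)
    p, delta = _null_pk_dk(n)
    order = np.argsort(p)[::-1]
    return float(np.sum(p[order] * delta[order]))


def random_difference_sd(n: int) -> float:
    """Exact null SD of the percentage difference.

    Uses E[Delta^2] = 10^4 * E[(2X-n)^2] / n^2 = 10^4 / n, since X is
    Binomial(n, 1/2) with Var(X) = n/4 and E[2X-n] = 0.
    """
    n = _validate_n(n)
    mean = random_difference_mean(n)
    var = 1.0e4 / n - mean * mean
    # n=1 gives exactly 0; guard the float residue.
    return math.sqrt(max(var, 0.0))


def collective_asymmetry(count: EscapeCount) -> float:
    """Observed percentage difference minus its fair-coin null expectation.

    Negative values mean the split was more even than chance would produce.
    """
    return percentage_difference(count) - random_difference_mean(count.n)


def null_distribution(n: int) -> list[tuple[float, float]]:
    """Null law of the percentage difference: (value, probability) pairs.

    Probabilities of left-counts sharing the same |2k-n| are aggregated, so
    the support has about n/2 + 1 points, sorted ascending by value.
    """
    n = _validate_n(n)
    p, delta = _null_pk_dk(n)
    agg: dict[float, float] = {}
    for d, q in zip(delta, p):
        agg[float(d)] = agg.get(float(d), 0.0) + float(q)
    return sorted(agg.items())


def null_moments(n: int) -> NullMoments:
    """Bundle mean and SD of the null difference at group size ``n``."""
    n = _validate_n(n)
    return NullMoments(
        n=n,
        mean_difference=random_difference_mean(n),
        sd_difference=random_difference_sd(n),
    )
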