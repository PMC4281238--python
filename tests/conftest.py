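import numpy as np
import pytest
from hypothesis import settings

from antescape.analysis import TrialTable
from antescape.stats import EscapeCount

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


def enumeration_null(n: int) -> tuple[float, float]:
    """Brute-force fair-coin null: mean and SD of 100*|L-R|/n over all 2^n
    equiprobable left/right assignments, via popcounts.  Independent of the
    binomial-sum implementation it checks."""
    ks = np.bitwise_count(np.arange(2**n, dtype=np.uint64)).astype(float)
    d = 100.0 * np.abs(2 * ks - n) / n
    return float(d.mean()), float(d.std())


def table_of(counts, prefix="t") -> TrialTable:
    return TrialTable([(f"{prefix}{i}", EscapeCount(l, r)) for i, (l, r) in enumerate(counts)])


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
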