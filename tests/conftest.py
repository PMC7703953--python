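import numpy as np
import pytest

from regimeshift import HazardPrior, TimeSeries


@pytest.fixture
def hazard25():
    return HazardPrior(25.0)


def make_two_regime_series(
    seed: int,
    n1: int = 30,
    n2: int = 30,
    mu1: float = 0.0,
    mu2: float = 3.0,
    s1: float = 1.0,
    s2: float = 1.0,
) -> TimeSeries:
    """Piecewise-Gaussian fixture with a change point at index n1."""
    rng = np.random.default_rng(seed)
    vals = np.concatenate([rng.normal(mu1, s1, n1), rng.normal(mu2, s2, n2)])
    return TimeSeries(np.arange(n1 + n2), vals, label="two-regime")


def total_variation_rows(post_a, post_b) -> np.ndarray:
    """Per-step TV distance between two run-length posteriors."""
    assert len(post_a) == len(post_b)
    out = []
    for t in range(len(post_a)):
        d1 = np.zeros(t + 1)
        d1[post_a.support[t]] = post_a.probs[t]
        d2 = np.zeros(t + 1)
        d2[post_b.support[t]] = post_b.probs[t]
        out.append(0.5 * np.abs(d1 - d2).sum())
    return np.array(out)
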