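import numpy as np
import pytest

from survcutpoint import SurvivalSample


@pytest.fixture
def four_record_sample() -> SurvivalSample:
    """Two diseased subjects with high markers, two disease-free with low/mid
    markers; no subject censored before tau = 1."""
    return SurvivalSample(
        marker=np.array([0.5, 1.5, 2.0, 1.0]),
        time=np.array([2.0, 0.5, 0.4, 3.0]),
        event=np.array([1, 1, 1, 0]),
    )


def make_sample(marker, time, event) -> SurvivalSample:
    return SurvivalSample(np.asarray(marker, float), np.asarray(time, float), np.asarray(event))


def random_uncensored_before_tau(rng: np.random.Generator, tau: float) -> SurvivalSample:
    """Random sample in which every subject with T <= tau has an observed event
    (censoring may only occur after tau)."""
    n = int(rng.integers(20, 61))
    marker = np.round(rng.normal(size=n) + rng.exponential(size=n), 1)  # ties likely
    time = rng.exponential(scale=0.5, size=n)
    event = np.where(time <= tau, 1, rng.integers(0, 2, size=n)).astype(int)
    # guarantee at least one event before tau and one survivor past tau
    time[0], event[0] = tau / 2, 1
    time[1], event[1] = tau * 2, 1
    return SurvivalSample(marker, time, event)
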