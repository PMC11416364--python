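import numpy as np
import pytest

from pksymreg.pk_model import DosingProfile, PKRates
from pksymreg.synthetic_data import CohortConfig, generate_dataset, sample_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rates(rng, spread=1.0):
    """Physiologically scaled random PKRates."""
    base = np.array([5e-3, 2e-2, 8e-3, 1e-2, 3e-3, 10.0])
    jitter = np.exp(rng.normal(0.0, 0.4 * spread, size=6))
    return PKRates.from_array(base * jitter)


def random_dosing(rng, n_events=4, horizon=3000.0):
    times = np.sort(rng.uniform(0.0, horizon * 0.6, size=n_events))
    times[0] = 0.0
    while np.any(np.diff(times) <= 0):
        times = np.sort(rng.uniform(0.0, horizon * 0.6, size=n_events))
        times[0] = 0.0
    rates = rng.uniform(0.0, 300.0, size=n_events)
    return DosingProfile(event_times=times, rates=rates)


@pytest.fixture
def small_cohort_dataset():
    """20 individuals, published-model truth, sigma=0.15."""
    cfg = CohortConfig(
        n_individuals=20, noise_sigma=0.15, seed=7,
        n_obs_infusion=6, n_obs_decay=3,
    )
    return generate_dataset(sample_cohort(cfg), cfg=cfg)


@pytest.fixture
def noise_free_dataset():
    cfg = CohortConfig(
        n_individuals=12, noise_sigma=0.0, seed=5,
        n_obs_infusion=6, n_obs_decay=3,
    )
    return generate_dataset(sample_cohort(cfg), cfg=cfg)
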