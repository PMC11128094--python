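import logging

import numpy as np
import pytest

from rtfbayes import RunConfig, SyntheticSpec, TimeSeriesDataset, generate_dataset

# ground truth used across fitting tests: a sharp transient peak on a slow
# sustained rise, sampled densely early where the peak lives
PEAKED_THETA = dict(
    Asus=1.0, t1=2.0, Atrans=2.0, t11=0.2, t2=0.6, Tshift=-2.0, p0=0.5, Trange=10.0
)
PEAKED_TIMES = np.array([0.0, 0.15, 0.4, 0.8, 1.5, 2.5, 4.0, 6.0, 8.0, 10.0])


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings(caplog):
    caplog.set_level(logging.ERROR, logger="rtfbayes.inference")


@pytest.fixture
def peaked_dataset() -> tuple[TimeSeriesDataset, dict]:
    spec = SyntheticSpec(
        params=PEAKED_THETA,
        times=PEAKED_TIMES,
        n_replicates=5,
        sigma=0.05,
        seed=9,
    )
    return generate_dataset(spec)


@pytest.fixture
def quick_config() -> RunConfig:
    return RunConfig(seed=17, chain_length=5000, n_chains=1)


def make_dataset(rng: np.random.Generator, T: int = 5, N: int = 3) -> TimeSeriesDataset:
    """Random small replicate dataset for likelihood/percentile oracles."""
    times = np.repeat(np.sort(rng.uniform(0, 10, T)), N)
    values = rng.normal(0, 1, T * N)
    reps = np.tile(np.arange(N).astype(str), T)
    return TimeSeriesDataset("c", "o", times, reps, values)
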