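"""Shared fixtures: small random and simulated groups built at test time."""

import numpy as np
import pytest

from gtrca.epochs import EpochSet, GroupDataset
from gtrca.simulate import SimulationSpec, build_dataset2


def random_epochs(
    rng, n_channels=4, n_samples=32, n_trials=5, sfreq=64.0, subject_id="s"
) -> EpochSet:
    times = np.arange(n_samples) / sfreq - 0.25
    return EpochSet(
        data=rng.standard_normal((n_channels, n_samples, n_trials)),
        sfreq=sfreq,
        times=times,
        subject_id=subject_id,
    )


def random_group(rng, n_subjects=3, **kw) -> GroupDataset:
    return GroupDataset(
        [random_epochs(rng, subject_id=f"s{a}", **kw) for a in range(n_subjects)]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_group(rng):
    """3 subjects x 4 channels x 32 samples x 5 trials of white noise."""
    return random_group(rng)


def small_sim_spec(**kw) -> SimulationSpec:
    """Reduced-scale simulation geometry for fast tests."""
    defaults = dict(
        n_subjects=4,
        n_trials=20,
        sfreq=128.0,
        tmin=-0.5,
        tmax=0.5,
        n_channels=16,
        lowpass_hz=40.0,
    )
    defaults.update(kw)
    return SimulationSpec(**defaults)


@pytest.fixture(scope="session")
def small_dataset2():
    """Reduced-scale shared-component scenario with ground truth."""
    spec = small_sim_spec(n_subjects=5)
    return build_dataset2(spec, seed=7, return_truth=True)
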