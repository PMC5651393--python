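import numpy as np
import pytest

from dfncflow.synthgen import SynthConfig, generate_cohort


def two_state_config(**overrides) -> SynthConfig:
    """A small two-state cohort with a 20-point group occupancy contrast."""
    base = dict(
        n_pairs=6,
        grid_shape=(8, 8, 8),
        n_sources=5,
        n_frames=80,
        occupancy_by_group={"HC": (0.4, 0.6), "mTBI": (0.6, 0.4)},
        seed=11,
    )
    base.update(overrides)
    return SynthConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """Shared tiny cohort for tests that only need plausible data."""
    return generate_cohort(two_state_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
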