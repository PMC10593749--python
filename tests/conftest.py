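import numpy as np
import pytest

from bootgait import SimConfig, build_stride_dataset, generate_cohort


@pytest.fixture(scope="session")
def tiny_config():
    """Small single-condition cohort: 3 subjects x 4 speeds x 2 trials x 5 strides."""
    return SimConfig(
        n_subjects=3,
        conditions=(0,),
        trials_per_cell=2,
        strides_per_trial=5,
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_cohort):
    dataset, audit = build_stride_dataset(tiny_cohort.trials)
    return dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
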