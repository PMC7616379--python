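import numpy as np
import pytest

from alloptical.pipeline import (
    PipelineConfig,
    compute_ensembles,
    preprocess_session,
    summarize_photostim,
)
from alloptical.simulate import SimConfig, generate_session


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale session: every trial type present, including the x3 block."""
    return SimConfig(
        n_neurons=60,
        n_trials=160,
        n_targets_per_group=12,
        n_offtarget_in_zones=4,
        n_x3_trials_per_type=12,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_session(small_config):
    return generate_session(small_config)


@pytest.fixture(scope="session")
def small_preprocessed(small_session):
    return preprocess_session(small_session)


@pytest.fixture(scope="session")
def small_ensembles(small_session, small_preprocessed):
    return compute_ensembles(small_preprocessed.evoked, small_session.trial_table)


@pytest.fixture(scope="session")
def small_photostim(small_session, small_preprocessed, small_ensembles):
    return summarize_photostim(
        small_preprocessed.evoked,
        small_session.trial_table,
        small_session.roi_centroids,
        small_session.spiral_sites,
        small_ensembles,
        PipelineConfig(),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
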