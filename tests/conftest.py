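"""Shared fixtures: a small seeded cohort, a tiny fitted state encoder,
and the replay pool built from them. Session-scoped because fitting even
a tiny autoencoder is the slowest part of the unit suite."""

import numpy as np
import pytest

from sepsisrl import (
    PreprocessConfig,
    SimParams,
    build_pool,
    fit_state_encoder,
    generate_cohort,
)

TINY_PREPROCESS = PreprocessConfig(
    encoder_dim=24, encoder_hidden=16, encoder_epochs=3, seed=5
)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(SimParams(n_patients=40, seed=7))


@pytest.fixture(scope="session")
def tiny_encoder(small_cohort):
    return fit_state_encoder(small_cohort, TINY_PREPROCESS)


@pytest.fixture(scope="session")
def small_pool(small_cohort, tiny_encoder):
    return build_pool(small_cohort, tiny_encoder)
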