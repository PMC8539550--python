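"""Shared fixtures.

The heavyweight objects (the 200-system synthetic dataset with 0.02
log-unit noise and the 10-member ensemble trained on it) are built once
per session and shared across unit, property and acceptance tests; the
study conditions (sample size, noise level, seeds) are fixed here.
"""

import numpy as np
import pytest

from sigscreen import (
    build_ensemble,
    demo_library,
    demo_solute_profile,
    generate_synthetic_dataset,
)

DATASET_SEED = 11
ENSEMBLE_SEED = 42
N_SYSTEMS = 200
NOISE_SD = 0.02


@pytest.fixture(scope="session")
def synth_dataset():
    """200 synthetic binary systems, noise sd 0.02 log units."""
    return generate_synthetic_dataset(N_SYSTEMS, NOISE_SD, seed=DATASET_SEED)


@pytest.fixture(scope="session")
def synth_ensemble(synth_dataset):
    """Ten accepted networks trained on the synthetic dataset."""
    return build_ensemble(synth_dataset, target_size=10, seed=ENSEMBLE_SEED)


@pytest.fixture(scope="session")
def small_dataset():
    """A quicker 40-system dataset for cheap unit tests."""
    return generate_synthetic_dataset(40, 0.02, seed=5)


@pytest.fixture(scope="session")
def library():
    return demo_library()


@pytest.fixture(scope="session")
def solute():
    return demo_solute_profile()
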