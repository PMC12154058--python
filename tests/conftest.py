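import numpy as np
import pytest

from fritqc import (CANONICAL_GRID, GeneratorConfig, SpectraSet,
                    default_origin_profiles, simulate_adulteration_dataset,
                    simulate_origin_dataset)


@pytest.fixture(scope="session")
def grid():
    return CANONICAL_GRID


@pytest.fixture(scope="session")
def profiles():
    return default_origin_profiles()


@pytest.fixture(scope="session")
def clean_config():
    """All nuisance effects off: spectra are exact band sums."""
    return GeneratorConfig(seed=7).without_effects()


@pytest.fixture(scope="session")
def small_origin_set():
    """Desk-scale origin set: 4 classes x 2 batches x 8 spectra = 64."""
    return simulate_origin_dataset(GeneratorConfig(seed=11), n_batches=2,
                                   n_per_batch=8)


@pytest.fixture(scope="session")
def small_adulteration_set():
    """Five levels x 20 replicates (the split contract needs 20/level)."""
    return simulate_adulteration_dataset(
        GeneratorConfig(seed=13), levels=[0.01, 0.05, 0.1, 0.25, 0.5])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
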