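import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from oxim import cohorts as ch
from oxim.syndata import SynthConfig, generate_cohorts


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """A 4-cohort, 200-sample, 250-gene compendium with the default programs."""
    return SynthConfig(
        cohort_sizes=[50, 50, 50, 50],
        n_genes=250,
        n_shared_genes=200,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_compendium(small_config):
    return generate_cohorts(small_config)


@pytest.fixture(scope="session")
def small_merged(small_compendium):
    matrices, clinical, truth = small_compendium
    merged = ch.merge([ch.binarize(m) for m in matrices])
    return merged, clinical, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
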