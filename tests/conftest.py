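import numpy as np
import pytest

from phenoscreen import synthgen as sg


@pytest.fixture(scope="session")
def small_screen():
    """A 12-compound x 4-line x 2-replicate screen with sparse interactions."""
    design = sg.gen_screen_design(12, 4, 2, seed=11)
    truth = sg.gen_ground_truth(12, 4, 6, gamma_density=0.03, sigma=0.1, seed=11)
    tables, truth = sg.gen_feature_tables(design, truth)
    return design, truth, tables


@pytest.fixture(scope="session")
def clean_screen():
    """Noise-free, interaction-free screen (exactly additive tables)."""
    design = sg.gen_screen_design(10, 3, 2, seed=5)
    truth = sg.gen_ground_truth(10, 3, 5, gamma_density=0.0, sigma=0.0, seed=5)
    tables, truth = sg.gen_feature_tables(design, truth)
    return design, truth, tables


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
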