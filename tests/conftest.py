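import numpy as np
import pytest

from coevonet import (
    compute_weights,
    count_frequencies,
    filter_to_native,
    infer_couplings,
    make_planted_model,
    sample_potts_msa,
)


@pytest.fixture(scope="session")
def planted_model():
    """Default 30-residue planted family used across tests."""
    return make_planted_model(30, seed=11)


@pytest.fixture(scope="session")
def sampled_msa(planted_model):
    """Equilibrium alignment (M=2000) from the planted model."""
    return sample_potts_msa(planted_model, 2000, seed=1)


@pytest.fixture(scope="session")
def inferred_tensor(planted_model, sampled_msa):
    """Native-filtered coupling tensor inferred from the sampled MSA."""
    weights = compute_weights(sampled_msa)
    tensor = infer_couplings(count_frequencies(sampled_msa, weights))
    return filter_to_native(tensor, planted_model.contact_map)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
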