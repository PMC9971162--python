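import numpy as np
import pytest

from circqc.simulate import SimConfig, simulate_candidates, simulate_reference


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_circ_true=60, n_circ_artifact=60,
                     library_size_mock=16_000, library_size_treated=8_000,
                     mean_mock_reads=10.0, seed=7)


@pytest.fixture(scope="session")
def reference(small_config):
    return simulate_reference(small_config)


@pytest.fixture(scope="session")
def candidate_set(small_config, reference):
    genome, ann = reference
    cands, truth = simulate_candidates(small_config, ann)
    return cands, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
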