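import numpy as np
import pytest

from swaylab.pipeline import PipelineConfig
from swaylab.simulate import simulate_study


@pytest.fixture(scope="session")
def small_sim():
    """A 2-subject synthetic study (90 trial slots), generated once."""
    return simulate_study(seed=42, n_subjects=2)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory, small_sim):
    """The 2-subject study written to disk in the pipeline layout."""
    root = tmp_path_factory.mktemp("study")
    return small_sim.to_directory(root)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()
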