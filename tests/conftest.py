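import numpy as np
import pytest

from fiberdrs.optics import CANCELLOUS_1211NM
from fiberdrs.synthetic_data import PhantomForwardModel, synth_measurement_set


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240108)


@pytest.fixture(scope="session")
def cancellous():
    return CANCELLOUS_1211NM


@pytest.fixture(scope="session")
def forward_model():
    return PhantomForwardModel()


@pytest.fixture(scope="session")
def synthetic_sets(forward_model, tmp_path_factory):
    """One cone-like and one bevel-like synthetic measurement set on disk."""
    root = tmp_path_factory.mktemp("msets")
    sets = {}
    for design, seed in (("cone", 101), ("bevel", 202)):
        out = root / design
        sets[design] = synth_measurement_set(forward_model, design, seed=seed,
                                             out_dir=out)
        sets[design + "_dir"] = out
    return sets
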