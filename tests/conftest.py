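import numpy as np
import pytest

from cotrafold.go_engine import build_go_model
from cotrafold.synthetic_data import (
    BundleSpec,
    make_extended_with_helices,
    make_helix_bundle,
)


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic 35-residue three-helix bundle."""
    return make_helix_bundle()


@pytest.fixture(scope="session")
def model(bundle):
    return build_go_model(bundle)


@pytest.fixture(scope="session")
def extended(bundle):
    """Post-tunnel starting state: helices formed, chain extended along -x."""
    return make_extended_with_helices(bundle)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_structure(rng, n=10, spread=4.0):
    """Random non-degenerate point cloud used as a fake Cα structure."""
    return rng.normal(scale=spread, size=(n, 3))
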