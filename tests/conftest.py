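import numpy as np
import pytest

from atm.io import Volume3D
from atm.phantom import BundleSpec, default_specs, make_subject


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def unit_grid():
    """16^3 grid at 1 mm with identity affine."""
    return Volume3D(np.zeros((16, 16, 16)), affine=np.eye(4), kind="intensity")


@pytest.fixture(scope="session")
def arc_spec():
    return default_specs(n_points=32)[0]


@pytest.fixture(scope="session")
def small_subject(arc_spec):
    """One-bundle phantom subject on the default 32^3 grid (K = 32)."""
    return make_subject([arc_spec], rng_seed=7)


@pytest.fixture(scope="session")
def two_bundle_subject():
    return make_subject(default_specs(n_points=32), rng_seed=11)
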