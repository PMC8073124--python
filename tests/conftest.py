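import numpy as np
import pytest

import ftirgrid as fg


@pytest.fixture(scope="session")
def study():
    """Default distorted 48×1582 synthetic study (seed-fixed)."""
    return fg.generate_study(seed=1)


@pytest.fixture(scope="session")
def clean_study():
    """Undistorted version of the study (separability oracle)."""
    return fg.generate_clean_study(seed=1)


@pytest.fixture(scope="session")
def axis():
    return fg.make_axis()


@pytest.fixture(scope="session")
def reference(axis):
    return fg.generate_reference(axis)


@pytest.fixture()
def small_set():
    """Tiny 3×64 SpectraSet for plumbing tests."""
    ax = fg.WavenumberAxis(np.linspace(1000.0, 1630.0, 64))
    rng = np.random.default_rng(7)
    a = 0.5 + 0.1 * rng.random((3, 64))
    return fg.SpectraSet(ax, a, np.array(["a", "a", "b"]), np.array(["s1", "s2", "s3"], dtype=object))
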