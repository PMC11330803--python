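"""Shared fixtures: a small phantom study reused across test modules."""

import numpy as np
import pytest

from rt4dcbct.phantom import BreathingTrace, default_spec, generate_4dct


@pytest.fixture(scope="session")
def small_spec():
    """32^3 phantom over the standard 256 mm field of view (8 mm voxels)."""
    return default_spec(32)


@pytest.fixture(scope="session")
def small_4dct(small_spec):
    """10-phase 4D-CT stand-in: (volumes, dvfs) on the 32^3 grid."""
    return generate_4dct(small_spec, BreathingTrace.cos2(10))


@pytest.fixture(scope="session")
def small_volumes(small_4dct):
    return small_4dct[0]


@pytest.fixture(scope="session")
def small_dvfs(small_4dct):
    return small_4dct[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
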