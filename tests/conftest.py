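"""Shared fixtures: small synthetic peptides and two-solvent ensembles."""

import numpy as np
import pytest

from lariatperm import synthetic_fixtures as sf


@pytest.fixture(scope="session")
def default_spec():
    return sf.FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def topology(default_spec):
    return sf.build_topology(default_spec)


@pytest.fixture(scope="session")
def small_pair(default_spec):
    """400-frame water/octanol benchmark pair with ground-truth record."""
    return sf.make_benchmark_pair(default_spec, F=400)


@pytest.fixture(scope="session")
def water_ensemble(small_pair):
    return small_pair[0]


@pytest.fixture(scope="session")
def octanol_ensemble(small_pair):
    return small_pair[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
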