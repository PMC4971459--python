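"""Shared fixtures: the default planted study, generated once per session."""

import numpy as np
import pytest

from e3screen.synthetic import (
    FixtureSpec,
    make_promoter_set,
    make_proteome,
    make_tm_topologies,
)


@pytest.fixture(scope="session")
def fixture_spec() -> FixtureSpec:
    return FixtureSpec()


@pytest.fixture(scope="session")
def proteome(fixture_spec):
    return make_proteome(fixture_spec)


@pytest.fixture(scope="session")
def topologies(proteome):
    return make_tm_topologies(proteome)


@pytest.fixture(scope="session")
def promoter_regions(fixture_spec):
    return make_promoter_set(fixture_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
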