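"""Shared fixtures: loaded molecular bundles and density models.

Everything is session-scoped — fixture loading verifies SHA-256 pins and
model construction is cheap, but the witness wavefunction (46 AOs) is worth
caching across tests.
"""

import numpy as np
import pytest

from densiwit.density import DensityModel
from densiwit.fixtures import load_fixture
from densiwit.rdm import embed_active

MOLECULES = ("H2", "LiH", "Li2", "HCN")


@pytest.fixture(scope="session")
def bundles():
    out = {}
    for name in MOLECULES + ("H2_witness",):
        out[name] = load_fixture(name)
    return out


@pytest.fixture(scope="session")
def models(bundles):
    out = {}
    for name, (wfn, rdm) in bundles.items():
        full = rdm if rdm.space == "full" else embed_active(rdm)
        out[name] = DensityModel(wfn, full)
    return out


@pytest.fixture(scope="session")
def cps_cache(models):
    """Critical points per fixture, found once."""
    from densiwit.topology import find_cps
    return {name: find_cps(m) for name, m in models.items()}


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
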