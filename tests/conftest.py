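"""Shared fixtures: small water systems and solved potentials."""

import numpy as np
import pytest

from ipswater import SystemRecipe, build_bulk
from ipswater.ips_potentials import METHOD_SPECS, solve_ips_coefficients


@pytest.fixture(scope="session")
def water64():
    """64 SPC/E waters at the bulk state point (box edge ~1.243 nm)."""
    return build_bulk(SystemRecipe(64, seed=11))


@pytest.fixture(scope="session")
def water27():
    return build_bulk(SystemRecipe(27, seed=13))


@pytest.fixture(params=sorted(METHOD_SPECS))
def method_id(request):
    return request.param


@pytest.fixture
def potential(method_id):
    return solve_ips_coefficients(METHOD_SPECS[method_id], 1.2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
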