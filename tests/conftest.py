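"""Shared fixtures: the three experimental conditions' parameter sets."""

import pytest

from a2mech import BellEvansParams, WLCParams


@pytest.fixture
def no_cfh_kinetics() -> BellEvansParams:
    """Unfolding kinetics of the A2 domain alone."""
    return BellEvansParams(k0=0.15, gamma=0.71)


@pytest.fixture
def wt_cfh_kinetics() -> BellEvansParams:
    """Unfolding kinetics with wild-type CFH bound."""
    return BellEvansParams(k0=0.017, gamma=1.88)


@pytest.fixture
def mutant_cfh_kinetics() -> BellEvansParams:
    """Unfolding kinetics with W1183R-CFH bound."""
    return BellEvansParams(k0=0.034, gamma=1.38)


@pytest.fixture
def no_cfh_wlc() -> WLCParams:
    """Elasticity of the A2 unfolding step without CFH."""
    return WLCParams(contour_length=55.3, persistence_length=0.28)
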