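from fractions import Fraction

import pytest

from caproflux import thermo


@pytest.fixture(scope="session")
def registry():
    return thermo.CompoundRegistry.default()


@pytest.fixture(scope="session")
def eq1(registry):
    return thermo.eq1(registry)


@pytest.fixture(scope="session")
def eq2(registry):
    return thermo.eq2(registry)


@pytest.fixture()
def frac():
    return Fraction
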