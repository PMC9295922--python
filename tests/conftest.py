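import numpy as np
import pytest

import hexapure as hp


@pytest.fixture(scope="session")
def honeybee():
    return hp.standard_system("honeybee")


@pytest.fixture(scope="session")
def honeybee_no_beta():
    return hp.standard_system("honeybee", include_beta=False)


@pytest.fixture(scope="session")
def bumblebee():
    return hp.standard_system("bumblebee")


@pytest.fixture(scope="session")
def honeybee_line(honeybee):
    """Default honeybee monochromatic line (max-distance rule, beta on)."""
    return hp.monochromatic_line(honeybee)


@pytest.fixture(scope="session")
def default_flora():
    """The default synthetic flora at seed 1 (200 flowers, equal class mix)."""
    return hp.generate_flora(hp.FloraConfig(seed=1))


def square_boundary(half_side=1.0):
    """A synthetic axis-aligned square boundary, for purity geometry tests
    where the distance to the boundary is known in closed form."""
    pts = [
        (half_side, half_side),
        (-half_side, half_side),
        (-half_side, -half_side),
        (half_side, -half_side),
    ]
    loci = tuple(
        (float(i), hp.HexagonLocus(P=np.zeros(3), E=np.zeros(3), x=x, y=y))
        for i, (x, y) in enumerate(pts)
    )
    return hp.MonochromaticLine(spectral_loci=loci, closure_loci=(), options={})
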