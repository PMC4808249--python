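import numpy as np
import pytest

from ccprofile.ccp import CCPConfig
from ccprofile.fixtures import FixtureSpec, make_hinge_pair
from ccprofile.refmap import ReferenceSequence, build_residue_map


@pytest.fixture
def hinge_spec():
    return FixtureSpec(
        length=60, geometry="helix", hinge_position=30, hinge_angle_deg=30.0,
        ligands=[("GNP", 45, 4.0)], seed=7,
    )


@pytest.fixture
def hinge_pair(hinge_spec):
    return make_hinge_pair(hinge_spec)


@pytest.fixture
def hinge_map(hinge_pair):
    free, bound = hinge_pair
    ref = ReferenceSequence("REF", free.polymer_chains[0].seqres)
    return build_residue_map(free.polymer_chains[0], bound.polymer_chains[0], ref)


@pytest.fixture
def ls_config():
    return CCPConfig(estimator="least_squares")


def pytest_configure(config):
    np.seterr(all="raise", under="ignore")
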