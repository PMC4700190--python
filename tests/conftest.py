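import numpy as np
import pytest

from spiralscan import CYND_SCREW, build_helical_assembly
from spiralscan.synthetic import make_c2_dimer, make_toy_protomer, truth_standards


@pytest.fixture(scope="session")
def small_protomer():
    """60-residue toy protomer with a planted interface patch at 20-29."""
    return make_toy_protomer(
        n_residues=60, radius=30.0, interface_residues=range(20, 30), seed=11
    )


@pytest.fixture(scope="session")
def small_assembly(small_protomer):
    return build_helical_assembly(small_protomer, CYND_SCREW, 5)


@pytest.fixture(scope="session")
def demo_protomer():
    """CynD-scale protomer: 330 residues, farthest atom at 55 A."""
    return make_toy_protomer(
        n_residues=330, radius=55.0, interface_residues=range(55, 73), seed=0
    )


@pytest.fixture(scope="session")
def demo_dimer(demo_protomer):
    return make_c2_dimer(demo_protomer)


@pytest.fixture(scope="session")
def standards():
    return truth_standards()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
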