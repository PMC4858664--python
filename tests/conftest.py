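import numpy as np
import pytest

from aggscape import (
    ProfileParams,
    PropensityScales,
    Sequence,
    SynthSpec,
    build_chain,
    build_hairpin,
    build_helix,
)
from aggscape._build import STRAND_PHI_PSI


@pytest.fixture(scope="session")
def scales():
    return PropensityScales.default()


@pytest.fixture(scope="session")
def params():
    return ProfileParams()


@pytest.fixture(scope="session")
def hairpin():
    return build_hairpin(5)


@pytest.fixture(scope="session")
def hairpin7():
    return build_hairpin(7)


@pytest.fixture(scope="session")
def helix():
    return build_helix(12)


@pytest.fixture(scope="session")
def extended():
    return build_chain("A" * 12, STRAND_PHI_PSI)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def fast_spec():
    """Small, fast synthetic benchmark instance."""
    return SynthSpec(ensemble_size=10, sasa_points=128, seed=7)


def random_coil(n_res: int, rng: np.random.Generator):
    """Chain with random backbone dihedrals: an H-bond-pattern stress fixture."""
    angles = [tuple(rng.uniform(-np.pi, np.pi, 2)) for _ in range(n_res)]
    return build_chain("A" * n_res, angles)
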