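import numpy as np
import pytest

from domaintwist import (
    SyntheticConfig,
    build_reference,
    build_two_domain_structure,
    domain_selections,
    make_reference_pair,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_config():
    """Minimal two-domain system used across modules."""
    return SyntheticConfig(n_atoms_N=20, n_atoms_C=20, seed=11)


@pytest.fixture(scope="session")
def small_system(small_config):
    """(structure, inactive, active, reference) for the small config."""
    structure = build_two_domain_structure(small_config)
    inactive, active = make_reference_pair(structure, small_config)
    n_sel, c_sel = domain_selections(small_config)
    reference = build_reference(inactive, active, n_sel, c_sel)
    return structure, inactive, active, reference


def random_cloud(rng, n=60, spread=5.0):
    """Gaussian point cloud helper shared by geometry tests."""
    return rng.normal(scale=spread, size=(n, 3))
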