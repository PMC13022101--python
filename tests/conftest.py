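import numpy as np
import pytest

from rmsx import SyntheticSpec, build_system, select_atoms


@pytest.fixture(scope="session")
def jitter_system():
    """Stationary isotropic Gaussian jitter, sigma = 0.5 Å per coordinate."""
    return build_system(
        SyntheticSpec(n_residues=10, n_frames=400, sigma=0.5, seed=7)
    )


@pytest.fixture(scope="session")
def dimer_system():
    """Two-chain system (A/B) with mild jitter."""
    return build_system(
        SyntheticSpec(n_residues=8, n_frames=30, sigma=0.2, n_chains=2, seed=11)
    )


@pytest.fixture
def ca_selection(jitter_system):
    return select_atoms(jitter_system)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
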