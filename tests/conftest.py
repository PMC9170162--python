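"""Shared fixtures for the endonet test suite."""

import numpy as np
import pytest

from endonet.tissue import assign_sensitivity, build_hex_lattice


@pytest.fixture(scope="session")
def lattice10():
    """A defect-free 10 x 10 hexagonal lattice (no jitter)."""
    return build_hex_lattice(10, 10, cell_diameter=30.0, jitter=0.0, seed=0)


@pytest.fixture(scope="session")
def lattice10_jittered():
    """Same lattice with vertex jitter."""
    return build_hex_lattice(10, 10, cell_diameter=30.0, jitter=5.0, seed=0)


@pytest.fixture(scope="session")
def sens10(lattice10):
    """Clustered sensitivity on the 10 x 10 lattice."""
    return assign_sensitivity(lattice10, 0.25, mode="clustered",
                              mean_cluster_size=5, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
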