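"""Shared fixtures: small simulated datasets and toy spot data."""

import numpy as np
import pytest

from spotdecon import priors, simulate
from spotdecon.core_io import SignatureSet, SpotDataset


@pytest.fixture(scope="session")
def small_sim():
    """8x8-grid, 5-type simulation used by fast unit tests."""
    return simulate.simulate_dataset("major", grid_side=8, seed=1)


@pytest.fixture(scope="session")
def small_priors(small_sim):
    return priors.build_priors(small_sim.data, small_sim.signatures(), seed=0)


@pytest.fixture()
def toy_dataset():
    """4 spots x 6 genes with hand-set counts on a 2x2 grid."""
    counts = np.array([
        [5, 0, 1, 2, 3, 4],
        [0, 2, 2, 2, 2, 2],
        [8, 8, 0, 0, 1, 1],
        [1, 1, 1, 1, 1, 1],
    ])
    return SpotDataset(
        counts=counts,
        gene_names=[f"G{i}" for i in range(6)],
        spot_ids=[f"s{i}" for i in range(4)],
        array_coords=np.array([[0, 0], [0, 1], [1, 0], [1, 1]]),
    )


@pytest.fixture()
def toy_signatures():
    return SignatureSet(["stateA", "stateB"],
                        {"stateA": ["G0", "G1"], "stateB": ["G4", "G5"]})
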