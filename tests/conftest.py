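import numpy as np
import pytest

from xldock.representation import FlexibleSegment, SystemModel
from xldock.synthetic import make_toy_system, simulate_crosslinks


@pytest.fixture(scope="session")
def toy_truth():
    """Session-wide three-body ground truth (deterministic)."""
    return make_toy_system(n_bodies=3, residues_per_body=60, linker_length=15, seed=1)


@pytest.fixture(scope="session")
def toy_xls(toy_truth):
    return simulate_crosslinks(toy_truth, n_true=40, n_decoy=4)


@pytest.fixture()
def two_bead_model():
    """Two free beads (separate components), radius 3 Å, at distance 4 Å."""
    coords = np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
    segs = [
        FlexibleSegment(component="a", residue_range=(1, 1), indices=np.array([0])),
        FlexibleSegment(component="b", residue_range=(1, 1), indices=np.array([1])),
    ]
    return SystemModel(
        coords=coords,
        rigid_bodies=[],
        flexible_segments=segs,
        residue_index={("a", 1): 0, ("b", 1): 1},
        bead_radii=np.array([3.0, 3.0]),
    )
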