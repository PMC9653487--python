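import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mscgate.structio import ChannelStructure, MembraneSlab
from mscgate.synthetic import make_state_pair


def simple_structure(
    positions,
    chain_ids=None,
    residue_numbers=None,
    residue_names=None,
    elements=None,
    vdw_radii=None,
    frame_aligned=True,
    symmetry_order=1,
):
    """Minimal ChannelStructure from raw coordinates (test helper)."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = len(positions)
    return ChannelStructure(
        positions,
        ["CA"] * n,
        elements if elements is not None else ["C"] * n,
        residue_names if residue_names is not None else ["LEU"] * n,
        residue_numbers if residue_numbers is not None else list(range(1, n + 1)),
        chain_ids if chain_ids is not None else ["A"] * n,
        vdw_radii,
        symmetry_order=symmetry_order,
        frame_aligned=frame_aligned,
    )


@pytest.fixture(scope="session")
def mimic_pair():
    """Default closed/open MscK-mimic pair with ground truth."""
    return make_state_pair()


@pytest.fixture(scope="session")
def mimic_slabs(mimic_pair):
    _, _, truth = mimic_pair
    return (
        MembraneSlab(*truth["closed"].tm_slab),
        MembraneSlab(*truth["open"].tm_slab),
    )
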