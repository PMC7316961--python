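import numpy as np
import pytest
import trimesh

import footmech.phantom as ph


@pytest.fixture(scope="session")
def foot():
    """Default synthetic foot (30 bones, CT-resolution masks)."""
    return ph.generate_foot_phantom(ph.PhantomSpec(seed=42))


@pytest.fixture(scope="session")
def load_case(foot):
    """One loaded configuration: truth transforms + voxelized skeleton."""
    tfs = ph.random_load_transforms(foot.bones, seed=7)
    state, mask = ph.apply_load_case(foot, tfs, "N_1.0_bare", "N", 1.0, "bare")
    return {"transforms": tfs, "state": state, "mask": mask}


@pytest.fixture(scope="session")
def bone_pair():
    """One calcaneus-scale generic/patient pair with known truth map."""
    return ph.generate_bone_pairs(n=1, seed=42)[0]


@pytest.fixture(scope="session")
def sphere():
    return trimesh.creation.icosphere(subdivisions=3, radius=10.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
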