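import numpy as np
import pytest

from stereosim import synthfmri


@pytest.fixture(scope="session")
def face_map():
    return synthfmri.make_face_like_depth_map(seed=7)


@pytest.fixture(scope="session")
def planted_dataset():
    """Small 3-run dataset with 10 strongly informative voxels."""
    model = synthfmri.VoxelPatternModel.planted(
        n_voxels=80, n_informative=10, effect_size=2.0, seed=11)
    data = synthfmri.simulate_timeseries(model, n_runs=3, noise_sigma=1.0, seed=12)
    return model, data


@pytest.fixture(scope="session")
def null_dataset():
    """Dataset whose labels carry no information (effect size 0)."""
    model = synthfmri.VoxelPatternModel.planted(
        n_voxels=40, n_informative=10, effect_size=0.0, seed=21)
    return synthfmri.simulate_timeseries(model, n_runs=2, noise_sigma=1.0, seed=22)
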