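import numpy as np
import pytest

from tmsinv.data import (CortexMask, EFieldVolume, MEPVector,
                         StimulationDataset, StimulationRecord)
from tmsinv.phantom import PhantomConfig, generate_dataset


@pytest.fixture(scope="session")
def phantom_config():
    return PhantomConfig.test_scale(seed=1)


@pytest.fixture(scope="session")
def phantom_dataset(phantom_config):
    """One 16^3, 196-stimulation phantom reused across the session."""
    return generate_dataset(phantom_config)


@pytest.fixture(scope="session")
def preprocessed_dataset(phantom_dataset):
    from tmsinv.data import preprocess
    ds, _ = preprocess(phantom_dataset)
    return ds


def make_record(rid, grid, mep_values, mask_shape=None, intensity=110,
                voxel_size=1.0):
    """Hand-built stimulation record for planted-dataset tests."""
    grid = np.asarray(grid, dtype=np.float32)
    return StimulationRecord(
        id=rid, coil_position=np.zeros(3), coil_orientation=45.0,
        intensity_pct_rmt=intensity,
        efield=EFieldVolume(grid=grid, voxel_size=voxel_size),
        mep=MEPVector(values=np.asarray(mep_values, dtype=float),
                      muscle_names=[f"M{i}" for i in
                                    range(len(mep_values))]))


def make_dataset(records, mask_grid):
    return StimulationDataset(records=list(records),
                              mask=CortexMask(grid=np.asarray(mask_grid)))


@pytest.fixture
def tiny_mask():
    g = np.zeros((6, 6, 6), dtype=np.uint8)
    g[2:4, 2:4, 2:4] = 1
    return g
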