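import numpy as np
import pytest

import xelobe as xl

SMALL_GRID = (48, 48, 36)


@pytest.fixture(scope="session")
def small_spec() -> xl.PhantomSpec:
    return xl.PhantomSpec(grid_shape=SMALL_GRID, random_seed=3)


@pytest.fixture(scope="session")
def subject(small_spec) -> xl.PhantomSubject:
    """One fully generated phantom subject, shared across tests."""
    return xl.generate_subject(small_spec)


@pytest.fixture(scope="session")
def uniform_schedule() -> xl.AcquisitionSchedule:
    return xl.AcquisitionSchedule.uniform()


@pytest.fixture(scope="session")
def identifiable_schedule() -> xl.AcquisitionSchedule:
    return xl.AcquisitionSchedule.identifiable_design()


@pytest.fixture()
def toy_masks() -> xl.LobarMaskSet:
    """3x3x1 grid with all five lobes present (RUL spans 3 voxels)."""
    labels = np.array([[[1], [1], [2]], [[3], [4], [5]], [[1], [2], [3]]], dtype=np.int16)
    return xl.LobarMaskSet(labels=labels, spacing=(1.0, 1.0, 1.0))
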