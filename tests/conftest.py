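import numpy as np
import pytest

import sbrteval as sv
from sbrteval.power import oc_phantom_spec


@pytest.fixture(scope="session")
def small_spec():
    """Compact 32^3 / 5 mm phantom used wherever full resolution is not
    the point (keeps the suite fast)."""
    return oc_phantom_spec()


@pytest.fixture(scope="session")
def small_structures(small_spec):
    return sv.make_phantom(small_spec)


@pytest.fixture(scope="session")
def small_plan():
    return sv.PlanSpec()


@pytest.fixture(scope="session")
def small_dose(small_structures, small_plan):
    return sv.make_plan_dose(
        small_structures, small_plan, rng=np.random.default_rng(7)
    )


def grid_from_voxels(doses, spacing=1.0):
    """DoseGrid wrapping an explicit voxel-dose array."""
    arr = np.asarray(doses, dtype=float)
    return sv.DoseGrid(arr, (spacing,) * arr.ndim)


@pytest.fixture
def eight_voxel_dvh():
    """Canonical 8-voxel example: doses 1..8 Gy in 1 cc voxels."""
    dose = grid_from_voxels(np.arange(1.0, 9.0).reshape(2, 2, 2), spacing=10.0)
    mask = np.ones((2, 2, 2), dtype=bool)
    return sv.compute_dvh(dose, mask, structure_name="cube8")
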