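"""Shared fixtures: small, session-scoped phantoms and plans.

All fixtures use the coarse 2 mm grid profile so the suite stays fast;
resolution-sensitive checks build their own grids.
"""

import numpy as np
import pytest

import rotodose as rd


@pytest.fixture(scope="session")
def fast_phantom():
    """Default fast-profile head phantom, seed 1: (image, structures, isocenter)."""
    return rd.make_head_phantom(rd.PhantomSpec.fast(seed=1))


@pytest.fixture(scope="session")
def fast_plan(fast_phantom):
    """(dose grid, goals) for the fast phantom's PTV."""
    _, structures, _ = fast_phantom
    goals = rd.PlanGoals()
    return rd.plan_dose(structures["PTV"], goals), goals


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_fractional_structure(rng, shape=(5, 5, 5), spacing=(2.0, 2.0, 2.0)):
    occ = rng.uniform(0.0, 1.0, size=shape)
    occ[occ < 0.2] = 0.0  # some empty voxels
    return rd.Structure(name="rand", role="OAR", shape_class="sphere",
                        occupancy=occ, spacing=np.asarray(spacing),
                        origin=np.zeros(3))
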