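import numpy as np
import pytest

from motiontol import (CohortSpec, GridGeometry, PhantomSpec,
                       default_constraints, prostate_phantom, simulate_cohort)


@pytest.fixture(scope="session")
def phantom0():
    """The default synthetic prostate plan (seed 0, anterior DIL)."""
    return prostate_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def cohort20():
    """The 20-patient synthetic cohort emulating the planning study."""
    return simulate_cohort(CohortSpec(n=20, seed=0))


@pytest.fixture(scope="session")
def constraints():
    return default_constraints()


@pytest.fixture
def small_geometry():
    return GridGeometry(origin=(0.0, 0.0, 0.0), spacing=(1.0, 1.0, 1.0),
                        dims=(5, 5, 5))


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
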