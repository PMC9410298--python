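import numpy as np
import pytest
from hypothesis import settings

from hemocoherence.cohort import CohortConfig, generate_cohort
from hemocoherence.geometry import VesselSegment, mesh_vessel
from hemocoherence.solver import BoundaryConditions, solve_flow

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

UM = 1e-6


@pytest.fixture(scope="session")
def base_solution():
    """Reference straight-channel case at the study's mean vessel geometry
    (17.2 um wide, 137.3 um long, 15 um/s plug inlet), default mesh."""
    seg = VesselSegment.straight(17.2, 137.3, 15.0)
    mesh = mesh_vessel(seg, 250, 20)
    return solve_flow(mesh, bc=BoundaryConditions(inlet_velocity=15 * UM))


@pytest.fixture(scope="session")
def default_cohort():
    """20 synthetic patients at the default configuration, seed 1."""
    cfg = CohortConfig(seed=1)
    return cfg, generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
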