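import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hes1rdme as h

settings.register_profile(
    "fast",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fast")


@pytest.fixture(scope="session")
def small_mesh():
    """Coarse two-compartment mesh, cheap enough for per-test simulation."""
    return h.build_spherical_cell_mesh(cell_radius=2.4, nucleus_radius=1.2, voxel_edge=0.6)


@pytest.fixture(scope="session")
def default_mesh():
    return h.build_spherical_cell_mesh()


@pytest.fixture(scope="session")
def default_setup(default_mesh):
    params = h.ParameterSet()
    system = h.build_reaction_system(params, default_mesh)
    jumps = h.compute_jump_rates(
        default_mesh,
        {"mRNA": params.D, "protein": params.D, "P_f": 0.0, "P_o": 0.0},
    )
    return params, system, jumps


@pytest.fixture(scope="session")
def wt_trajectory(default_mesh, default_setup):
    """One 400-min baseline trajectory shared across tests."""
    params, system, jumps = default_setup
    init = h.initial_state(default_mesh, seed=11)
    return h.simulate_nsm(system, jumps, init, t_end=400, record_dt=1.0, seed=11)


def small_setup(mesh, **overrides):
    """Build (params, system, jumps) on a mesh with parameter overrides."""
    params = h.ParameterSet().with_overrides(**overrides)
    system = h.build_reaction_system(params, mesh)
    jumps = h.compute_jump_rates(
        mesh, {"mRNA": params.D, "protein": params.D, "P_f": 0.0, "P_o": 0.0}
    )
    return params, system, jumps
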