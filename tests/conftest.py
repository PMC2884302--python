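import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import abiplan as ab
from abiplan import presets

settings.register_profile(
    "ci",
    max_examples=25,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


MINI_SPEC = {
    "grid_shape": [40, 40, 24],
    "spacing_mm": [2.0, 2.0, 2.0],
    "structures": [
        {"name": "body", "role": "body",
         "shape": {"type": "cylinder", "center": [0.0, 0.0], "radius": 36.0}},
        {"name": "ptv", "role": "target",
         "shape": {"type": "annulus_sector", "center": [0.0, 0.0],
                   "r_inner": 10.0, "r_outer": 22.0, "z_range": [-16.0, 16.0],
                   "gap_direction_deg": 0.0, "gap_angle_deg": 90.0}},
        {"name": "cord", "role": "oar",
         "shape": {"type": "cylinder", "center": [0.0, 0.0], "radius": 5.0}},
        {"name": "parotid_l", "role": "oar",
         "shape": {"type": "ellipsoid", "center": [29.0, 2.0, 0.0],
                   "semiaxes": [5.0, 7.0, 9.0]}},
        {"name": "parotid_r", "role": "oar",
         "shape": {"type": "ellipsoid", "center": [-29.0, 2.0, 0.0],
                   "semiaxes": [5.0, 7.0, 9.0]}},
    ],
}

MINI_OBJECTIVE = ab.DoseObjective(
    (
        ab.StructureGoal("ptv", "target", d_max=53.0, d_min=48.0, prescription=50.4, penalty=10.0),
        ab.StructureGoal("cord", "oar", d_max=45.0, penalty=8.0),
        ab.StructureGoal("parotid_l", "oar", d_max=25.0, penalty=3.0),
        ab.StructureGoal("parotid_r", "oar", d_max=25.0, penalty=3.0),
        ab.StructureGoal("body", "body", d_max=55.0, penalty=1.0),
    )
)


@pytest.fixture(scope="session")
def mini_phantom():
    return ab.build_phantom(MINI_SPEC)


@pytest.fixture(scope="session")
def mini_beams():
    return [ab.Beam(gantry_angle=a) for a in (0.0, 120.0, 240.0)]


@pytest.fixture(scope="session")
def mini_apertures(mini_phantom, mini_beams):
    return ab.design_apertures(mini_phantom, mini_beams, margin=4.0, min_per_beam=3, max_per_beam=4)


@pytest.fixture(scope="session")
def mini_points(mini_phantom):
    return ab.place_sample_points(mini_phantom, density=1.0, seed=7)


@pytest.fixture(scope="session")
def mini_matrix(mini_phantom, mini_apertures, mini_points):
    return ab.compute_dose_matrix(mini_phantom, mini_apertures, mini_points)


@pytest.fixture(scope="session")
def mini_objective():
    return MINI_OBJECTIVE


@pytest.fixture(scope="session")
def case_a_bundle():
    return presets.simulate_case("case-a", density=1.0, seed=17)


@pytest.fixture(scope="session")
def case_b_bundle():
    return presets.simulate_case("case-b", density=1.0, seed=17)


def make_consistent_system(rng, m, n):
    """A random non-negative dose matrix with a known non-negative weight vector."""
    D = rng.uniform(0.0, 1.0, size=(m, n))
    w_true = rng.uniform(0.1, 2.0, size=n)
    return D, w_true, D @ w_true
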