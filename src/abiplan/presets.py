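"""Packaged phantom presets.

Two synthetic cases mirror the study conditions the optimizer is meant for:

* ``case-a`` — a concave head-and-neck-like geometry: a horseshoe target
  wrapping a central cord-like cylindrical OAR, flanked by two lateral
  parotid-like OARs; seven coplanar 6 MV beams, four to five anatomy-based
  apertures each.  Prescription 50.4 Gy, cord limit 45 Gy.
* ``case-b`` — a lateral brain-like lesion beside a brainstem-like cylinder,
  a chiasm-like node and two optic-nerve-like nodes; seven coplanar beams,
  three to five apertures each.  Prescription 50 Gy with tight OAR maxima.

At the default sampling density of 1 point/cc each case yields on the order
of 1100-1300 sample points and ~30 apertures, the problem size the exact
solver is designed around.
"""

from __future__ import annotations

import dataclasses

from .errors import InvalidSpecError
from .objective import DoseObjective, StructureGoal
from .phantom import (
    Beam,
    DoseInfluenceMatrix,
    KernelParameters,
    Phantom,
    SamplePointSet,
    Aperture,
    build_phantom,
    compute_dose_matrix,
    design_apertures,
    place_sample_points,
)
from .replan import PlanGoal

PRESET_NAMES = ("case-a", "case-b")

_CASE_A_SPEC = {
    "grid_shape": [80, 80, 40],
    "spacing_mm": [2.0, 2.0, 2.0],
    "structures": [
        {"name": "body", "role": "body",
         "shape": {"type": "cylinder", "center": [0.0, 0.0], "radius": 72.0}},
        {"name": "ptv", "role": "target",
         "shape": {"type": "annulus_sector", "center": [0.0, 0.0],
                   "r_inner": 18.0, "r_outer": 48.0, "z_range": [-36.0, 36.0],
                   "gap_direction_deg": 0.0, "gap_angle_deg": 90.0}},
        {"name": "cord", "role": "oar",
         "shape": {"type": "cylinder", "center": [0.0, 0.0], "radius": 8.0}},
        {"name": "parotid_l", "role": "oar",
         "shape": {"type": "ellipsoid", "center": [62.0, 5.0, 0.0],
                   "semiaxes": [9.0, 13.0, 18.0]}},
        {"name": "parotid_r", "role": "oar",
         "shape": {"type": "ellipsoid", "center": [-62.0, 5.0, 0.0],
                   "semiaxes": [9.0, 13.0, 18.0]}},
    ],
}

_CASE_B_SPEC = {
    "grid_shape": [70, 70, 40],
    "spacing_mm": [2.0, 2.0, 2.0],
    "structures": [
        {"name": "body", "role": "body",
         "shape": {"type": "cylinder", "center": [0.0, 0.0], "radius": 65.0}},
        {"name": "ptv", "role": "target",
         "shape": {"type": "sphere", "center": [24.0, 0.0, 0.0], "radius": 39.0}},
        {"name": "brainstem", "role": "oar",
         "shape": {"type": "cylinder", "center": [-26.0, 0.0], "radius": 9.0}},
        {"name": "chiasm", "role": "oar",
         "shape": {"type": "sphere", "center": [-22.0, 24.0, 6.0], "radius": 6.0}},
        {"name": "optic_nerve_r", "role": "oar",
         "shape": {"type": "sphere", "center": [-14.0, 36.0, 4.0], "radius": 5.0}},
        {"name": "optic_nerve_l", "role": "oar",
         "shape": {"type": "sphere", "center": [-34.0, 20.0, 4.0], "radius": 5.0}},
    ],
}

_BEAM_ANGLES = {
    "case-a": (0.0, 45.0, 100.0, 150.0, 210.0, 260.0, 315.0),
    "case-b": (20.0, 70.0, 120.0, 170.0, 220.0, 270.0, 320.0),
}

_APERTURE_PARAMS = {
    "case-a": {"margin": 6.0, "min_per_beam": 4, "max_per_beam": 5},
    "case-b": {"margin": 6.0, "min_per_beam": 3, "max_per_beam": 5},
}

_OBJECTIVES = {
    "case-a": (
        StructureGoal("ptv", "target", d_max=53.0, d_min=48.0, prescription=50.4, penalty=10.0),
        StructureGoal("cord", "oar", d_max=45.0, penalty=8.0),
        StructureGoal("parotid_l", "oar", d_max=25.0, penalty=3.0),
        StructureGoal("parotid_r", "oar", d_max=25.0, penalty=3.0),
        StructureGoal("body", "body", d_max=55.0, penalty=1.0),
    ),
    "case-b": (
        StructureGoal("ptv", "target", d_max=53.0, d_min=47.5, prescription=50.0, penalty=10.0),
        StructureGoal("brainstem", "oar", d_max=50.0, penalty=8.0),
        StructureGoal("chiasm", "oar", d_max=50.0, penalty=8.0),
        StructureGoal("optic_nerve_r", "oar", d_max=45.0, penalty=5.0),
        StructureGoal("optic_nerve_l", "oar", d_max=50.0, penalty=5.0),
        StructureGoal("body", "body", d_max=55.0, penalty=1.0),
    ),
}

_PLAN_GOALS = {
    "case-a": (
        PlanGoal("ptv", 50.4, 95.0, "at_least"),
        PlanGoal("ptv", 53.0, 55.0, "at_most"),
        PlanGoal("ptv", 60.0, 0.0, "at_most"),
        PlanGoal("parotid_l", 20.0, 40.0, "at_most"),
        PlanGoal("parotid_r", 20.0, 40.0, "at_most"),
        PlanGoal("cord", 45.0, 0.0, "at_most"),
    ),
    "case-b": (
        PlanGoal("ptv", 50.0, 95.0, "at_least"),
        PlanGoal("ptv", 53.0, 53.0, "at_most"),
        PlanGoal("ptv", 60.0, 0.0, "at_most"),
        PlanGoal("brainstem", 50.0, 0.0, "at_most"),
        PlanGoal("brainstem", 35.0, 45.0, "at_most"),
        PlanGoal("chiasm", 50.0, 0.0, "at_most"),
        PlanGoal("optic_nerve_r", 45.0, 0.0, "at_most"),
        PlanGoal("optic_nerve_l", 50.0, 0.0, "at_most"),
    ),
}

# Illustrative (not reconstructive) penalty-edit schedules for the scripted
# replanning loop: six trials for case-a, nine for case-b.
PENALTY_SCHEDULES: dict[str, tuple[dict[str, float], ...]] = {
    "case-a": (
        {},
        {"cord": 12.0},
        {"cord": 16.0, "parotid_l": 4.0, "parotid_r": 4.0},
        {"ptv": 14.0},
        {"cord": 20.0},
        {"ptv": 16.0, "body": 1.5},
    ),
    "case-b": (
        {},
        {"brainstem": 10.0},
        {"chiasm": 10.0},
        {"ptv": 12.0},
        {"brainstem": 12.0, "optic_nerve_l": 6.0},
        {"ptv": 14.0},
        {"chiasm": 12.0},
        {"body": 1.5},
        {"ptv": 16.0},
    ),
}


def _check(name: str) -> str:
    if name not in PRESET_NAMES:
        raise InvalidSpecError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return name


def phantom_spec(name: str) -> dict:
    """The JSON-style phantom specification of a preset."""
    import copy

    return copy.deepcopy({"case-a": _CASE_A_SPEC, "case-b": _CASE_B_SPEC}[_check(name)])


def beams(name: str) -> list[Beam]:
    return [Beam(gantry_angle=a) for a in _BEAM_ANGLES[_check(name)]]


def aperture_params(name: str) -> dict:
    return dict(_APERTURE_PARAMS[_check(name)])


def objective(name: str) -> DoseObjective:
    return DoseObjective(_OBJECTIVES[_check(name)])


def plan_goals(name: str) -> tuple[PlanGoal, ...]:
    return _PLAN_GOALS[_check(name)]


def penalty_schedule(name: str) -> tuple[dict[str, float], ...]:
    return PENALTY_SCHEDULES[_check(name)]


@dataclasses.dataclass(frozen=True)
class CaseBundle:
    """Everything needed to optimize one preset case."""

    name: str
    phantom: Phantom
    beams: tuple[Beam, ...]
    apertures: tuple[Aperture, ...]
    points: SamplePointSet
    matrix: DoseInfluenceMatrix
    objective: DoseObjective
    goals: tuple[PlanGoal, ...]


def simulate_case(
    name: str,
    density: float = 1.0,
    seed: int = 17,
    kernel: KernelParameters | None = None,
) -> CaseBundle:
    """Build phantom, apertures, sample points and dose matrix for a preset."""
    name = _check(name)
    phantom = build_phantom(phantom_spec(name))
    bms = beams(name)
    aps = design_apertures(phantom, bms, **aperture_params(name))
    pts = place_sample_points(phantom, density, seed)
    matrix = compute_dose_matrix(phantom, aps, pts, kernel)
    return CaseBundle(
        name=name,
        phantom=phantom,
        beams=tuple(bms),
        apertures=tuple(aps),
        points=pts,
        matrix=matrix,
        objective=objective(name),
        goals=plan_goals(name),
    )
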