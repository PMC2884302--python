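"""Interactive replanning drivers: penalty trials and aperture-count sweeps.

The optimizer is fast enough that planning proceeds as a human-in-the-loop
sequence of trials: edit some structure penalties, re-solve, inspect the
dose-volume goals, repeat.  :class:`PlanningSession` records that loop and
can replay it bit-exactly from a saved JSON file.

:func:`aperture_sweep` re-optimizes the same case with an increasing number
of apertures per beam.  Aperture sets are nested (each count's set is a
prefix of the next) and the prescribed-dose vector is held fixed across the
sweep, so the weighted least-squares surrogate at the unconstrained solution
is provably non-increasing in the aperture count.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError
from .evaluation import PlanMetrics, dose_volume_index, plan_metrics
from .objective import DoseObjective, StructureGoal
from .phantom import (
    Beam,
    DoseInfluenceMatrix,
    KernelParameters,
    Phantom,
    compute_dose_matrix,
    design_apertures,
    place_sample_points,
)
from .solver import default_lambda, optimize_weights, prescribed_dose_vector

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class PlanGoal:
    """A Table-style dose-volume goal: V(threshold_gy) {>=|<=} limit_percent."""

    structure: str
    threshold_gy: float
    limit_percent: float
    direction: str  # 'at_least' | 'at_most'

    def __post_init__(self):
        if self.direction not in ("at_least", "at_most"):
            raise ConfigurationError("direction must be 'at_least' or 'at_most'")

    @property
    def key(self) -> str:
        op = ">=" if self.direction == "at_least" else "<="
        return f"{self.structure} V{self.threshold_gy:g} {op} {self.limit_percent:g}%"

    def passes(self, volume_percent: float) -> bool:
        if self.direction == "at_least":
            return volume_percent >= self.limit_percent
        return volume_percent <= self.limit_percent


@dataclasses.dataclass(frozen=True)
class TrialRecord:
    """One optimization trial in a session."""

    trial_index: int  # consecutive from 1
    penalties: dict[str, float]
    cost_initial: float
    cost_final: float
    metrics: PlanMetrics
    goal_pass: dict[str, bool]
    per_structure_cost: dict[str, float]
    weights: np.ndarray


def matrix_digest(matrix: DoseInfluenceMatrix) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(matrix.values).tobytes())
    h.update("|".join(map(str, matrix.row_structures)).encode())
    h.update("|".join(map(str, matrix.column_labels)).encode())
    return h.hexdigest()


class PlanningSession:
    """Append-only trial history over one dose-influence matrix."""

    def __init__(
        self,
        matrix: DoseInfluenceMatrix,
        objective: DoseObjective,
        goals: Sequence[PlanGoal] = (),
        *,
        lam: float | None = None,
        nonneg: bool = True,
        mu_per_weight: float = 1.0,
    ):
        objective.check_covers(matrix.row_structures)
        self.matrix = matrix
        self.initial_objective = objective
        self.objective = objective
        self.goals = tuple(goals)
        self.lam = lam
        self.nonneg = nonneg
        self.mu_per_weight = mu_per_weight
        self.trials: list[TrialRecord] = []

    def run_trial(self, penalty_update: dict[str, float] | None = None) -> TrialRecord:
        """Apply a penalty edit, re-optimize, and append the trial record."""
        if penalty_update:
            self.objective = self.objective.with_penalties(penalty_update)
        result = optimize_weights(
            self.matrix, self.objective, lam=self.lam, nonneg=self.nonneg
        )
        from .objective import cost as _cost

        report = _cost(result.doses, self.objective, self.matrix.row_structures)
        goal_pass = {}
        for g in self.goals:
            d = result.doses[self.matrix.row_structures == g.structure]
            goal_pass[g.key] = g.passes(dose_volume_index(d, "V_at_dose", g.threshold_gy))
        record = TrialRecord(
            trial_index=len(self.trials) + 1,
            penalties=dict(self.objective.penalties),
            cost_initial=result.cost_initial,
            cost_final=result.cost_final,
            metrics=plan_metrics(result, self.mu_per_weight),
            goal_pass=goal_pass,
            per_structure_cost=dict(report.per_structure),
            weights=result.weights,
        )
        self.trials.append(record)
        logger.info(
            "trial %d: cost %.4g -> %.4g, MU %.1f, %d apertures",
            record.trial_index, record.cost_initial, record.cost_final,
            record.metrics.total_mu, record.metrics.n_apertures,
        )
        return record

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def goal_dict(g: StructureGoal) -> dict:
            return {
                "structure": g.structure, "role": g.role, "d_max": g.d_max,
                "d_min": g.d_min, "prescription": g.prescription, "penalty": g.penalty,
            }

        schedule = []
        prev = dict(self.initial_objective.penalties)
        for t in self.trials:
            schedule.append({k: v for k, v in t.penalties.items() if prev.get(k) != v})
            prev = t.penalties
        return {
            "matrix_sha256": matrix_digest(self.matrix),
            "objective": [goal_dict(g) for g in self.initial_objective.goals],
            "plan_goals": [dataclasses.asdict(g) for g in self.goals],
            "lam": self.lam,
            "nonneg": self.nonneg,
            "mu_per_weight": self.mu_per_weight,
            "schedule": schedule,
            "trials": [
                {
                    "trial_index": t.trial_index,
                    "penalties": t.penalties,
                    "cost_initial": t.cost_initial,
                    "cost_final": t.cost_final,
                    "total_mu": t.metrics.total_mu,
                    "n_apertures": t.metrics.n_apertures,
                    "goal_pass": t.goal_pass,
                }
                for t in self.trials
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def replay(cls, path: str | Path, matrix: DoseInfluenceMatrix) -> "PlanningSession":
        """Rebuild a session from file and re-run its penalty schedule."""
        data = json.loads(Path(path).read_text())
        if data["matrix_sha256"] != matrix_digest(matrix):
            raise ValidationError("matrix does not match the one recorded in the session file")
        objective = DoseObjective(
            tuple(StructureGoal(**g) for g in data["objective"])
        )
        goals = tuple(PlanGoal(**g) for g in data["plan_goals"])
        session = cls(
            matrix, objective, goals,
            lam=data["lam"], nonneg=data["nonneg"], mu_per_weight=data["mu_per_weight"],
        )
        for update in data["schedule"]:
            session.run_trial(update or None)
        return session


# ---------------------------------------------------------------------------
# Aperture-count sweep
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class SweepRecord:
    """Outcome of one aperture-count setting in a sweep."""

    apertures_per_beam: int
    total_apertures: int
    cost_final: float  # one-sided penalty cost at the delivered (non-negative) weights
    surrogate_cost: float  # WLS surrogate at the unconstrained exact solution


def aperture_sweep(
    phantom: Phantom,
    beams: Sequence[Beam],
    objective: DoseObjective,
    per_beam_counts: Sequence[int],
    seed: int,
    *,
    density: float = 1.0,
    kernel: KernelParameters | None = None,
    margin: float = 6.0,
    bev_spacing: float | None = None,
    lam: float | None = None,
) -> list[SweepRecord]:
    """Optimize the same case at several apertures-per-beam counts.

    Counts must be ascending (>= 1).  The k-aperture set per beam is a prefix
    of the (k+1)-aperture set; counts beyond what the anatomy-derived split
    sequence supports are capped with a logged warning.  The prescribed-dose
    vector and lambda are fixed from the largest set so the surrogate cost is
    comparable — and provably non-increasing — across the sweep.
    """
    counts = [int(k) for k in per_beam_counts]
    if not counts or any(k < 1 for k in counts) or counts != sorted(counts):
        raise ConfigurationError("per_beam_counts must be ascending integers >= 1")
    points = place_sample_points(phantom, density, seed)
    kmax = counts[-1]
    full_aps = design_apertures(
        phantom, beams, margin=margin, min_per_beam=kmax, max_per_beam=kmax,
        bev_spacing=bev_spacing,
    )
    full = compute_dose_matrix(phantom, full_aps, points, kernel)
    reference = full.values @ np.ones(full.n)
    targets, penalties = prescribed_dose_vector(objective, reference, full.row_structures)
    if lam is None:
        lam = default_lambda(full.values, penalties)

    records = []
    for k in counts:
        aps_k = design_apertures(
            phantom, beams, margin=margin, min_per_beam=k, max_per_beam=k,
            bev_spacing=bev_spacing,
        )
        ids = [a.id for a in aps_k]
        sub = full.select_columns(ids)
        result = optimize_weights(
            sub, objective,
            target_doses=targets, point_penalties=penalties,
            lam=lam, nonneg=True,
        )
        records.append(
            SweepRecord(
                apertures_per_beam=k,
                total_apertures=len(ids),
                cost_final=result.cost_final,
                surrogate_cost=result.surrogate_unconstrained,
            )
        )
        logger.info(
            "sweep k=%d: %d apertures, surrogate %.6g, cost %.6g",
            k, len(ids), result.surrogate_unconstrained, result.cost_final,
        )
    return records
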