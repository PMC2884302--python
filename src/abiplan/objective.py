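"""Quadratic penalty objective for aperture-weight optimization.

The plan quality of a set of aperture weights is scored with the one-sided
quadratic penalty cost

    F(d) = sum_i p_i (D_i - PD_i)^2,

summed over sample points i, where a target point contributes when its dose
falls outside [d_min, d_max] and an OAR (or unclassified body) point
contributes only when it exceeds d_max.  p_i is the per-structure penalty.

The exact non-iterative solve works on a symmetric weighted least-squares
surrogate: :func:`prescribed_dose_vector` maps the per-structure goals to one
prescribed dose per point (targets are anchored at the prescription; OAR
points at min(current dose, d_max), so compliant OAR points are not pulled
up toward their limit) and to per-point penalty weights.  The one-sided cost
is used for evaluation and reporting only.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, NamedTuple

import numpy as np

from .errors import ConfigurationError

TARGET_ROLES = ("target",)
OAR_ROLES = ("oar", "body")  # body points behave like a normal-tissue OAR


@dataclasses.dataclass(frozen=True)
class StructureGoal:
    """Dose limits and penalty for one structure.

    Targets need a prescription and satisfy d_min <= prescription <= d_max;
    OARs only carry a maximum dose.  ``penalty`` weights the structure's
    quadratic violation terms (0 removes its points from the solve).
    """

    structure: str
    role: str  # 'target' | 'oar' | 'body'
    d_max: float
    d_min: float | None = None
    prescription: float | None = None
    penalty: float = 1.0

    def __post_init__(self):
        if self.role not in TARGET_ROLES + OAR_ROLES:
            raise ConfigurationError(f"{self.structure}: unknown role {self.role!r}")
        if self.penalty < 0:
            raise ConfigurationError(f"{self.structure}: penalty must be >= 0")
        if self.role in TARGET_ROLES:
            if self.prescription is None:
                raise ConfigurationError(f"target {self.structure} needs a prescription")
            if self.d_min is None:
                object.__setattr__(self, "d_min", self.prescription)
            if not self.d_min <= self.prescription <= self.d_max:
                raise ConfigurationError(
                    f"target {self.structure}: need d_min <= prescription <= d_max"
                )

    @property
    def is_target(self) -> bool:
        return self.role in TARGET_ROLES


@dataclasses.dataclass(frozen=True)
class DoseObjective:
    """One :class:`StructureGoal` per structure appearing in the sample points."""

    goals: tuple[StructureGoal, ...]

    def __post_init__(self):
        names = [g.structure for g in self.goals]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate structure in objective")

    def goal_for(self, structure: str) -> StructureGoal:
        for g in self.goals:
            if g.structure == structure:
                return g
        raise ConfigurationError(f"no goal configured for structure {structure!r}")

    def check_covers(self, labels: Iterable[str]) -> None:
        known = {g.structure for g in self.goals}
        missing = sorted(set(labels) - known)
        if missing:
            raise ConfigurationError(
                "sample points carry structure labels with no goal: " + ", ".join(missing)
            )

    def with_penalties(self, update: dict[str, float]) -> "DoseObjective":
        """A copy with some structures' penalties replaced."""
        unknown = sorted(set(update) - {g.structure for g in self.goals})
        if unknown:
            raise ConfigurationError("penalty update for unknown structure(s): " + ", ".join(unknown))
        for s, p in update.items():
            if p < 0:
                raise ConfigurationError(f"{s}: penalty must be >= 0")
        return DoseObjective(
            tuple(
                dataclasses.replace(g, penalty=float(update.get(g.structure, g.penalty)))
                for g in self.goals
            )
        )

    @property
    def penalties(self) -> dict[str, float]:
        return {g.structure: g.penalty for g in self.goals}


@dataclasses.dataclass(frozen=True)
class CostReport:
    """One-sided quadratic cost, split by structure."""

    total: float
    per_structure: dict[str, float]
    violated_points: int


def cost(doses: np.ndarray, objective: DoseObjective, labels: np.ndarray) -> CostReport:
    """Evaluate the one-sided quadratic penalty cost of a dose distribution."""
    doses = np.asarray(doses, dtype=float)
    labels = np.asarray(labels)
    if not np.isfinite(doses).all():
        raise ConfigurationError("doses must be finite")
    objective.check_covers(labels)
    per: dict[str, float] = {}
    violated = 0
    for g in objective.goals:
        d = doses[labels == g.structure]
        if d.size == 0:
            per[g.structure] = 0.0
            continue
        over = np.maximum(d - g.d_max, 0.0)
        if g.is_target:
            under = np.maximum(g.d_min - d, 0.0)
            sq = over**2 + under**2
        else:
            sq = over**2
        per[g.structure] = float(g.penalty * sq.sum())
        violated += int(np.count_nonzero(sq))
    return CostReport(total=float(sum(per.values())), per_structure=per, violated_points=violated)


def prescribed_dose_vector(
    objective: DoseObjective, reference_doses: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-point prescribed doses and penalty weights for the linear solve.

    ``reference_doses`` are the doses at the uniform-weight starting plan.
    Target points are anchored at the structure prescription; OAR/body points
    at min(reference dose, d_max), so a compliant OAR point is held at its
    current dose rather than being pulled up to the limit by the symmetric
    least-squares fit.  Returns (targets, weights).
    """
    reference_doses = np.asarray(reference_doses, dtype=float)
    labels = np.asarray(labels)
    objective.check_covers(labels)
    targets = np.empty_like(reference_doses)
    weights = np.empty_like(reference_doses)
    for g in objective.goals:
        sel = labels == g.structure
        if g.is_target:
            targets[sel] = g.prescription
        else:
            targets[sel] = np.minimum(reference_doses[sel], g.d_max)
        weights[sel] = g.penalty
    return targets, weights


class PercentReduction(NamedTuple):
    """Relative cost reduction; ``rounded`` is the display (nearest-integer) value."""

    unrounded: float
    rounded: int


def percent_reduction(initial: float, final: float) -> PercentReduction:
    """100 * (initial - final) / initial, with nearest-integer display rounding."""
    if initial <= 0:
        raise ValueError("initial cost must be positive")
    value = 100.0 * (initial - final) / initial
    return PercentReduction(unrounded=value, rounded=int(round(value)))
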