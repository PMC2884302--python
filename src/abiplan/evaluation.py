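"""Plan evaluation: DVH curves, dose-volume indices and delivery metrics.

Volumes are computed over the optimizer's native resolution — the sample
points — so a DVH value V(t) is the percentage of a structure's points
receiving at least t Gy.  Delivery metrics use the minimal monitor-unit
model MU = mu_per_weight * sum(weights); apertures whose weight falls below
a small fraction of the maximum are dropped from the deliverable plan.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple, Sequence

import numpy as np

from .solver import OptimizationResult

DROP_FRACTION = 1e-6  # weights below this fraction of max(weight) are dropped


@dataclasses.dataclass(frozen=True)
class DVHCurve:
    """Cumulative dose-volume curve: volume_percent[i] of the structure
    receives at least dose_bins[i] Gy."""

    structure: str
    dose_bins: np.ndarray  # Gy, ascending, fixed width
    volume_percent: np.ndarray  # in [0, 100], non-increasing


def dvh(doses: np.ndarray, bin_width: float = 0.1, structure: str = "") -> DVHCurve:
    """Cumulative DVH of one structure's point doses."""
    doses = np.asarray(doses, dtype=float)
    if doses.size == 0:
        raise ValueError("empty structure: cannot compute a DVH")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    top = float(doses.max())
    n_bins = int(np.floor(top / bin_width)) + 2  # last edge exceeds max -> V = 0
    edges = np.arange(n_bins) * bin_width
    volume = 100.0 * (doses[None, :] >= edges[:, None]).mean(axis=1)
    return DVHCurve(structure=structure, dose_bins=edges, volume_percent=volume)


def dose_volume_index(
    doses: np.ndarray, kind: str, threshold: float | None = None
) -> float:
    """V_at_dose (percent of points >= threshold), D_max or D_mean."""
    doses = np.asarray(doses, dtype=float)
    if doses.size == 0:
        raise ValueError("empty structure: no dose-volume index")
    if kind == "V_at_dose":
        if threshold is None:
            raise ValueError("V_at_dose needs a threshold")
        return float(100.0 * (doses >= threshold).mean())
    if kind == "D_max":
        return float(doses.max())
    if kind == "D_mean":
        return float(doses.mean())
    raise ValueError(f"unknown index kind {kind!r}")


class IndexValue(NamedTuple):
    structure: str
    kind: str
    threshold: float | None
    value: float


@dataclasses.dataclass(frozen=True)
class PlanMetrics:
    """Plan-level delivery metrics."""

    total_mu: float
    n_apertures: int
    indices: tuple[IndexValue, ...] = ()


def plan_indices(
    doses: np.ndarray,
    labels: np.ndarray,
    specs: Sequence[tuple[str, str, float | None]],
) -> tuple[IndexValue, ...]:
    """Evaluate (structure, kind, threshold) index requests on labeled doses."""
    doses = np.asarray(doses, dtype=float)
    labels = np.asarray(labels)
    out = []
    for structure, kind, threshold in specs:
        d = doses[labels == structure]
        out.append(IndexValue(structure, kind, threshold, dose_volume_index(d, kind, threshold)))
    return tuple(out)


def plan_metrics(
    result: OptimizationResult | np.ndarray,
    mu_per_weight: float = 1.0,
    indices: tuple[IndexValue, ...] = (),
) -> PlanMetrics:
    """Delivery metrics of a plan: total MU and deliverable aperture count."""
    if mu_per_weight <= 0:
        raise ValueError("mu_per_weight must be positive")
    weights = result.weights if isinstance(result, OptimizationResult) else np.asarray(result, float)
    total_mu = float(mu_per_weight * weights.sum())
    wmax = float(weights.max(initial=0.0))
    n_apertures = int(np.count_nonzero(weights > DROP_FRACTION * wmax)) if wmax > 0 else 0
    return PlanMetrics(total_mu=total_mu, n_apertures=n_apertures, indices=indices)


class Reduction(NamedTuple):
    """Percent reduction relative to a reference; ``rounded`` for display."""

    unrounded: float
    rounded: int


@dataclasses.dataclass(frozen=True)
class PlanComparison:
    mu_reduction: Reduction
    aperture_reduction: Reduction
    index_deltas: dict[tuple[str, str, float | None], float]


def compare_plans(test: PlanMetrics, reference: PlanMetrics) -> PlanComparison:
    """Percent MU/aperture reductions of ``test`` relative to ``reference``
    (the beamlet-style comparator), plus per-index differences."""
    if reference.total_mu <= 0 or reference.n_apertures <= 0:
        raise ValueError("reference plan must have positive MU and apertures")

    def _red(ref: float, val: float) -> Reduction:
        u = 100.0 * (ref - val) / ref
        return Reduction(unrounded=u, rounded=int(round(u)))

    ref_idx = {(i.structure, i.kind, i.threshold): i.value for i in reference.indices}
    deltas = {
        (i.structure, i.kind, i.threshold): i.value - ref_idx[(i.structure, i.kind, i.threshold)]
        for i in test.indices
        if (i.structure, i.kind, i.threshold) in ref_idx
    }
    return PlanComparison(
        mu_reduction=_red(reference.total_mu, test.total_mu),
        aperture_reduction=_red(reference.n_apertures, test.n_apertures),
        index_deltas=deltas,
    )
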