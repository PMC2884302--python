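"""Exact (non-iterative) aperture-weight optimization by Gaussian elimination.

The dose-influence system D0 w = d is heavily overdetermined (hundreds to
thousands of sample points vs tens of apertures), so the exact solve is
applied to the weighted least-squares normal equations

    (D0' P D0 + lambda I) w = D0' P d,

where P = diag(per-point penalties) and lambda is a small Tikhonov term that
both smooths the weights and regularizes exactly collinear aperture columns
(a conformal aperture equals the sum of its split sub-apertures).  The n x n
system is solved by bespoke Gaussian elimination with partial pivoting and
back-substitution — no iteration.  Physical non-negativity is enforced by
clamp-and-refit: apertures whose weight comes out negative are removed and
the reduced system re-solved exactly, repeated until all remaining weights
are non-negative (at most n exact solves; full NNLS is available behind an
option flag).
Doses after optimization are reconstructed as D0 w, reversing the forward
operation without any dose-engine call.
"""

from __future__ import annotations

import dataclasses
import time

import numpy as np

from .errors import DegenerateSystemError, SingularSystemError
from .objective import DoseObjective, cost, prescribed_dose_vector
from .phantom import DoseInfluenceMatrix

DEFAULT_PIVOT_RTOL = 1e-12
DEFAULT_LAMBDA_SCALE = 1e-6  # lambda = scale * trace(D'PD) / n


# ---------------------------------------------------------------------------
# System assembly
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class LinearSystem:
    """Normal-equations form of the weighted least-squares problem."""

    A: np.ndarray  # (n, n), symmetric
    b: np.ndarray  # (n,)
    n: int
    conditioning: float

    def __post_init__(self):
        if self.A.shape != (self.n, self.n) or self.b.shape != (self.n,):
            raise DegenerateSystemError("system dimensions are inconsistent")
        if not np.allclose(self.A, self.A.T, rtol=1e-10, atol=0):
            raise DegenerateSystemError("normal matrix is not symmetric")


def _unpack(matrix, labels=None):
    if isinstance(matrix, DoseInfluenceMatrix):
        structures = matrix.row_structures if labels is None else np.asarray(labels)
        return matrix.values, structures, np.asarray(matrix.column_labels)
    values = np.asarray(matrix, dtype=float)
    return values, (None if labels is None else np.asarray(labels)), None


def build_normal_system(
    matrix, targets: np.ndarray, penalties: np.ndarray, lam: float
) -> LinearSystem:
    """Assemble A = D0' P D0 + lambda I and b = D0' P d."""
    D, _, _ = _unpack(matrix)
    targets = np.asarray(targets, dtype=float)
    penalties = np.asarray(penalties, dtype=float)
    m, n = D.shape
    if m < n:
        raise DegenerateSystemError(f"need at least as many points ({m}) as apertures ({n})")
    if targets.shape != (m,) or penalties.shape != (m,):
        raise DegenerateSystemError("targets/penalties must have one entry per point")
    if (penalties < 0).any():
        raise DegenerateSystemError("penalties must be >= 0")
    if not (penalties > 0).any():
        raise DegenerateSystemError("all penalties are zero: nothing constrains the weights")
    if lam < 0:
        raise DegenerateSystemError("lambda must be >= 0")
    PD = penalties[:, None] * D
    A = D.T @ PD + lam * np.eye(n)
    A = (A + A.T) / 2.0
    b = PD.T @ targets
    with np.errstate(all="ignore"):
        conditioning = float(np.linalg.cond(A))
    return LinearSystem(A=A, b=b, n=n, conditioning=conditioning)


def default_lambda(matrix, penalties: np.ndarray) -> float:
    """Tikhonov default: 1e-6 * trace(D0' P D0) / n."""
    D, _, _ = _unpack(matrix)
    penalties = np.asarray(penalties, dtype=float)
    trace = float(np.einsum("ij,i,ij->", D, penalties, D))
    return DEFAULT_LAMBDA_SCALE * trace / D.shape[1]


# ---------------------------------------------------------------------------
# Gaussian elimination
# ---------------------------------------------------------------------------


def gaussian_eliminate(
    A: np.ndarray, b: np.ndarray, pivot_rtol: float = DEFAULT_PIVOT_RTOL
) -> np.ndarray:
    """Solve A x = b by forward elimination with partial pivoting and
    back-substitution.

    Pivoting selects the maximum-magnitude entry of the current column (ties
    broken by lowest row index).  A pivot below ``pivot_rtol * max|A|``
    raises :class:`SingularSystemError` naming the elimination step.
    """
    A = np.array(A, dtype=float)
    b = np.array(b, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    n = A.shape[0]
    if b.shape != (n,):
        raise ValueError("b does not match A")
    scale = float(np.abs(A).max())
    if scale == 0.0:
        raise SingularSystemError("matrix is identically zero", step=0)
    M = np.hstack([A, b[:, None]])
    for k in range(n):
        p = k + int(np.argmax(np.abs(M[k:, k])))  # first max -> lowest row index
        if abs(M[p, k]) < pivot_rtol * scale:
            raise SingularSystemError(
                f"singular system: pivot {M[p, k]:.3e} below threshold at elimination step {k}",
                step=k,
            )
        if p != k:
            M[[k, p]] = M[[p, k]]
        factors = M[k + 1 :, k] / M[k, k]
        M[k + 1 :, k:] -= factors[:, None] * M[k, k:]
    x = np.empty(n)
    for k in range(n - 1, -1, -1):
        x[k] = (M[k, n] - M[k, k + 1 : n] @ x[k + 1 : n]) / M[k, k]
    return x


# ---------------------------------------------------------------------------
# End-to-end optimization
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class OptimizationResult:
    """Optimized aperture weights with reconstructed doses and diagnostics.

    ``cost_initial``/``cost_final`` are one-sided penalty costs at uniform and
    optimized weights when an objective drives the solve; in direct
    prescribed-dose mode they equal the surrogate values.  ``surrogate_*`` are
    the weighted least-squares surrogate values (including the lambda term);
    ``surrogate_unconstrained`` is the surrogate at the exact elimination
    solution before any non-negativity clamping.
    """

    weights: np.ndarray
    doses: np.ndarray
    cost_initial: float
    cost_final: float
    smoothing_lambda: float
    active_apertures: int
    elapsed: float
    surrogate_initial: float
    surrogate_final: float
    surrogate_unconstrained: float
    reference_doses: np.ndarray
    aperture_ids: np.ndarray | None = None
    conditioning: float = float("nan")


def reconstruct_doses(matrix, weights: np.ndarray) -> np.ndarray:
    """Doses at every sample point for the given weights: D0 @ w."""
    D, _, _ = _unpack(matrix)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (D.shape[1],):
        raise ValueError(f"expected {D.shape[1]} weights, got {weights.shape}")
    return D @ weights


def _surrogate(D, targets, penalties, lam, w):
    r = D @ w - targets
    return float(penalties @ (r * r) + lam * (w @ w))


def optimize_weights(
    matrix,
    objective: DoseObjective | None = None,
    labels: np.ndarray | None = None,
    *,
    target_doses: np.ndarray | None = None,
    point_penalties: np.ndarray | None = None,
    lam: float | None = None,
    nonneg: bool = True,
    nnls: bool = False,
    pivot_rtol: float = DEFAULT_PIVOT_RTOL,
) -> OptimizationResult:
    """Optimize aperture weights in one exact solve.

    Reference doses are computed at uniform weights (all 1); the objective is
    translated to per-point prescribed doses and penalties (or taken directly
    from ``target_doses``/``point_penalties``); the normal system is assembled
    and solved by Gaussian elimination.  With ``nonneg``, negative weights are
    clamped to zero and the remaining apertures re-solved once (``nnls=True``
    substitutes a full non-negative least-squares fit instead).
    """
    t0 = time.perf_counter()
    D, row_structures, column_labels = _unpack(matrix, labels)
    m, n = D.shape
    w_uniform = np.ones(n)
    reference = D @ w_uniform

    if target_doses is None:
        if objective is None:
            raise DegenerateSystemError("need an objective or explicit target_doses")
        targets, penalties = prescribed_dose_vector(objective, reference, row_structures)
    else:
        targets = np.asarray(target_doses, dtype=float)
        penalties = (
            np.ones(m) if point_penalties is None else np.asarray(point_penalties, dtype=float)
        )
    n_pos = int(np.count_nonzero(penalties > 0))
    if n_pos == 0:
        raise DegenerateSystemError("no strictly positive penalty rows: problem is infeasible")
    if lam is None:
        lam = default_lambda(D, penalties)
    if n_pos < n and lam == 0:
        raise DegenerateSystemError(
            f"only {n_pos} positive penalty rows for {n} apertures with lambda=0"
        )
    system = build_normal_system(D, targets, penalties, lam)
    w = gaussian_eliminate(system.A, system.b, pivot_rtol=pivot_rtol)
    surrogate_unconstrained = _surrogate(D, targets, penalties, lam, w)

    if nonneg:
        if nnls:
            from scipy.optimize import nnls as _nnls

            sqp = np.sqrt(penalties)
            M = np.vstack([sqp[:, None] * D, np.sqrt(lam) * np.eye(n)])
            y = np.concatenate([sqp * targets, np.zeros(n)])
            w, _ = _nnls(M, y)
        elif (w < 0).any():
            # Successively drop negative apertures and re-solve the reduced
            # exact system until all remaining weights are non-negative.
            # Each pass is one elimination solve; at most n passes.
            keep = np.ones(n, dtype=bool)
            while True:
                neg = keep & (w < 0)
                if not neg.any():
                    break
                keep &= ~neg
                w = np.zeros(n)
                if not keep.any():
                    break
                w[keep] = gaussian_eliminate(
                    system.A[np.ix_(keep, keep)], system.b[keep], pivot_rtol=pivot_rtol
                )

    doses = D @ w
    surrogate_initial = _surrogate(D, targets, penalties, lam, w_uniform)
    surrogate_final = _surrogate(D, targets, penalties, lam, w)
    if objective is not None:
        if row_structures is None:
            raise DegenerateSystemError("structure labels are required with an objective")
        cost_initial = cost(reference, objective, row_structures).total
        cost_final = cost(doses, objective, row_structures).total
    else:
        cost_initial, cost_final = surrogate_initial, surrogate_final

    return OptimizationResult(
        weights=w,
        doses=doses,
        cost_initial=cost_initial,
        cost_final=cost_final,
        smoothing_lambda=float(lam),
        active_apertures=int(np.count_nonzero(w > 0)),
        elapsed=time.perf_counter() - t0,
        surrogate_initial=surrogate_initial,
        surrogate_final=surrogate_final,
        surrogate_unconstrained=surrogate_unconstrained,
        reference_doses=reference,
        aperture_ids=column_labels,
        conditioning=system.conditioning,
    )
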