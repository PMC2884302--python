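"""Plain-text/HDF5 readers and writers and the run manifest.

All CSV files are comma-separated UTF-8 with a mandatory header row; floats
are serialized with Python's shortest round-trip ``repr`` so a write/read
cycle is bit-stable.  Dose matrices can also travel as HDF5 (datasets:
``values``, ``row_labels``, ``row_structures``, ``column_labels``), lossless
at double precision.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .objective import DoseObjective, StructureGoal
from .phantom import Aperture, DoseInfluenceMatrix, SamplePointSet, leaf_intervals
from .replan import PlanGoal
from .solver import OptimizationResult


def _fmt(x: float) -> str:
    return repr(float(x))


# ---------------------------------------------------------------------------
# Sample points
# ---------------------------------------------------------------------------


def write_points_csv(path: str | Path, points: SamplePointSet) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["point_id", "structure", "x_mm", "y_mm", "z_mm"])
        for pid, s, xyz in zip(points.point_ids, points.structure_labels, points.coordinates):
            w.writerow([pid, s, _fmt(xyz[0]), _fmt(xyz[1]), _fmt(xyz[2])])


def read_points_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (point_ids, structures, coordinates)."""
    df = pd.read_csv(path, dtype={"point_id": str, "structure": str}, float_precision="round_trip")
    return (
        df["point_id"].to_numpy(),
        df["structure"].to_numpy(),
        df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# Dose-influence matrix
# ---------------------------------------------------------------------------


def write_matrix_csv(path: str | Path, matrix: DoseInfluenceMatrix) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["point_id", "structure", *map(str, matrix.column_labels)])
        for pid, s, row in zip(matrix.row_labels, matrix.row_structures, matrix.values):
            w.writerow([pid, s, *(_fmt(v) for v in row)])


def read_matrix_csv(path: str | Path) -> DoseInfluenceMatrix:
    df = pd.read_csv(path, dtype={"point_id": str, "structure": str}, float_precision="round_trip")
    cols = [c for c in df.columns if c not in ("point_id", "structure")]
    return DoseInfluenceMatrix(
        values=df[cols].to_numpy(dtype=float),
        row_labels=df["point_id"].to_numpy(),
        row_structures=df["structure"].to_numpy(),
        column_labels=np.asarray(cols),
    )


def write_matrix_hdf5(path: str | Path, matrix: DoseInfluenceMatrix) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=matrix.values)
        st = h5py.string_dtype()
        f.create_dataset("row_labels", data=np.asarray(matrix.row_labels, dtype=object), dtype=st)
        f.create_dataset(
            "row_structures", data=np.asarray(matrix.row_structures, dtype=object), dtype=st
        )
        f.create_dataset(
            "column_labels", data=np.asarray(matrix.column_labels, dtype=object), dtype=st
        )


def read_matrix_hdf5(path: str | Path) -> DoseInfluenceMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        return DoseInfluenceMatrix(
            values=f["values"][()],
            row_labels=f["row_labels"].asstr()[()],
            row_structures=f["row_structures"].asstr()[()],
            column_labels=f["column_labels"].asstr()[()],
        )


def read_matrix(path: str | Path) -> DoseInfluenceMatrix:
    """Dispatch on extension: .h5/.hdf5 or CSV."""
    p = Path(path)
    if p.suffix.lower() in (".h5", ".hdf5"):
        return read_matrix_hdf5(p)
    return read_matrix_csv(p)


# ---------------------------------------------------------------------------
# Constraints / objective
# ---------------------------------------------------------------------------

_GOAL_FIELDS = ("structure", "role", "d_min", "d_max", "prescription", "penalty")


def _goal_from_record(rec: Mapping) -> StructureGoal:
    def opt(key):
        v = rec.get(key)
        if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
            return None
        return float(v)

    return StructureGoal(
        structure=str(rec["structure"]),
        role=str(rec["role"]),
        d_max=float(rec["d_max"]),
        d_min=opt("d_min"),
        prescription=opt("prescription"),
        penalty=float(rec.get("penalty", 1.0)),
    )


def read_constraints(path: str | Path) -> tuple[DoseObjective, tuple[PlanGoal, ...]]:
    """Read an objective (and optional dose-volume plan goals) from JSON or CSV."""
    p = Path(path)
    if p.suffix.lower() == ".json":
        data = json.loads(p.read_text())
        goals = tuple(_goal_from_record(g) for g in data["goals"])
        plan = tuple(PlanGoal(**g) for g in data.get("plan_goals", []))
        return DoseObjective(goals), plan
    df = pd.read_csv(p)
    return DoseObjective(tuple(_goal_from_record(r) for r in df.to_dict("records"))), ()


def write_constraints_json(
    path: str | Path, objective: DoseObjective, plan_goals: Sequence[PlanGoal] = ()
) -> None:
    data = {
        "goals": [
            {f: getattr(g, f) for f in _GOAL_FIELDS} for g in objective.goals
        ],
        "plan_goals": [
            {
                "structure": g.structure, "threshold_gy": g.threshold_gy,
                "limit_percent": g.limit_percent, "direction": g.direction,
            }
            for g in plan_goals
        ],
    }
    Path(path).write_text(json.dumps(data, indent=1))


def check_labels_covered(matrix: DoseInfluenceMatrix, objective: DoseObjective) -> None:
    """Raise :class:`ValidationError` listing matrix structures without a goal."""
    known = {g.structure for g in objective.goals}
    missing = sorted(set(map(str, matrix.row_structures)) - known)
    if missing:
        raise ValidationError(
            "matrix rows carry structure labels missing from the constraints: "
            + ", ".join(missing)
        )


# ---------------------------------------------------------------------------
# Results, doses, DVH
# ---------------------------------------------------------------------------


def write_result_json(
    path: str | Path, result: OptimizationResult, options: Mapping | None = None
) -> None:
    ids = (
        list(map(str, result.aperture_ids))
        if result.aperture_ids is not None
        else [f"aperture_{i}" for i in range(result.weights.size)]
    )
    data = {
        "weights": dict(zip(ids, map(float, result.weights))),
        "cost_initial": result.cost_initial,
        "cost_final": result.cost_final,
        "surrogate_initial": result.surrogate_initial,
        "surrogate_final": result.surrogate_final,
        "smoothing_lambda": result.smoothing_lambda,
        "active_apertures": result.active_apertures,
        "conditioning": result.conditioning,
        "elapsed_seconds": result.elapsed,
        "options": dict(options or {}),
    }
    Path(path).write_text(json.dumps(data, indent=1))


def write_doses_csv(
    path: str | Path, matrix: DoseInfluenceMatrix, doses: np.ndarray
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["point_id", "structure", "dose_gy"])
        for pid, s, d in zip(matrix.row_labels, matrix.row_structures, doses):
            w.writerow([pid, s, _fmt(d)])


def read_doses_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(path, dtype={"point_id": str, "structure": str}, float_precision="round_trip")
    return df["point_id"].to_numpy(), df["structure"].to_numpy(), df["dose_gy"].to_numpy(float)


def write_dvh_csv(path: str | Path, curves: Sequence) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["structure", "dose_gy", "volume_percent"])
        for c in curves:
            for d, v in zip(c.dose_bins, c.volume_percent):
                w.writerow([c.structure, _fmt(d), _fmt(v)])


# ---------------------------------------------------------------------------
# Apertures
# ---------------------------------------------------------------------------


def write_apertures(directory: str | Path, apertures: Sequence[Aperture]) -> None:
    """One 0/1 CSV mask per aperture plus a JSON index with beam metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = []
    for ap in apertures:
        np.savetxt(directory / f"{ap.id}.csv", ap.open_mask.astype(int), fmt="%d", delimiter=",")
        index.append(
            {
                "id": ap.id,
                "gantry_angle": ap.beam.gantry_angle,
                "couch_angle": ap.beam.couch_angle,
                "kind": ap.kind,
                "bev_spacing_mm": [ap.grid.du, ap.grid.dv],
                "open_area_mm2": ap.open_area_mm2,
                "leaf_rows_open": sum(1 for row in leaf_intervals(ap) if row),
            }
        )
    (directory / "index.json").write_text(json.dumps(index, indent=1))


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    seed: int | None,
    inputs: Mapping[str, str | Path],
    options: Mapping,
    outputs: Sequence[str] = (),
) -> None:
    from . import __version__

    manifest = {
        "package": "abiplan",
        "version": __version__,
        "command": command,
        "seed": seed,
        "inputs": {k: {"path": str(p), "sha256": sha256_of(p)} for k, p in inputs.items()},
        "options": dict(options),
        "outputs": list(outputs),
    }
    Path(out_dir, "manifest.json").write_text(json.dumps(manifest, indent=1))
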