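"""Synthetic phantoms, anatomy-based apertures, sample points and dose-influence matrices.

This module replaces the commercial treatment-planning system that an
aperture-weight optimizer would normally sit behind.  It provides

* voxelized phantoms built from parametric shapes (body / target / OARs),
* anatomy-based MLC apertures designed in the beam's-eye view (BEV):
  a target-conformal aperture per beam plus one OAR-blocked aperture per
  organ-at-risk overlapping the target projection, padded with split
  sub-apertures,
* uniform random sample-point placement at a prescribed density (points/cc),
* a primary-photon dose kernel (exponential depth attenuation times the
  aperture transmission blurred by a Gaussian penumbra) that fills the
  dose-influence matrix D0: Gy at each sample point per unit aperture weight.

Conventions: 0-based voxel indices; voxel-centered physical coordinates in mm
with the grid center at the isocenter (0, 0, 0); axes ordered (x, y, z);
gantry angle measured clockwise from the +y axis in the axial plane;
parallel-beam (non-divergent) coplanar geometry.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .errors import GeometryError, InvalidSpecError

logger = logging.getLogger(__name__)

ROLES = ("body", "target", "oar")


# ---------------------------------------------------------------------------
# Phantom
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class Phantom:
    """A voxel grid with labeled binary structure masks.

    Exactly one structure has role ``body``; every other mask is a subset of
    the body and the target is disjoint from every OAR.
    """

    grid_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]  # mm per axis
    structures: Mapping[str, np.ndarray]  # name -> bool mask, shape == grid_shape
    roles: Mapping[str, str]  # name -> body | target | oar

    def __post_init__(self):
        if any(n <= 0 for n in self.grid_shape) or any(s <= 0 for s in self.spacing):
            raise InvalidSpecError("grid_shape and spacing must be positive")
        bodies = [n for n, r in self.roles.items() if r == "body"]
        if len(bodies) != 1:
            raise InvalidSpecError("phantom needs exactly one structure with role 'body'")
        for name, mask in self.structures.items():
            if self.roles.get(name) not in ROLES:
                raise InvalidSpecError(f"structure {name!r} has no valid role")
            if mask.shape != tuple(self.grid_shape) or mask.dtype != bool:
                raise InvalidSpecError(f"mask of {name!r} does not match the grid")
            if not mask.any():
                raise InvalidSpecError(f"structure {name!r} is empty")
        body = self.structures[bodies[0]]
        for name, mask in self.structures.items():
            if name != bodies[0] and (mask & ~body).any():
                raise InvalidSpecError(f"structure {name!r} extends outside the body")
        for tname in self.names_with_role("target"):
            for oname in self.names_with_role("oar"):
                if (self.structures[tname] & self.structures[oname]).any():
                    raise InvalidSpecError(f"target {tname!r} overlaps OAR {oname!r}")

    # -- geometry helpers ---------------------------------------------------

    @property
    def body_name(self) -> str:
        return next(n for n, r in self.roles.items() if r == "body")

    @property
    def body(self) -> np.ndarray:
        return self.structures[self.body_name]

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def volume_cc(self, name: str) -> float:
        return float(self.structures[name].sum()) * self.voxel_volume_cc

    @property
    def structure_volumes(self) -> dict[str, float]:
        return {n: self.volume_cc(n) for n in self.structures}

    def names_with_role(self, role: str) -> list[str]:
        return [n for n, r in self.roles.items() if r == role]

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinates (mm) along each axis, isocenter at 0."""
        return tuple(
            (np.arange(n) - (n - 1) / 2.0) * s
            for n, s in zip(self.grid_shape, self.spacing)
        )

    def coordinates(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(N, 3) mm coordinates of voxel centers, optionally restricted to a mask."""
        if mask is None:
            mask = np.ones(self.grid_shape, dtype=bool)
        idx = np.argwhere(mask)
        offs = (np.asarray(self.grid_shape) - 1) / 2.0
        return (idx - offs) * np.asarray(self.spacing)

    def voxel_index(self, coords: np.ndarray) -> np.ndarray:
        """Nearest voxel index for each mm coordinate row."""
        offs = (np.asarray(self.grid_shape) - 1) / 2.0
        return np.rint(np.asarray(coords) / np.asarray(self.spacing) + offs).astype(int)


def _shape_mask(shape: Mapping, axes) -> np.ndarray:
    """Rasterize one parametric shape onto the voxel grid."""
    x, y, z = axes
    X = x[:, None, None]
    Y = y[None, :, None]
    Z = z[None, None, :]
    kind = shape.get("type")
    if kind == "cylinder":  # axis along z
        cx, cy = shape["center"]
        r = float(shape["radius"])
        m = (X - cx) ** 2 + (Y - cy) ** 2 <= r**2
        m = np.broadcast_to(m, (x.size, y.size, z.size)).copy()
        if "z_range" in shape:
            z0, z1 = shape["z_range"]
            m &= (Z >= z0) & (Z <= z1)
        return m
    if kind == "sphere":
        cx, cy, cz = shape["center"]
        r = float(shape["radius"])
        return (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= r**2
    if kind == "ellipsoid":
        cx, cy, cz = shape["center"]
        ax, ay, az = shape["semiaxes"]
        return ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2 <= 1.0
    if kind == "box":
        lo, hi = shape["lo"], shape["hi"]
        return (
            (X >= lo[0]) & (X <= hi[0])
            & (Y >= lo[1]) & (Y <= hi[1])
            & (Z >= lo[2]) & (Z <= hi[2])
        )
    if kind == "annulus_sector":
        # Horseshoe: cylindrical annulus with an angular gap.  The gap
        # direction uses the gantry convention (degrees clockwise from +y).
        cx, cy = shape["center"]
        r_in, r_out = float(shape["r_inner"]), float(shape["r_outer"])
        if not 0 <= r_in < r_out:
            raise InvalidSpecError("annulus_sector needs 0 <= r_inner < r_outer")
        rsq = (X - cx) ** 2 + (Y - cy) ** 2
        m = (rsq >= r_in**2) & (rsq <= r_out**2)
        m = np.broadcast_to(m, (x.size, y.size, z.size)).copy()
        gap_dir = float(shape.get("gap_direction_deg", 0.0))
        gap = float(shape.get("gap_angle_deg", 0.0))
        if gap > 0:
            phi = np.degrees(np.arctan2(X - cx, Y - cy))  # clockwise from +y
            dphi = (phi - gap_dir + 180.0) % 360.0 - 180.0
            m &= np.broadcast_to(np.abs(dphi) > gap / 2.0, m.shape)
        if "z_range" in shape:
            z0, z1 = shape["z_range"]
            m &= (Z >= z0) & (Z <= z1)
        return m
    raise InvalidSpecError(f"unknown shape type {kind!r}")


def build_phantom(spec: Mapping) -> Phantom:
    """Build a :class:`Phantom` from a parametric JSON-style specification.

    ``spec`` holds ``grid_shape`` (3 ints), ``spacing_mm`` (3 floats) and a
    ``structures`` list of ``{"name", "role", "shape"}`` entries.  Non-body
    structures are clipped to the body; a structure entirely outside the body,
    an empty structure, or a target overlapping an OAR is an error.
    """
    grid_shape = tuple(int(n) for n in spec["grid_shape"])
    spacing = tuple(float(s) for s in spec["spacing_mm"])
    if any(n <= 0 for n in grid_shape) or any(s <= 0 for s in spacing):
        raise InvalidSpecError("grid_shape and spacing_mm must be positive")
    dummy = Phantom.__new__(Phantom)  # only for axes(); no validation yet
    object.__setattr__(dummy, "grid_shape", grid_shape)
    object.__setattr__(dummy, "spacing", spacing)
    axes = dummy.axes()

    entries = list(spec["structures"])
    bodies = [e for e in entries if e.get("role") == "body"]
    if len(bodies) != 1:
        raise InvalidSpecError("specification needs exactly one body structure")
    body_mask = _shape_mask(bodies[0]["shape"], axes)
    if not body_mask.any():
        raise InvalidSpecError("body structure is empty")

    structures: dict[str, np.ndarray] = {bodies[0]["name"]: body_mask}
    roles: dict[str, str] = {bodies[0]["name"]: "body"}
    for e in entries:
        if e is bodies[0]:
            continue
        name, role = e["name"], e["role"]
        if role not in ("target", "oar"):
            raise InvalidSpecError(f"structure {name!r}: role must be target or oar")
        if name in structures:
            raise InvalidSpecError(f"duplicate structure name {name!r}")
        raw = _shape_mask(e["shape"], axes)
        if not raw.any():
            raise InvalidSpecError(f"structure {name!r} is empty")
        mask = raw & body_mask
        if not mask.any():
            raise InvalidSpecError(f"structure {name!r} lies outside the body")
        structures[name] = mask
        roles[name] = role
    return Phantom(grid_shape, spacing, structures, roles)


# ---------------------------------------------------------------------------
# Beams and beam's-eye-view geometry
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class Beam:
    """A treatment beam. Gantry angle is degrees clockwise from +y (axial plane)."""

    gantry_angle: float
    couch_angle: float = 0.0
    source_axis_distance: float = 1000.0  # mm; informational under parallel geometry
    isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def direction_to_source(self) -> np.ndarray:
        """Unit vector pointing from the isocenter toward the source."""
        if self.couch_angle != 0.0:
            raise GeometryError("only coplanar beams (couch_angle = 0) are supported")
        t = math.radians(self.gantry_angle)
        return np.array([math.sin(t), math.cos(t), 0.0])

    def bev_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """In-plane (u) and longitudinal (v) unit vectors of the BEV plane."""
        if self.couch_angle != 0.0:
            raise GeometryError("only coplanar beams (couch_angle = 0) are supported")
        t = math.radians(self.gantry_angle)
        return np.array([math.cos(t), -math.sin(t), 0.0]), np.array([0.0, 0.0, 1.0])


@dataclasses.dataclass(frozen=True)
class BEVGrid:
    """Pixel grid of the beam's-eye-view plane at the isocenter."""

    nu: int
    nv: int
    du: float  # mm
    dv: float  # mm

    @property
    def u0(self) -> float:
        return -(self.nu - 1) / 2.0 * self.du

    @property
    def v0(self) -> float:
        return -(self.nv - 1) / 2.0 * self.dv

    def to_pixels(self, u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return (np.asarray(u) - self.u0) / self.du, (np.asarray(v) - self.v0) / self.dv


def bev_grid(phantom: Phantom, spacing: float | None = None) -> BEVGrid:
    """A BEV grid large enough to hold the phantom under any gantry rotation."""
    if spacing is None:
        spacing = float(min(phantom.spacing))
    lx, ly, lz = (n * s for n, s in zip(phantom.grid_shape, phantom.spacing))
    ru = math.hypot(lx, ly) / 2.0
    rv = lz / 2.0
    nu = 2 * math.ceil(ru / spacing) + 1
    nv = 2 * math.ceil(rv / spacing) + 1
    return BEVGrid(nu, nv, spacing, spacing)


def project_mask(phantom: Phantom, mask: np.ndarray, beam: Beam, grid: BEVGrid) -> np.ndarray:
    """Parallel-beam projection of a voxel mask onto the BEV pixel grid."""
    coords = phantom.coordinates(mask)
    if coords.shape[0] == 0:
        return np.zeros((grid.nu, grid.nv), dtype=bool)
    eu, ev = beam.bev_axes()
    u = coords @ eu
    v = coords @ ev
    pu, pv = grid.to_pixels(u, v)
    iu = np.clip(np.rint(pu).astype(int), 0, grid.nu - 1)
    iv = np.clip(np.rint(pv).astype(int), 0, grid.nv - 1)
    proj = np.zeros((grid.nu, grid.nv), dtype=bool)
    proj[iu, iv] = True
    # rotation of a 2 mm lattice onto a 2 mm raster can leave pinholes
    return ndimage.binary_closing(proj, structure=np.ones((3, 3), bool))


# ---------------------------------------------------------------------------
# Apertures
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class Aperture:
    """A binary MLC aperture in the beam's-eye view."""

    id: str
    beam: Beam
    open_mask: np.ndarray  # bool, shape (grid.nu, grid.nv)
    grid: BEVGrid
    kind: str  # 'target-conformal' | 'oar-blocked'

    def __post_init__(self):
        if not self.open_mask.any():
            raise InvalidSpecError(f"aperture {self.id!r} has no open element")

    @property
    def open_area_mm2(self) -> float:
        return float(self.open_mask.sum()) * self.grid.du * self.grid.dv


def _disk(radius_px: float) -> np.ndarray:
    r = max(int(math.ceil(radius_px)), 1)
    y, x = np.ogrid[-r : r + 1, -r : r + 1]
    return x**2 + y**2 <= radius_px**2


def _bisect_mask(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
    """Split a BEV mask into two halves of roughly equal open area along u."""
    col_area = mask.sum(axis=1)
    open_cols = np.flatnonzero(col_area)
    if open_cols.size < 2:
        return None
    cum = np.cumsum(col_area)
    half = cum[-1] / 2.0
    cut = int(np.searchsorted(cum, half)) + 1
    cut = min(max(cut, open_cols[0] + 1), open_cols[-1])  # both halves non-empty
    left = mask.copy()
    left[cut:, :] = False
    right = mask.copy()
    right[:cut, :] = False
    if not left.any() or not right.any():
        return None
    return left, right


def _split_sequence(mask: np.ndarray) -> Iterator[np.ndarray]:
    """Deterministic breadth-first bisection of an aperture mask.

    Yields sub-apertures in a fixed order so that the first k splits of a mask
    are always a prefix of the first k+1 — this is what makes aperture-count
    sweeps nested.
    """
    queue = [mask]
    while queue:
        halves = _bisect_mask(queue.pop(0))
        if halves is None:
            continue
        for h in halves:
            yield h
            queue.append(h)


def design_apertures(
    phantom: Phantom,
    beams: Sequence[Beam],
    margin: float = 6.0,
    min_per_beam: int = 3,
    max_per_beam: int = 5,
    bev_spacing: float | None = None,
) -> list[Aperture]:
    """Design anatomy-based apertures for every beam.

    Per beam: the first aperture conforms to the target projection dilated by
    ``margin`` (mm); one additional aperture per OAR whose projection overlaps
    the target's blocks that OAR; split sub-apertures of the conformal field
    pad the count up to ``min_per_beam``; the list is truncated at
    ``max_per_beam``.  If the split sequence is exhausted the beam is capped
    below ``min_per_beam`` with a logged warning.
    """
    if not 1 <= min_per_beam <= max_per_beam:
        raise InvalidSpecError("need 1 <= min_per_beam <= max_per_beam")
    angles = [b.gantry_angle for b in beams]
    if len(set(angles)) != len(angles):
        raise InvalidSpecError("gantry angles within a plan must be distinct")
    targets = phantom.names_with_role("target")
    if not targets:
        raise InvalidSpecError("phantom has no target structure")
    target_mask = np.zeros(phantom.grid_shape, dtype=bool)
    for t in targets:
        target_mask |= phantom.structures[t]
    grid = bev_grid(phantom, bev_spacing)
    dilate = _disk(margin / grid.du) if margin > 0 else None

    apertures: list[Aperture] = []
    for beam in beams:
        tag = f"g{beam.gantry_angle:05.1f}"
        tproj = project_mask(phantom, target_mask, beam, grid)
        if not tproj.any():
            raise GeometryError(f"target projection is empty for beam {tag}")
        conformal = (
            ndimage.binary_dilation(tproj, structure=dilate) if dilate is not None else tproj
        )
        per_beam = [Aperture(f"{tag}_conformal", beam, conformal, grid, "target-conformal")]
        for oar in sorted(phantom.names_with_role("oar")):
            oproj = project_mask(phantom, phantom.structures[oar], beam, grid)
            if not (oproj & tproj).any():
                continue
            blocked = conformal & ~oproj
            if blocked.any():
                per_beam.append(
                    Aperture(f"{tag}_block-{oar}", beam, blocked, grid, "oar-blocked")
                )
        splits = _split_sequence(conformal)
        i = 0
        while len(per_beam) < min_per_beam:
            piece = next(splits, None)
            if piece is None:
                logger.warning(
                    "beam %s: split sequence exhausted at %d apertures (min_per_beam=%d)",
                    tag, len(per_beam), min_per_beam,
                )
                break
            i += 1
            per_beam.append(Aperture(f"{tag}_split{i}", beam, piece, grid, "target-conformal"))
        apertures.extend(per_beam[:max_per_beam])
    return apertures


def leaf_intervals(aperture: Aperture) -> list[list[tuple[float, float]]]:
    """Collapse a BEV mask to per-row MLC leaf openings.

    For each v-row, returns the list of open (u_start, u_end) intervals in mm
    (pixel-edge positions).  Purely an export convenience; the optimizer works
    on masks.
    """
    g = aperture.grid
    rows = []
    for j in range(g.nv):
        col = aperture.open_mask[:, j]
        edges = np.diff(np.concatenate(([0], col.view(np.int8), [0])))
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        rows.append(
            [
                (g.u0 + (s - 0.5) * g.du, g.u0 + (e - 0.5) * g.du)
                for s, e in zip(starts, ends)
            ]
        )
    return rows


# ---------------------------------------------------------------------------
# Sample points
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class SamplePointSet:
    """Dose-evaluation points with structure labels.

    Each point lies inside the mask of its labeled structure; per structure
    there are round(density * sampling volume) points, minimum 1.
    """

    coordinates: np.ndarray  # (N, 3) mm
    structure_labels: np.ndarray  # (N,) str
    point_ids: np.ndarray  # (N,) str
    density: float  # points per cc
    seed: int

    def __post_init__(self):
        n = self.coordinates.shape[0]
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise InvalidSpecError("coordinates must be (N, 3)")
        if len(self.structure_labels) != n or len(self.point_ids) != n:
            raise InvalidSpecError("labels/ids must match the number of points")

    def __len__(self) -> int:
        return self.coordinates.shape[0]


def sampling_regions(phantom: Phantom) -> dict[str, np.ndarray]:
    """Per-structure sampling masks: the body region excludes target and OARs
    so every point carries a unique label."""
    regions: dict[str, np.ndarray] = {}
    non_body = np.zeros(phantom.grid_shape, dtype=bool)
    for name in phantom.structures:
        if name != phantom.body_name:
            non_body |= phantom.structures[name]
    for name, mask in phantom.structures.items():
        regions[name] = (mask & ~non_body) if name == phantom.body_name else mask
    return regions


def sampling_volumes(phantom: Phantom) -> dict[str, float]:
    """cc of each structure's sampling region (body excludes target/OARs)."""
    vv = phantom.voxel_volume_cc
    return {n: float(m.sum()) * vv for n, m in sampling_regions(phantom).items()}


def place_sample_points(phantom: Phantom, density: float, seed: int) -> SamplePointSet:
    """Uniform random sample points in each structure at ``density`` points/cc.

    Per structure, round(density * volume) points (minimum 1) are drawn
    uniformly inside the structure's sampling region: a voxel is chosen
    uniformly, then the point is jittered uniformly within that voxel.
    Deterministic for a fixed seed.
    """
    if density <= 0:
        raise InvalidSpecError("sampling density must be positive")
    rng = np.random.default_rng(seed)
    spacing = np.asarray(phantom.spacing)
    offs = (np.asarray(phantom.grid_shape) - 1) / 2.0
    vv = phantom.voxel_volume_cc
    coords, labels, ids = [], [], []
    for name, region in sampling_regions(phantom).items():
        flat = np.flatnonzero(region)
        if flat.size == 0:
            raise InvalidSpecError(f"sampling region of {name!r} is empty")
        n_pts = max(1, round(density * flat.size * vv))
        chosen = rng.choice(flat, size=n_pts, replace=True)
        idx = np.stack(np.unravel_index(chosen, phantom.grid_shape), axis=1)
        jitter = rng.uniform(-0.5, 0.5, size=(n_pts, 3))
        coords.append((idx - offs + jitter) * spacing)
        labels.extend([name] * n_pts)
        ids.extend(f"{name}_{i:04d}" for i in range(n_pts))
    return SamplePointSet(
        coordinates=np.concatenate(coords, axis=0),
        structure_labels=np.asarray(labels),
        point_ids=np.asarray(ids),
        density=float(density),
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Dose-influence matrix
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class KernelParameters:
    """Primary-photon dose kernel parameters.

    phi0: Gy per unit aperture weight at zero depth (open field).
    mu: linear attenuation coefficient, 1/cm (~6 MV photons).
    sigma: isotropic Gaussian penumbra width in the BEV plane, mm.
    step: ray-marching step for the depth integral, mm.
    """

    phi0: float = 2.0
    mu: float = 0.05
    sigma: float = 3.0
    step: float = 1.0


@dataclasses.dataclass(frozen=True)
class DoseInfluenceMatrix:
    """m x n matrix of dose (Gy) per unit aperture weight.

    Rows are sample points (with structure labels), columns are apertures.
    Entries are non-negative and every column irradiates at least one point.
    """

    values: np.ndarray  # (m, n) float
    row_labels: np.ndarray  # (m,) point ids
    row_structures: np.ndarray  # (m,) structure names
    column_labels: np.ndarray  # (n,) aperture ids

    def __post_init__(self):
        v = self.values
        if v.ndim != 2:
            raise InvalidSpecError("dose matrix must be 2-D")
        if len(self.row_labels) != v.shape[0] or len(self.row_structures) != v.shape[0]:
            raise InvalidSpecError("row labels must match the matrix")
        if len(self.column_labels) != v.shape[1]:
            raise InvalidSpecError("column labels must match the matrix")
        if not np.isfinite(v).all() or (v < 0).any():
            raise InvalidSpecError("dose matrix entries must be finite and >= 0")
        dead = np.flatnonzero(v.max(axis=0) <= 0)
        if dead.size:
            names = ", ".join(np.asarray(self.column_labels)[dead][:5])
            raise InvalidSpecError(f"aperture column(s) deliver no dose: {names}")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def select_columns(self, ids: Sequence[str]) -> "DoseInfluenceMatrix":
        order = {c: i for i, c in enumerate(np.asarray(self.column_labels))}
        cols = [order[i] for i in ids]
        return DoseInfluenceMatrix(
            values=np.ascontiguousarray(self.values[:, cols]),
            row_labels=self.row_labels,
            row_structures=self.row_structures,
            column_labels=np.asarray(list(ids)),
        )


def _depths_mm(phantom: Phantom, coords: np.ndarray, beam: Beam, step: float) -> np.ndarray:
    """Radiological depth (mm of body tissue) from the surface to each point
    along the ray toward the source, by fixed-step marching."""
    direction = beam.direction_to_source()
    extent = math.sqrt(sum((n * s) ** 2 for n, s in zip(phantom.grid_shape, phantom.spacing)))
    n_steps = int(math.ceil(extent / step))
    t = (np.arange(n_steps) + 0.5) * step
    pos = coords[:, None, :] + t[None, :, None] * direction[None, None, :]
    offs = (np.asarray(phantom.grid_shape) - 1) / 2.0
    idx = np.rint(pos / np.asarray(phantom.spacing) + offs).astype(int)
    inside = np.ones(idx.shape[:2], dtype=bool)
    for ax in range(3):
        inside &= (idx[..., ax] >= 0) & (idx[..., ax] < phantom.grid_shape[ax])
    idx_c = np.clip(idx, 0, np.asarray(phantom.grid_shape) - 1)
    in_body = phantom.body[idx_c[..., 0], idx_c[..., 1], idx_c[..., 2]] & inside
    return step * in_body.sum(axis=1)


def compute_dose_matrix(
    phantom: Phantom,
    apertures: Sequence[Aperture],
    points: SamplePointSet,
    kernel: KernelParameters | None = None,
) -> DoseInfluenceMatrix:
    """Fill the dose-influence matrix with the primary-photon kernel.

    entry(m, n) = phi0 * exp(-mu * depth_n(m)) * T_n(m), where depth is the
    in-body path length from the surface to point m along beam n's axis and
    T is the aperture transmission (open mask blurred by a Gaussian penumbra
    of width sigma) at the point's BEV projection.
    """
    kernel = kernel or KernelParameters()
    coords = points.coordinates
    vox = phantom.voxel_index(coords)
    inside = np.all((vox >= 0) & (vox < np.asarray(phantom.grid_shape)), axis=1)
    if not inside.all() or not phantom.body[vox[:, 0], vox[:, 1], vox[:, 2]].all():
        raise GeometryError("all sample points must lie inside the body")

    beams: dict[float, Beam] = {}
    for ap in apertures:
        beams.setdefault(ap.beam.gantry_angle, ap.beam)
    depth_cm = {
        angle: _depths_mm(phantom, coords, beam, kernel.step) / 10.0
        for angle, beam in beams.items()
    }
    uv_pix: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    for angle, beam in beams.items():
        eu, ev = beam.bev_axes()
        uv_pix[angle] = (coords @ eu, coords @ ev)

    values = np.empty((len(points), len(apertures)), dtype=float)
    for j, ap in enumerate(apertures):
        sig = (kernel.sigma / ap.grid.du, kernel.sigma / ap.grid.dv)
        blurred = ndimage.gaussian_filter(
            ap.open_mask.astype(float), sigma=sig, mode="constant", cval=0.0
        )
        u, v = uv_pix[ap.beam.gantry_angle]
        pu, pv = ap.grid.to_pixels(u, v)
        trans = ndimage.map_coordinates(
            blurred, np.vstack([pu, pv]), order=1, mode="constant", cval=0.0
        )
        np.clip(trans, 0.0, 1.0, out=trans)
        values[:, j] = kernel.phi0 * np.exp(-kernel.mu * depth_cm[ap.beam.gantry_angle]) * trans

    return DoseInfluenceMatrix(
        values=values,
        row_labels=points.point_ids,
        row_structures=points.structure_labels,
        column_labels=np.asarray([ap.id for ap in apertures]),
    )
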