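"""Phantom construction, aperture design, sampling and the dose kernel."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import abiplan as ab
from abiplan.errors import GeometryError, InvalidSpecError
from abiplan.phantom import bev_grid, project_mask, sampling_volumes


# ---------------------------------------------------------------------------
# build_phantom
# ---------------------------------------------------------------------------


def _sphere_spec(radius=10.0, spacing=1.0, box=40):
    return {
        "grid_shape": [box, box, box],
        "spacing_mm": [spacing] * 3,
        "structures": [
            {"name": "body", "role": "body",
             "shape": {"type": "box", "lo": [-19, -19, -19], "hi": [19, 19, 19]}},
            {"name": "ptv", "role": "target",
             "shape": {"type": "sphere", "center": [0, 0, 0], "radius": radius}},
        ],
    }


def test_mini_phantom_invariants(mini_phantom):
    body = mini_phantom.body
    for name, mask in mini_phantom.structures.items():
        assert mask.any()
        assert not (mask & ~body).any(), f"{name} leaves the body"
    ptv = mini_phantom.structures["ptv"]
    for oar in mini_phantom.names_with_role("oar"):
        assert not (ptv & mini_phantom.structures[oar]).any()
    # horseshoe target wraps the cord: cord centroid sits in the target's bounding box
    assert mini_phantom.volume_cc("ptv") > mini_phantom.volume_cc("cord")


def test_structure_volume_is_voxel_count_times_voxel_volume(mini_phantom):
    for name, mask in mini_phantom.structures.items():
        assert mini_phantom.volume_cc(name) == pytest.approx(
            mask.sum() * mini_phantom.voxel_volume_cc
        )


def test_sphere_volume_matches_analytic():
    ph = ab.build_phantom(_sphere_spec(radius=10.0, spacing=1.0))
    analytic_cc = 4.0 / 3.0 * math.pi * 10.0**3 / 1000.0  # 4.19 cc
    assert ph.volume_cc("ptv") == pytest.approx(analytic_cc, rel=0.05)


@pytest.mark.parametrize(
    "mutate",
    [
        # target fully outside the body
        lambda s: s["structures"][1]["shape"].update(center=[200, 200, 200]),
        # target overlapping an OAR
        lambda s: s["structures"].append(
            {"name": "oar1", "role": "oar",
             "shape": {"type": "sphere", "center": [0, 0, 0], "radius": 5.0}}
        ),
        # empty structure
        lambda s: s["structures"][1]["shape"].update(radius=0.2),
    ],
)
def test_invalid_specs_rejected(mutate):
    spec = _sphere_spec(radius=10.0, spacing=2.0, box=30)
    spec["grid_shape"] = [30, 30, 30]
    mutate(spec)
    with pytest.raises(InvalidSpecError):
        ab.build_phantom(spec)


# ---------------------------------------------------------------------------
# design_apertures
# ---------------------------------------------------------------------------


def test_case_a_aperture_count_in_expected_range():
    ph = ab.build_phantom(ab.presets.phantom_spec("case-a"))
    beams = ab.presets.beams("case-a")
    aps = ab.design_apertures(ph, beams, margin=6.0, min_per_beam=3, max_per_beam=5)
    assert 21 <= len(aps) <= 35  # 7 beams x 3..5 apertures


def test_blocked_apertures_are_strict_subsets(mini_apertures):
    by_beam = {}
    for ap in mini_apertures:
        by_beam.setdefault(ap.beam.gantry_angle, []).append(ap)
    for aps in by_beam.values():
        conformal = aps[0]
        assert conformal.kind == "target-conformal"
        for ap in aps[1:]:
            assert not (ap.open_mask & ~conformal.open_mask).any()
            if ap.kind == "oar-blocked":
                assert ap.open_mask.sum() < conformal.open_mask.sum()


def test_beam_without_oar_overlap_yields_conformal_splits():
    spec = _sphere_spec(radius=12.0, spacing=2.0, box=30)
    spec["grid_shape"] = [30, 30, 30]
    ph = ab.build_phantom(spec)
    aps = ab.design_apertures(ph, [ab.Beam(0.0)], min_per_beam=3, max_per_beam=5)
    assert len(aps) == 3
    assert all(a.kind == "target-conformal" for a in aps)
    # splits partition the conformal aperture
    assert np.array_equal(aps[1].open_mask | aps[2].open_mask, aps[0].open_mask)
    assert not (aps[1].open_mask & aps[2].open_mask).any()


def test_duplicate_gantry_angles_rejected(mini_phantom):
    with pytest.raises(InvalidSpecError):
        ab.design_apertures(mini_phantom, [ab.Beam(0.0), ab.Beam(0.0)])


def test_noncoplanar_beam_rejected(mini_phantom):
    with pytest.raises(GeometryError):
        ab.design_apertures(mini_phantom, [ab.Beam(0.0, couch_angle=30.0)])


def test_empty_projection_is_geometry_error(mini_phantom):
    empty = np.zeros(mini_phantom.grid_shape, dtype=bool)
    grid = bev_grid(mini_phantom)
    proj = project_mask(mini_phantom, empty, ab.Beam(0.0), grid)
    assert not proj.any()  # the design loop raises GeometryError on this


# ---------------------------------------------------------------------------
# place_sample_points
# ---------------------------------------------------------------------------


def test_sample_point_counts_follow_density(mini_phantom, mini_points):
    vols = sampling_volumes(mini_phantom)
    for name, vol in vols.items():
        expected = max(1, round(1.0 * vol))
        assert (mini_points.structure_labels == name).sum() == expected


def test_minimum_one_point_for_tiny_structure():
    spec = _sphere_spec(radius=4.0, spacing=1.0, box=20)
    spec["grid_shape"] = [20, 20, 20]
    spec["structures"][0]["shape"] = {"type": "box", "lo": [-9, -9, -9], "hi": [9, 9, 9]}
    ph = ab.build_phantom(spec)
    pts = ab.place_sample_points(ph, density=1.0, seed=1)
    assert (pts.structure_labels == "ptv").sum() == 1  # 0.27 cc -> min rule


def test_doubling_density_doubles_counts(mini_phantom):
    p1 = ab.place_sample_points(mini_phantom, 1.0, seed=3)
    p2 = ab.place_sample_points(mini_phantom, 2.0, seed=3)
    for name in mini_phantom.structures:
        n1 = (p1.structure_labels == name).sum()
        n2 = (p2.structure_labels == name).sum()
        assert abs(n2 - 2 * n1) <= 1


def test_sampling_is_deterministic_and_inside_masks(mini_phantom):
    a = ab.place_sample_points(mini_phantom, 1.0, seed=11)
    b = ab.place_sample_points(mini_phantom, 1.0, seed=11)
    assert np.array_equal(a.coordinates, b.coordinates)
    assert np.array_equal(a.structure_labels, b.structure_labels)
    idx = mini_phantom.voxel_index(a.coordinates)
    for name, mask in mini_phantom.structures.items():
        sel = a.structure_labels == name
        assert mask[idx[sel, 0], idx[sel, 1], idx[sel, 2]].all()


# ---------------------------------------------------------------------------
# compute_dose_matrix
# ---------------------------------------------------------------------------


def _slab_case():
    """100 mm slab of tissue irradiated from +y with a wide-open aperture."""
    spec = {
        "grid_shape": [60, 60, 20],
        "spacing_mm": [2.0, 2.0, 2.0],
        "structures": [
            {"name": "body", "role": "body",
             "shape": {"type": "box", "lo": [-50, -50, -16], "hi": [50, 50, 16]}},
            {"name": "ptv", "role": "target",
             "shape": {"type": "box", "lo": [-30, -50, -10], "hi": [30, 50, 10]}},
        ],
    }
    ph = ab.build_phantom(spec)
    beam = ab.Beam(0.0)  # source toward +y
    grid = bev_grid(ph)
    open_mask = np.ones((grid.nu, grid.nv), dtype=bool)
    from abiplan.phantom import Aperture

    ap = Aperture("open", beam, open_mask, grid, "target-conformal")
    return ph, ap


def _point_set(coords):
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = coords.shape[0]
    return ab.SamplePointSet(
        coordinates=coords,
        structure_labels=np.array(["ptv"] * n),
        point_ids=np.array([f"p{i}" for i in range(n)]),
        density=1.0,
        seed=0,
    )


def test_attenuation_matches_closed_form():
    ph, ap = _slab_case()
    kernel = ab.KernelParameters(phi0=1.0, mu=0.05, sigma=3.0, step=0.5)
    # slab surface at y = +50 mm; depths 1 mm and 99 mm
    pts = _point_set([[0.0, 49.0, 0.0], [0.0, -49.0, 0.0]])
    m = ab.compute_dose_matrix(ph, [ap], pts, kernel)
    assert m.values[0, 0] == pytest.approx(math.exp(-0.05 * 0.1), rel=0.01)
    assert m.values[1, 0] == pytest.approx(math.exp(-0.05 * 9.9), rel=0.02)


def test_penumbra_tail_is_negligible_far_from_aperture():
    ph, _ = _slab_case()
    beam = ab.Beam(0.0)
    grid = bev_grid(ph)
    mask = np.zeros((grid.nu, grid.nv), dtype=bool)
    cu, cv = grid.nu // 2, grid.nv // 2
    mask[cu - 3 : cu + 4, cv - 3 : cv + 4] = True  # small central field
    from abiplan.phantom import Aperture

    ap = Aperture("small", beam, mask, grid, "target-conformal")
    kernel = ab.KernelParameters(phi0=1.0, mu=0.05, sigma=3.0)
    # one point under the field (keeps the column alive), one far off axis
    pts = _point_set([[0.0, 49.0, 0.0], [40.0, 49.0, 0.0]])  # 40 mm > 10 sigma off edge
    m = ab.compute_dose_matrix(ph, [ap], pts, kernel)
    assert m.values[0, 0] > 0.5
    assert m.values[1, 0] < 1e-6


def test_point_outside_body_raises():
    ph, ap = _slab_case()
    with pytest.raises(GeometryError):
        ab.compute_dose_matrix(ph, [ap], _point_set([[0.0, 55.0, 0.0]]))


def test_shrinking_aperture_never_increases_dose(mini_phantom, mini_apertures, mini_points):
    from abiplan.phantom import Aperture

    ap = mini_apertures[0]
    shrunk_mask = ap.open_mask.copy()
    open_idx = np.argwhere(shrunk_mask)
    shrunk_mask[tuple(open_idx[: len(open_idx) // 2].T)] = False
    shrunk = Aperture("shrunk", ap.beam, shrunk_mask, ap.grid, ap.kind)
    m = ab.compute_dose_matrix(mini_phantom, [ap, shrunk], mini_points)
    assert (m.values[:, 1] <= m.values[:, 0] + 1e-12).all()


def test_dose_matrix_bit_reproducible(mini_phantom, mini_apertures, mini_points):
    a = ab.compute_dose_matrix(mini_phantom, mini_apertures, mini_points)
    b = ab.compute_dose_matrix(mini_phantom, mini_apertures, mini_points)
    assert np.array_equal(a.values, b.values)


@given(seed=st.integers(0, 10_000))
def test_dose_matrix_nonneg_finite_over_random_phantoms(seed):
    rng = np.random.default_rng(seed)
    r_t = rng.uniform(6.0, 12.0)
    off = rng.uniform(-6.0, 6.0, size=2)
    spec = {
        "grid_shape": [24, 24, 16],
        "spacing_mm": [3.0, 3.0, 3.0],
        "structures": [
            {"name": "body", "role": "body",
             "shape": {"type": "cylinder", "center": [0.0, 0.0], "radius": 32.0}},
            {"name": "ptv", "role": "target",
             "shape": {"type": "sphere", "center": [off[0], off[1], 0.0], "radius": r_t}},
        ],
    }
    ph = ab.build_phantom(spec)
    aps = ab.design_apertures(ph, [ab.Beam(0.0), ab.Beam(90.0)], min_per_beam=1, max_per_beam=2)
    pts = ab.place_sample_points(ph, density=0.5, seed=seed)
    m = ab.compute_dose_matrix(ph, aps, pts)
    assert np.isfinite(m.values).all()
    assert (m.values >= 0).all()
    assert (m.values.max(axis=0) > 0).all()


def test_leaf_intervals_cover_open_area(mini_apertures):
    ap = mini_apertures[0]
    rows = ab.leaf_intervals(ap)
    assert len(rows) == ap.grid.nv
    total = sum(
        (end - start) / ap.grid.du for row in rows for start, end in row
    )
    assert total == pytest.approx(ap.open_mask.sum())
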