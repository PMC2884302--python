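# Methods

## Model and assumptions

The optimizer treats an IMRT plan as a non-negative weight vector `w` over a
fixed set of anatomy-based apertures.  Dose is linear in the weights:
`d = D0 w`, where `D0[i, j]` is the dose at sample point `i` per unit weight
of aperture `j`.  Two cost functions play distinct roles:

* **Evaluation cost (one-sided).**  `F(d) = Σ p_i (D_i − PD_i)²`, where a
  target point contributes only outside its `[d_min, d_max]` window and an
  OAR or unclassified body point only above its `d_max`.  This is the
  clinically meaningful score: a compliant point costs nothing.
* **Solve surrogate (symmetric).**  The exact, non-iterative solve minimizes
  `Σ p_i (D_i − d_p,i)² + λ‖w‖²` with a single prescribed dose `d_p,i` per
  point.  A one-sided cost has no linear normal equations; the surrogate
  does, and one Gaussian-elimination solve of
  `(D0ᵀ P D0 + λI) w = D0ᵀ P d_p` minimizes it globally (it is convex).

The bridge between the two is the prescribed-dose mapping: target points are
anchored at the structure prescription (driving homogeneity there), OAR/body
points at `min(reference dose, d_max)`, where the reference dose is the dose
at uniform weights (all 1).  Anchoring compliant OAR points at their current
dose prevents the symmetric fit from *pulling doses up* toward the limit —
the main artifact a naive least-squares treatment would introduce.  The
one-sided cost is then evaluated at the solution for reporting; on both
packaged presets it falls by ~98–99% relative to the uniform-weight plan.
Because the surrogate is a proxy, the one-sided cost is not guaranteed to
decrease for arbitrary inputs; the regression suite pins it on the presets.

Target points contribute one row (the prescription anchor), not separate
`d_min`/`d_max` rows; this keeps the system one-row-per-point and makes the
solve unambiguous.

## The solver

`gaussian_eliminate` is a bespoke dense solver: forward elimination with
partial (max-magnitude, lowest-index-on-ties) pivoting, then
back-substitution.  A pivot below `1e-12 · max|A|` raises a singular-system
error naming the elimination step.  The normal matrix is only `n × n`
(`n` ≈ 20–40 apertures), so the solve costs microseconds; a full
1200-equation × 30-unknown optimization, including system assembly, runs in
about a millisecond on one CPU.

**Smoothing / regularization.**  λ defaults to `1e-6 · trace(D0ᵀPD0)/n`.
Besides damping weight oscillations, λ > 0 is structurally necessary for the
packaged aperture sets: the dose kernel is linear in the open mask, so a
beam's conformal aperture column is *exactly* the sum of its split
sub-aperture columns and the normal matrix is rank-deficient at λ = 0.
λ = 0 remains available (and exact) for full-column-rank systems, e.g. the
consistent-system recovery mode.

**Non-negativity.**  The unconstrained solution may contain negative
weights.  The package drops those apertures and re-solves the reduced exact
system, repeating until all remaining weights are non-negative (at most `n`
elimination solves; deterministic).  A single drop-and-refit pass was tried
first and rejected: on the `case-b` preset the refit itself produces two
large newly-negative weights, and hard-clamping them inflates the surrogate
about twentyfold — above the uniform-weight cost.  The iterated rule keeps
every intermediate step an exact solve and, in practice, lands within a few
percent of the true non-negative least-squares optimum; full NNLS (via
scipy) sits behind the `nnls=True` flag for verification.

## Synthetic phantom and dose kernel

The simulator replaces a commercial planning system's role as dose source.
It makes no claim to clinical dosimetry; it produces qualitatively realistic
dose gradients so the optimizer faces the geometry that matters (depth
attenuation, field-edge penumbra, OAR shadowing).

* **Phantoms** are voxel grids (2 mm default) with parametric structures
  (cylinder, sphere, ellipsoid, box, annulus-sector "horseshoe").
  Coordinates are voxel-centered mm with the isocenter at the grid center;
  gantry angles are degrees clockwise from +y in the axial plane.
* **Geometry** is parallel-beam (no divergence) and coplanar (couch 0,
  collimator 0).  Divergence changes none of the optimizer behavior under
  test and is omitted.
* **Dose kernel**: `entry = Φ0 · exp(−μ · depth) · T`, with `Φ0 = 2` Gy per
  unit weight at zero depth, `μ = 0.05 cm⁻¹` (~6 MV primary attenuation) and
  `T` the aperture mask blurred by an isotropic Gaussian penumbra of
  `σ = 3 mm`, bilinearly interpolated at the point's BEV projection.  Depth
  is in-body path length found by 1 mm ray marching (so closed-form checks
  hold to ~1%).  No scatter, no heterogeneity, no output-factor model.
* **Apertures**: per beam, a target-conformal field (projection dilated by a
  6 mm margin), one OAR-blocked field per OAR whose projection overlaps the
  target's, and deterministic breadth-first bisection splits of the
  conformal field to pad the per-beam count.  Because the split order is
  fixed, the k-aperture set per beam is a prefix of the (k+1)-set — the
  nestedness that makes sweep monotonicity a theorem rather than an
  observation.  Requesting more apertures than the split sequence supports
  caps the count with a logged warning.
* **Sample points**: per structure, `round(ρ · V)` points (min 1) at
  `ρ = 1 point/cc` default, drawn uniformly inside the structure mask
  (uniform voxel choice + in-voxel jitter), seeded.  Points labeled ``body``
  are drawn from body-minus-(target ∪ OARs), so labels are unique and
  normal-tissue limits are not applied inside the target.

What passing tests on these phantoms do **not** show: accuracy against a
convolution-superposition or pencil-beam engine, heterogeneity effects, MLC
deliverability (leaf gaps, interdigitation), or real patient anatomy.  They
do show that the optimization layer — system assembly, elimination,
clamping, evaluation, replanning — behaves exactly as specified for any
dose-influence matrix a real planning system would supply.

## Packaged presets

`case-a` (head-and-neck-like): 80×80×40 grid at 2 mm; horseshoe target
(r 18–48 mm, 270° arc, 72 mm long, ≈330 cc) around an 8 mm cord cylinder,
two lateral parotid-like ellipsoids; beams 0/45/100/150/210/260/315°; 4–5
apertures per beam (28 total); target 50.4 Gy (window 48–53), cord max 45,
parotids max 25, body max 55, penalties 10/8/3/3/1.

`case-b` (brain-like): 70×70×40 grid; 39 mm spherical target (≈250 cc)
beside a brainstem-like cylinder and chiasm/optic-nerve-like nodes; seven
coplanar beams; 3–5 apertures per beam; target 50 Gy (window 47.5–53),
brainstem/chiasm max 50, nerves max 45/50, body max 55.

At ρ = 1 these give ~1300 and ~1057 sample points — the matrix scale the
method targets.  The penalty-trial schedules shipped with the presets (six
edits for case-a, nine for case-b) are illustrative scripts for the
interactive loop, not reconstructions of any particular planning session.

## Numerical choices and degenerate inputs

* Pivot singularity threshold `1e-12` relative to `max|A|`; elimination
  reports the failing step.
* All-zero penalty vectors, fewer positive-penalty rows than apertures at
  λ = 0, and m < n are rejected as degenerate before the solve.
* DVH bin width 0.1 Gy default; curves are defined on sample points, are
  non-increasing, start at 100% and end at 0%.
* Apertures with weight below `1e-6 · max(weight)` are dropped from the
  deliverable plan (MU keeps the full sum; the difference is below any
  reporting precision).
* Percent reductions are displayed nearest-integer (the rounding that
  reproduces the published benchmark tables); unrounded values are always
  retained alongside.
* CSV round trips use shortest-`repr` floats and round-trip parsing, so a
  write/read cycle is bit-exact; HDF5 matrices are lossless by construction.
* Sweeps fix the prescribed-dose vector and λ from the largest aperture set,
  so the surrogate is comparable across counts; with nested sets its
  unconstrained minimum is non-increasing in the count.

## Known limitations

* The one-sided cost is non-convex in the constraint-activation sense; the
  surrogate finds a good local solution, not a certified global optimum of
  `F`.
* No dose-volume (partial-volume) or biological (EUD) objectives — the cost
  is purely point-dose quadratic.
* MU is proportional to weight (1 MU per weight unit by default); no
  output-factor or per-beam minimum-MU model.
* Coplanar, parallel-beam geometry only; no DICOM import/export.
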