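# abiplan

Exact, non-iterative aperture-weight optimization for anatomy-based
intensity-modulated radiotherapy (IMRT).

## The problem

In aperture-based inverse planning (ABIP) the deliverable multileaf-collimator
(MLC) shapes are fixed up front from the anatomy — per beam, one field
conformal to the target's beam's-eye-view projection plus fields that
additionally block each organ-at-risk (OAR) — and only the weight of each
aperture is optimized.  Compared with beamlet-based inverse planning (BBIP),
this cuts monitor units (MU) and segment counts roughly in half while keeping
the dose distribution clinically comparable.  The package is for medical
physicists and algorithm developers who want a fully self-contained,
scriptable implementation of this workflow: it ships a synthetic
phantom/dose-kernel simulator in place of a commercial planning system, so
every experiment runs from a seed, with no patient data.

## The method

Plan quality is scored with a one-sided quadratic penalty cost over dose
sample points,

    F(d) = Σᵢ pᵢ (Dᵢ − PDᵢ)²,

where a target point is penalized when its dose leaves [D_min, D_max] and an
OAR point when it exceeds D_max, with per-structure penalties pᵢ.  The doses
are linear in the aperture weights w through the dose-influence matrix D₀
(Gy per unit weight, one row per sample point, one column per aperture), so
the m ≫ n system D₀ w = d_p is solved in weighted least-squares normal form

    (D₀ᵀ P D₀ + λI) w = D₀ᵀ P d_p ,

by Gaussian elimination with partial pivoting and back-substitution — a
single exact solve, no iteration, fractions of a second at clinical size
(~1200 equations, ~30 apertures).  The prescribed-dose vector d_p anchors
target points at the prescription and compliant OAR points at their current
dose; λ is a small Tikhonov smoothing term.  Negative weights are removed by
iterated clamp-and-refit (full NNLS available behind a flag).  Doses after
optimization come from reversing the operation, d = D₀ w, with no further
dose calculation.  Evaluation covers cumulative DVHs, dose-volume indices
(V_dose, D_max, D_mean), MU/segment metrics and ABIP-vs-BBIP comparisons,
plus a scripted penalty-trial loop and an apertures-per-beam sweep.

## Worked example

Simulate the packaged concave head-and-neck-like case (horseshoe target
around a cord-like OAR, seven coplanar beams) and optimize it:

```sh
$ abiplan simulate --preset case-a --seed 17 --out demo
matrix: 1300 points x 28 apertures -> demo

$ abiplan optimize --matrix demo/matrix.csv --constraints demo/constraints.json --out demo/opt
cost: 485142 -> 7513.77  (98% reduction)
active apertures: 17/28, solve time 1.9 ms
```

The first command writes the phantom summary, aperture masks, sample points
(1 point/cc), the 1300 × 28 dose-influence matrix and the preset constraints
(prescription 50.4 Gy to the target, 45 Gy maximum to the cord).  The second
solves the normal system: the one-sided cost drops from 485142 (uniform
weights heavily underdose the target) to 7513.77, a 98% reduction; 17 of the
28 apertures keep a strictly positive weight and form the deliverable plan.
`abiplan evaluate` then produces per-structure DVH curves and metrics, and
`abiplan sweep`/`abiplan trial` drive the aperture-count and penalty-editing
studies.  The same functionality is available as a library
(`abiplan.presets.simulate_case`, `abiplan.optimize_weights`, ...).

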