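# Methods

## Scope and model

`mousemsk` implements the computational core of a whole-body mouse
musculoskeletal model: a kinematic skeleton of rigid segments and
rotational joints, rigid-tendon Hill-type muscles routed along polyline
paths, and the analysis machinery built on them (moment arms, joint
moments, fiber operating ranges, parameter estimation, and variance-based
sensitivity analysis). Forward dynamics, contact, and physics-engine
coupling are out of scope, as are bone digitization and muscle wrapping
surfaces (polyline paths with waypoints stand in for wrapping geometry).

Units: millimetres, newtons and degrees at file boundaries; radians
internally. Inertial estimation uses SI (metres, kilograms).

## Skeleton

Segments form a rooted tree; each joint has 1–3 rotational DoFs with a
fixed rotation center in the parent frame. DoF rotations compose in the
joint's declared order (flexion-extension first by convention), each by
the right-hand rule about its unit axis. The zero-pose — all angles zero —
is the reference configuration and may lie outside anatomical ranges.

The bundled whole-body configuration has 108 segments: 50 vertebrae
(8 cervical, 13 thoracic, 6 lumbar, 3 coccygeal, 20 caudal), the pelvis
(with the 4 sacral vertebrae merged in), the head, 15 bones per forelimb
and 13 per hindlimb, joined by 107 joints. Segment placements are nominal
straight-chain offsets at a plausible overall scale; real bone geometry is
deliberately not bundled (see *Limitations*). A published joint count that
depends on a different DoF bookkeeping is not asserted; the config
documents its own tally.

Joint limits are torsional spring-dampers engaging beyond the range:
zero inside, then a stiffness ramp over a transition width `w` (torque
`-k p^2 / 2w` for penetration `p < w`, linear `-k (p - w/2)` beyond), with
the damper scaled by the same ramp so torque is continuous at the
boundary. Defaults `k = 0.5 N·m/rad`, `d = 0.01 N·m·s/rad`, `w = 2°` are
small-animal-scale choices and are configuration values, not code.

Inertial properties come from the convex hull of a segment's mesh at
uniform density 1000 kg/m³ (water), as a proxy for the soft-tissue volume
around each bone. Mass, COM and inertia use exact divergence-theorem
polyhedral integrals (via trimesh), not voxelization; open meshes are
repaired when possible and rejected otherwise.

## Muscle model

Rigid tendon: the tendon stays at its slack length `lts`, so fiber
geometry follows algebraically from the muscle-tendon length `lmt` with
the fixed-height pennation model (`lm·sin α` constant):

    lm = sqrt((lmt − lts)² + (lmo·sin αo)²),  α = atan2(lmo·sin αo, lmt − lts)

Force along the tendon line:

    F = Fm0 · (a · f_act(l̃m) · f_v(ṽ) + f_pas(l̃m)) · cos α,  l̃m = lm/lmo

The dimensionless curve set (all shape constants in one `CurveSet` block,
so alternate sets are drop-in):

* **Active FL** — Gaussian sum; default a single term
  `exp(−(l̃m−1)²/0.45)`, exactly 1 at the optimum and symmetric about it.
* **Passive FL** — exponential engaging at `l̃m = 1`, reaching 1 at strain
  0.6 (shape exponent 4), zero at and below the optimum.
* **FV** — Hill hyperbola for shortening (`a_f = 0.25`), saturating
  eccentric branch with plateau 1.4 and slope-matched at `ṽ = 0` (C1).
  Isometric analyses (`vmt = 0`) never leave `f_v = 1`.

Degenerate inputs: pennation capped at 89°, fiber length floored at
`0.01·lmo`; a fiber with `lmt ≤ lts` is flagged slack and transmits no
force. `vmmax` defaults to 10 optimal fiber lengths per second. Forelimb
maximum isometric forces derive from PCSA × σ with σ = 0.3 N/mm².

Whether the passive element carries damping is left open deliberately:
curves are pluggable and the default passive element is elastic only.

## Path geometry

`lmt` is the summed straight-line length over world-frame polyline points
(Eq. lmt = Σ‖P_{n+1} − P_n‖). Moment arms use the tendon-excursion
(perturbation) method, `r = ∂lmt/∂θ`, as a central difference with
default step 1e-4 rad; central rather than forward differencing was
chosen for its O(δ²) truncation error, which the test suite verifies by
step-halving on a pendulum fixture with a closed-form derivative. The
sign convention is the literal derivative: positive `r` means the muscle
lengthens with positive rotation (i.e. resists it); analyses that group
by function use |r| and record direction separately. A DoF whose rotation
changes no inter-point distance gets exactly `r = 0`. The DoF-crossing
pair (P_WO, P_WI) is the unique adjacent pair straddling the joint's
child subtree, validated in tests against a brute-force scan for the one
inter-point distance that changes under rotation.

Joint moments are isometric by default, `τ = r·F` at full activation.
ROM sweeps rotate one DoF through its range with every other DoF held at
a named default pose, which is the standard single-joint analysis
convention and is stated in each output.

## Attachment transfer

A 12-parameter affine (not similarity — bones differ in shape, not just
scale) is estimated from ≥ 4 non-coplanar landmark pairs by linear least
squares; rank deficiency is reported with the design-matrix condition
number. Landmark picking itself is manual work done in mesh software and
is out of scope; this module owns only the estimation and application.

## Parameter estimation

**Length-parameter scaling.** Given elementwise-corresponding `lmt`
samples of the same muscle in a reference and a target model, the scale
factors `(s_lmo, s_lts)` minimize the squared mismatch of rigid-tendon
normalized fiber length across poses. No constraint preserves the
`lts/lmo` ratio. The objective is 2-D and smooth; a bounded Powell search
from three fixed starts (bounds [0.2, 5]) is deterministic and, on a
uniformly scaled model, recovers the scale factor to well under 1%.

**Tendon slack length.** With no reference model, `lts` minimizes the
squared deviation of `l̃m` from a target profile over pose samples of
*all* spanned DoFs (weighted equally — the natural choice absent any
stated weighting), subject to the operating range reaching the active
region (`l̃m ≤ 1` somewhere). Fibers are not restricted to the ascending
limb; targets beyond the optimum are followed there. The search scans a
1000-point bracket over [0, max lmt] for the best feasible candidate and
refines it with a bounded scalar minimizer; tests pin it to a dense
grid-search oracle. The default target profile maps the muscle's `lmt`
range linearly onto l̃m ∈ [0.8, 1.2], placing the optimum at mid-range —
the canonical assumption when no fiber-length data exist; the profile is
an argument, not a constant.

**Pose sampling.** Default 5 grid points per spanned DoF, full Cartesian
product, capped at 10⁴ poses with seeded Sobol'-sequence subsampling
beyond the cap. Both optimizers are deterministic given the sampling seed.

## Analyses

* **Functional map** — per muscle and DoF direction (split by the sign of
  `r`), max |r| and max |τ| over the ROM sweep, normalized within each
  (DoF, direction) group by the dominant muscle; spans with `r` identically
  zero are flagged (grey boxes), normalized values in (0, 0.01] are
  rendered as ε (threshold configurable), and sign changes set the
  zero-crossing flag.
* **Zero-crossings** — linearly interpolated sign changes of `r(θ)`;
  exact-zero samples reported once.
* **Fiber operating range** — min/max `l̃m` over the Cartesian grid of
  all spanned-DoF ranges (default 7 points per DoF, capped at 10⁵ poses
  with seeded subsampling), classified active-only (`l̃m ≤ 1` throughout),
  passive-only (`l̃m > 1` throughout) or mixed.

## Sensitivity analysis

First-order Sobol' indices with Saltelli sampling: A and B matrices drawn
from one scrambled Sobol' sequence (2d-dimensional, so A and B share a
stream deterministically), estimator `S_i = mean(f_B·(f_ABi − f_A))/Var`,
variance pooled over A and B. Percentile bootstrap CIs (default 100
resamples) come from resampling sample rows; everything is bit-reproducible
at fixed seed. Base N defaults to 1024 (power of two, as the sampling
scheme requires). Constant output is flagged rather than propagated as
NaN. The engine is validated against closed-form indices of an additive
linear function and the Ishigami function.

Two drivers wrap the engine with the scalar output functional being the
RMS over 50 equally spaced ROM samples (resolution configurable):

* **Attachments** — the six bone-local coordinates of P_WO and P_WI, each
  uniform within ±0.5 mm; bone-local (rather than world) perturbation was
  chosen so perturbed points ride with their segment. Per-point sums of
  the three coordinate indices give a direction-independent summary.
* **Parameters** — Fm0, lmo, lts, αo, each uniform within ±10% of its
  value. A nominal value of zero (commonly αo) makes the interval
  degenerate; such parameters are excluded from sampling and reported as
  structurally zero.

## Synthetic fixtures: what they do and do not show

The fixture generators produce small models with closed-form references:
a two-segment pendulum (law-of-cosines `lmt`, analytic moment arm), a
two-DoF serial chain for multi-DoF estimation, and uniformly scaled
copies for scale-recovery tests. They emulate the *mechanics* real models
exercise — multi-DoF spanning, pennation, slack fibers, passive
engagement — but not real anatomy: no bone meshes, no measured attachment
coordinates, no wrapping-compensation waypoint layouts. Passing tests
therefore establish that the computational machinery is correct, not that
any particular mouse-specific curve is reproduced; model-specific results
require a user-supplied model file.

## Limitations

* The published mouse attachment geometry lives in an external repository
  and is not bundled; whole-animal quantities that depend on it (overall
  model length and mass, per-muscle moment-arm curves) are out of scope.
* The bundled parameter table transcribes the printed source bit-exactly;
  six rows' printed lts/lmo ratios differ from the quotient of their own
  printed columns by slightly more than 2-decimal rounding (up to 0.0064)
  and are flagged `ratio-mismatch` in the CSV.
* Joint rotation centers are fixed over the range of motion; real joints
  translate as they rotate.
* No elastic-tendon equilibrium, activation dynamics, or wrapping
  surfaces; analyses assume full, constant activation where moments are
  reported.
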