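"""Muscle parameter estimation.

Two bespoke procedures:

* :func:`scale_length_parameters` — carry optimal fiber length (lmo) and
  tendon slack length (lts) from a reference model to a target model with
  different bone geometry.  The scale factors minimize the squared mismatch
  of rigid-tendon normalized fiber length between the two models across a
  shared set of joint poses covering the feasible ranges of every DoF the
  muscle spans.  No constraint preserves the lts/lmo ratio.

* :func:`estimate_tendon_slack_length` — estimate lts when no reference
  model exists, by matching the rigid-tendon normalized-fiber-length
  profile over sampled poses of *all* spanned DoFs to a target profile,
  under the constraint that the operating range reaches the active region
  (normalized length <= 1 somewhere).  Fibers are not restricted to the
  ascending limb: target profiles may put part of the range past the
  optimum, and the optimizer follows them there.

Both objectives are low-dimensional and smooth; a bounded derivative-free
search (coarse bracketing grid + local refinement from the best starts) is
deterministic given the pose-sampling seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .muscle import MuscleParams
from .paths import MusclePath, muscle_tendon_length, spans_dof
from .skeleton import Pose, SkeletonModel

__all__ = [
    "PoseSampleSet",
    "ScalingResult",
    "ConstraintInfeasibleError",
    "sample_poses",
    "scale_length_parameters",
    "estimate_tendon_slack_length",
    "canonical_norm_length_profile",
]

SCALE_BOUNDS = (0.2, 5.0)
POSE_CAP = 10_000


class ConstraintInfeasibleError(RuntimeError):
    """No tendon slack length gives the muscle any active-region operation."""


@dataclass
class PoseSampleSet:
    poses: list[Pose]
    dof_names: tuple[str, ...]
    method: str = "grid"
    n_per_dof: int = 5
    seed: int = 0

    def __len__(self) -> int:
        return len(self.poses)


def sample_poses(
    model: SkeletonModel,
    dof_names,
    n_per_dof: int = 5,
    method: str = "grid",
    seed: int = 0,
    cap: int = POSE_CAP,
    base_pose: Pose | None = None,
) -> PoseSampleSet:
    """Sample poses over the ranges of ``dof_names``; other DoFs at ``base_pose``.

    ``grid`` takes the full Cartesian product of ``n_per_dof`` equally
    spaced angles per DoF; beyond ``cap`` poses a seeded Sobol' sequence
    over the range box is used instead.  ``sobol`` forces the latter with
    ``n_per_dof ** n_dofs`` points (capped).
    """
    dof_names = tuple(dof_names)
    ranges = [model.dof(d).range for d in dof_names]
    base = dict(base_pose.angles) if base_pose else {}
    n_grid = n_per_dof ** len(dof_names)
    if method == "grid" and n_grid <= cap:
        axes = [np.linspace(lo, hi, n_per_dof) for lo, hi in ranges]
        combos = itertools.product(*axes)
    else:
        n = min(n_grid, cap)
        sampler = qmc.Sobol(d=len(dof_names), scramble=True, seed=seed)
        unit = sampler.random(n)
        lo = np.array([r[0] for r in ranges])
        hi = np.array([r[1] for r in ranges])
        combos = lo + unit * (hi - lo)
        method = "sobol"
    poses = [
        Pose({**base, **dict(zip(dof_names, angles))}) for angles in combos
    ]
    return PoseSampleSet(poses, dof_names, method, n_per_dof, seed)


@dataclass
class ScalingResult:
    muscle: str
    scale_lmo: float
    scale_lts: float
    objective: float
    residuals: np.ndarray  # per-pose normalized-length mismatch
    converged: bool = True
    history: list = field(default_factory=list)

    @property
    def scaled_params(self) -> tuple[float, float]:
        return self.scale_lmo, self.scale_lts


def _norm_fiber_length(lmt: np.ndarray, l_opt: float, l_slack: float, alpha_opt_rad: float):
    """Vectorized rigid-tendon normalized fiber length (fixed-height pennation)."""
    h = l_opt * math.sin(alpha_opt_rad)
    return np.sqrt((lmt - l_slack) ** 2 + h * h) / l_opt


def scale_length_parameters(
    ref_lmt,
    tgt_lmt,
    ref_params: MuscleParams,
    bounds: tuple[float, float] = SCALE_BOUNDS,
) -> ScalingResult:
    """Scale lmo and lts from a reference model to a target model.

    ``ref_lmt`` and ``tgt_lmt`` are muscle-tendon lengths (mm) of the same
    muscle over elementwise-corresponding pose samples in the two models.
    Finds scale factors (s_lmo, s_lts) minimizing the squared difference
    between the target model's normalized fiber length (with scaled
    parameters) and the reference model's (with reference parameters),
    summed over poses.
    """
    ref_lmt = np.asarray(ref_lmt, float)
    tgt_lmt = np.asarray(tgt_lmt, float)
    if ref_lmt.shape != tgt_lmt.shape:
        raise ValueError("reference and target lmt arrays must correspond elementwise")
    if (ref_lmt <= 0).any() or (tgt_lmt <= 0).any():
        raise ValueError("lmt values must be positive")
    a = ref_params.alpha_opt_rad
    ref_norm = _norm_fiber_length(ref_lmt, ref_params.l_opt, ref_params.l_slack, a)

    def resid(scales):
        s_lmo, s_lts = scales
        tgt_norm = _norm_fiber_length(
            tgt_lmt, s_lmo * ref_params.l_opt, s_lts * ref_params.l_slack, a
        )
        return tgt_norm - ref_norm

    def objective(scales):
        r = resid(scales)
        return float(r @ r)

    history = []
    best = None
    for start in ((1.0, 1.0), (0.5, 0.5), (2.0, 2.0)):
        res = optimize.minimize(
            objective,
            np.asarray(start),
            method="Powell",
            bounds=[bounds, bounds],
            options={"xtol": 1e-10, "ftol": 1e-12},
        )
        history.append((start, float(res.fun)))
        if best is None or res.fun < best.fun:
            best = res
    return ScalingResult(
        muscle=ref_params.name,
        scale_lmo=float(best.x[0]),
        scale_lts=float(best.x[1]),
        objective=float(best.fun),
        residuals=resid(best.x),
        converged=bool(best.success),
        history=history,
    )


def canonical_norm_length_profile(lmt: np.ndarray, span: tuple[float, float] = (0.8, 1.2)):
    """Default target normalized-fiber-length profile over an lmt sample.

    Maps the muscle's lmt range linearly onto ``span`` so the fiber passes
    through its optimum (1.0) at mid-range — the canonical assumption when
    no reference length data exist.  Degenerate (constant-lmt) samples map
    to the optimum.
    """
    lmt = np.asarray(lmt, float)
    lo, hi = lmt.min(), lmt.max()
    if hi - lo < 1e-12:
        return np.full_like(lmt, (span[0] + span[1]) / 2.0)
    return span[0] + (lmt - lo) / (hi - lo) * (span[1] - span[0])


def estimate_tendon_slack_length(
    model: SkeletonModel,
    path: MusclePath,
    params: MuscleParams,
    pose_samples: PoseSampleSet,
    target_norm_lengths=None,
    n_grid: int = 1000,
) -> tuple[float, dict]:
    """Estimate tendon slack length lts (mm) for a muscle.

    Minimizes the squared deviation of the rigid-tendon normalized fiber
    length from ``target_norm_lengths`` across all pose samples (all
    spanned DoFs weighted equally), subject to the operating range
    intersecting the active region (min normalized length <= 1).  The
    search brackets lts in [0, max lmt] with an ``n_grid``-point scan and
    refines the best feasible candidate with a bounded local minimizer.

    Returns ``(lts, diagnostics)`` where diagnostics holds the objective,
    the operating range at the optimum and the grid used.
    """
    for d in pose_samples.dof_names:
        if not spans_dof(model, path, d):
            raise ValueError(f"{path.muscle}: does not span DoF {d!r}")
    lmts = np.array(
        [muscle_tendon_length(model, p, path) for p in pose_samples.poses]
    )
    if target_norm_lengths is None:
        target = canonical_norm_length_profile(lmts)
    else:
        target = np.asarray(target_norm_lengths, float)
        if target.shape != lmts.shape:
            raise ValueError("target profile must correspond to the pose samples")
    a = params.alpha_opt_rad
    hi = float(lmts.max())

    def norm_lengths(lts):
        return _norm_fiber_length(lmts, params.l_opt, lts, a)

    def objective(lts):
        r = norm_lengths(lts) - target
        return float(r @ r)

    grid = np.linspace(0.0, hi, n_grid)
    feasible = np.array([norm_lengths(g).min() <= 1.0 for g in grid])
    if not feasible.any():
        raise ConstraintInfeasibleError(
            f"{path.muscle}: no lts in [0, {hi:.3g}] mm reaches the active region"
        )
    obj = np.array([objective(g) if ok else np.inf for g, ok in zip(grid, feasible)])
    i = int(np.argmin(obj))
    lo_b = grid[max(i - 1, 0)]
    hi_b = grid[min(i + 1, n_grid - 1)]
    big = obj[np.isfinite(obj)].max() * 10 + 1.0

    def penalized(lts):
        if norm_lengths(lts).min() > 1.0:
            return big
        return objective(lts)

    res = optimize.minimize_scalar(
        penalized, bounds=(lo_b, hi_b), method="bounded",
        options={"xatol": 1e-10},
    )
    lts = float(res.x) if res.fun <= obj[i] else float(grid[i])
    nl = norm_lengths(lts)
    return lts, {
        "objective": objective(lts),
        "norm_length_range": (float(nl.min()), float(nl.max())),
        "grid_best": float(grid[i]),
        "n_poses": len(lmts),
    }
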