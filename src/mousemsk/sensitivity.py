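"""Variance-based (Sobol') global sensitivity analysis, first-order indices.

The engine estimates first-order Sobol' indices S_i — the fraction of
output variance attributable to each input alone — with the Saltelli
sampling scheme: two independent N x d sample matrices A and B are drawn
from a scrambled Sobol' sequence over the input box, plus d hybrid
matrices AB_i (A with column i taken from B).  The estimator is

    S_i = mean( f(B) * (f(AB_i) - f(A)) ) / Var(f)

(Saltelli et al. 2010), with Var(f) taken over the pooled A and B
evaluations.  Percentile bootstrap confidence intervals come from
resampling the N sample rows.  Everything is deterministic given the seed.

Two domain drivers wrap the engine:

* :func:`attachment_sensitivity` — sensitivity of the RMS moment arm over
  a DoF's range to the 3D positions of the two attachment points (P_WO,
  P_WI) bounding the polyline segment that crosses the joint, each
  perturbed within +/- 0.5 mm per coordinate in its bone-local frame.
  Per-point sums of the three coordinate indices give a
  direction-independent measure.
* :func:`parameter_sensitivity` — sensitivity of the RMS isometric moment
  (full activation) to the four Hill parameters (Fm0, lmo, lts, alpha_o),
  each perturbed within +/- 10 % of its value.  Parameters whose nominal
  value is zero have a degenerate interval and are reported as
  structurally zero rather than sampled.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.stats import qmc

from .muscle import MuscleParams
from .paths import MusclePath, crossing_segment, joint_moment, moment_arm
from .skeleton import Pose, SkeletonModel

__all__ = [
    "SensitivityProblem",
    "SobolResult",
    "sobol_first_order",
    "attachment_sensitivity",
    "parameter_sensitivity",
]

DEFAULT_N = 1024
DEFAULT_BOOTSTRAP = 100
DEFAULT_ROM_SAMPLES = 50
ATTACHMENT_DELTA_MM = 0.5
PARAMETER_FRACTION = 0.10


@dataclass(frozen=True)
class SensitivityProblem:
    names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]  # (lower, upper) per parameter
    n: int = DEFAULT_N
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.names) != len(self.bounds):
            raise ValueError("names and bounds must correspond")
        for name, (lo, hi) in zip(self.names, self.bounds):
            if not lo < hi:
                raise ValueError(f"parameter {name!r}: lower bound must be < upper")
        if self.n < 2 or self.n & (self.n - 1):
            raise ValueError("base sample count n must be a power of 2")


@dataclass
class SobolResult:
    first_order: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    grouped_sums: dict[str, float] = dataclasses.field(default_factory=dict)
    structural_zeros: tuple[str, ...] = ()
    constant_output: bool = False
    n: int = 0
    seed: int = 0


def _saltelli_matrices(problem: SensitivityProblem):
    """A, B (n x d) over the bound box from one scrambled Sobol' stream."""
    d = len(problem.names)
    sampler = qmc.Sobol(d=2 * d, scramble=True, seed=problem.seed)
    unit = sampler.random(problem.n)
    lo = np.array([b[0] for b in problem.bounds])
    hi = np.array([b[1] for b in problem.bounds])
    A = lo + unit[:, :d] * (hi - lo)
    B = lo + unit[:, d:] * (hi - lo)
    return A, B


def sobol_first_order(
    problem: SensitivityProblem,
    f,
    n_bootstrap: int = DEFAULT_BOOTSTRAP,
    ci_level: float = 0.95,
) -> SobolResult:
    """First-order Sobol' indices of scalar ``f`` over the problem's box.

    ``f`` maps an (m, d) array of parameter rows to an (m,) array (or a
    single row to a scalar; vectorization is probed).  Constant output is
    flagged instead of propagating 0/0.
    """
    d = len(problem.names)
    A, B = _saltelli_matrices(problem)

    def evaluate(X):
        try:
            out = np.asarray(f(X), dtype=float)
        except (TypeError, ValueError):
            out = None
        if out is None or out.shape != (len(X),):
            out = np.array([float(f(row)) for row in X])
        return out

    fA = evaluate(A)
    fB = evaluate(B)
    if not (np.isfinite(fA).all() and np.isfinite(fB).all()):
        raise ValueError("model output not finite over the bound box")

    fAB = np.empty((d, problem.n))
    for i in range(d):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        fAB[i] = evaluate(ABi)

    pooled = np.concatenate([fA, fB])
    var = pooled.var(ddof=1)
    if var <= 1e-12 * max(1.0, np.mean(pooled) ** 2):
        return SobolResult(
            first_order={}, conf_int={}, constant_output=True,
            n=problem.n, seed=problem.seed,
        )

    def indices(idx):
        a, b, ab = fA[idx], fB[idx], fAB[:, idx]
        v = np.concatenate([a, b]).var(ddof=1)
        return (b * (ab - a)).mean(axis=1) / v

    full = np.arange(problem.n)
    S = indices(full)
    rng = np.random.default_rng(problem.seed + 1)
    boots = np.empty((n_bootstrap, d))
    for k in range(n_bootstrap):
        boots[k] = indices(rng.integers(0, problem.n, problem.n))
    alpha = (1.0 - ci_level) / 2.0
    lo_ci = np.quantile(boots, alpha, axis=0)
    hi_ci = np.quantile(boots, 1.0 - alpha, axis=0)
    return SobolResult(
        first_order=dict(zip(problem.names, map(float, S))),
        conf_int={
            name: (float(l), float(h))
            for name, l, h in zip(problem.names, lo_ci, hi_ci)
        },
        n=problem.n,
        seed=problem.seed,
    )


def _rms(values: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(values))))


def attachment_sensitivity(
    model: SkeletonModel,
    path: MusclePath,
    params: MuscleParams,
    dof: str,
    delta: float = ATTACHMENT_DELTA_MM,
    n: int = DEFAULT_N,
    seed: int = 0,
    rom_samples: int = DEFAULT_ROM_SAMPLES,
    default_pose: Pose | None = None,
) -> SobolResult:
    """Sobol' sensitivity of the RMS moment arm to P_WO / P_WI positions.

    The six inputs are the x/y/z bone-local coordinates of the two points
    bounding the DoF-crossing polyline segment, each uniform within
    +/- ``delta`` mm of its nominal value.  ``grouped_sums`` reports the
    per-point sums of the coordinate indices.
    """
    p_wo, p_wi = crossing_segment(model, path, dof)
    idx_wo = path.points.index(p_wo)
    idx_wi = path.points.index(p_wi)
    base = default_pose or Pose()
    lo, hi = model.dof(dof).range
    thetas = np.linspace(lo, hi, rom_samples)

    names = tuple(
        f"{pt}_{ax}" for pt in ("P_WO", "P_WI") for ax in ("x", "y", "z")
    )
    nominal = np.concatenate(
        [np.asarray(p_wo.local_position, float), np.asarray(p_wi.local_position, float)]
    )
    bounds = tuple((v - delta, v + delta) for v in nominal)
    problem = SensitivityProblem(names, bounds, n=n, seed=seed)

    def f(X):
        X = np.atleast_2d(X)
        out = np.empty(len(X))
        for k, row in enumerate(X):
            pts = list(path.points)
            pts[idx_wo] = dataclasses.replace(p_wo, local_position=tuple(row[:3]))
            pts[idx_wi] = dataclasses.replace(p_wi, local_position=tuple(row[3:]))
            perturbed = MusclePath(path.muscle, tuple(pts))
            r = [
                moment_arm(model, base.with_angle(dof, th), perturbed, dof)
                for th in thetas
            ]
            out[k] = _rms(np.asarray(r))
        return out

    result = sobol_first_order(problem, f)
    if not result.constant_output:
        result.grouped_sums = {
            "P_WO": float(sum(result.first_order[f"P_WO_{ax}"] for ax in "xyz")),
            "P_WI": float(sum(result.first_order[f"P_WI_{ax}"] for ax in "xyz")),
        }
    return result


def parameter_sensitivity(
    model: SkeletonModel,
    path: MusclePath,
    params: MuscleParams,
    dof: str,
    fraction: float = PARAMETER_FRACTION,
    n: int = DEFAULT_N,
    seed: int = 0,
    rom_samples: int = DEFAULT_ROM_SAMPLES,
    default_pose: Pose | None = None,
) -> SobolResult:
    """Sobol' sensitivity of the RMS isometric moment to the Hill parameters.

    Inputs are Fm0, lmo, lts and alpha_o, each uniform within
    +/- ``fraction`` of its nominal value.  Zero-valued parameters (e.g.
    alpha_o = 0) have a degenerate +/-10 % interval; they are excluded
    from sampling and reported in ``structural_zeros`` with index 0.
    """
    base = default_pose or Pose()
    lo, hi = model.dof(dof).range
    thetas = np.linspace(lo, hi, rom_samples)

    all_names = ("f_max", "l_opt", "l_slack", "alpha_opt")
    nominal = {n_: getattr(params, n_) for n_ in all_names}
    active = tuple(n_ for n_ in all_names if nominal[n_] != 0.0)
    zeros = tuple(n_ for n_ in all_names if nominal[n_] == 0.0)
    bounds = tuple(
        (nominal[n_] * (1 - fraction), nominal[n_] * (1 + fraction)) for n_ in active
    )
    problem = SensitivityProblem(active, bounds, n=n, seed=seed)

    def f(X):
        X = np.atleast_2d(X)
        out = np.empty(len(X))
        for k, row in enumerate(X):
            p = dataclasses.replace(params, **dict(zip(active, row)))
            tau = [
                joint_moment(model, base.with_angle(dof, th), path, p, dof)
                for th in thetas
            ]
            out[k] = _rms(np.asarray(tau))
        return out

    result = sobol_first_order(problem, f)
    result.structural_zeros = zeros
    for z in zeros:
        result.first_order.setdefault(z, 0.0)
        result.conf_int.setdefault(z, (0.0, 0.0))
    return result
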