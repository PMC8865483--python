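"""Range-of-motion analyses: moment-arm sweeps, functional grouping, fiber ranges.

These reproduce the toolkit's standard muscle-function summaries:

* :func:`rom_sweep` — moment arm r and isometric moment tau (full
  activation) of one muscle over one DoF's range, all other DoFs held at a
  default pose.
* :func:`zero_crossings` — angles at which r changes sign, i.e. where the
  muscle switches function about that DoF.
* :func:`functional_map` — per muscle and DoF direction, the maximum |r|
  and |tau|, normalized within each joint-function group by its dominant
  muscle; spans with zero influence are flagged ("grey boxes").
* :func:`fiber_length_range` — min/max normalized fiber length over the
  Cartesian grid of all spanned-DoF ranges, classified into active-only
  (l~m <= 1 everywhere), passive-only (l~m > 1 everywhere) or mixed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .muscle import MuscleParams, fiber_state_rigid_tendon
from .paths import MusclePath, joint_moment, moment_arm, muscle_tendon_length, spans_dof
from .skeleton import Pose, SkeletonModel

__all__ = [
    "RomSweep",
    "FunctionalEntry",
    "FunctionalMap",
    "FiberRange",
    "rom_sweep",
    "zero_crossings",
    "functional_map",
    "fiber_length_range",
    "spanned_dofs",
]

EPSILON_THRESHOLD = 0.01  # normalized entries in (0, eps] rendered as "epsilon"
ZERO_TOL = 1e-9  # |r| below this counts as no influence
DEFAULT_GRID_PER_DOF = 7
GRID_CAP = 100_000


@dataclass
class RomSweep:
    dof: str
    angles: np.ndarray  # rad
    moment_arms: np.ndarray  # mm (divided by normalization_ref if given)
    moments: np.ndarray  # N*mm
    normalization_ref: float | None = None


@dataclass
class FunctionalEntry:
    muscle: str
    dof: str
    direction: str  # "positive" | "negative" (sense of increasing theta)
    max_moment_arm: float  # mm, absolute
    max_moment: float  # N*mm, absolute
    norm_moment_arm: float = np.nan  # within-group normalized, [0, 1]
    norm_moment: float = np.nan
    zero_influence: bool = False  # spans the joint but r == 0 throughout
    zero_crossing: bool = False
    epsilon: bool = False  # positive but below EPSILON_THRESHOLD after normalizing


@dataclass
class FunctionalMap:
    entries: list[FunctionalEntry]

    def lookup(self, muscle: str, dof: str, direction: str) -> FunctionalEntry:
        for e in self.entries:
            if (e.muscle, e.dof, e.direction) == (muscle, dof, direction):
                return e
        raise KeyError((muscle, dof, direction))


@dataclass
class FiberRange:
    muscle: str
    l_m_norm_min: float
    l_m_norm_max: float
    region: str  # "active-only" | "passive-only" | "mixed"


def spanned_dofs(model: SkeletonModel, path: MusclePath) -> list[str]:
    """DoFs whose joints the path crosses, in model declaration order."""
    return [d for d in model.dof_names() if spans_dof(model, path, d)]


def rom_sweep(
    model: SkeletonModel,
    path: MusclePath,
    params: MuscleParams,
    dof: str,
    n_samples: int = 50,
    default_pose: Pose | None = None,
    normalization_ref: float | None = None,
    activation: float = 1.0,
) -> RomSweep:
    """Sweep ``dof`` through its range; r and isometric tau at each angle.

    All other DoFs stay at ``default_pose``.  ``normalization_ref`` (mm,
    e.g. a thigh length) divides the moment arms when given.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    base = default_pose or Pose()
    lo, hi = model.dof(dof).range
    angles = np.linspace(lo, hi, n_samples)
    r = np.empty(n_samples)
    tau = np.empty(n_samples)
    for i, th in enumerate(angles):
        pose = base.with_angle(dof, th)
        r[i] = moment_arm(model, pose, path, dof)
        tau[i] = joint_moment(model, pose, path, params, dof, activation=activation)
    if normalization_ref:
        r = r / normalization_ref
    return RomSweep(dof, angles, r, tau, normalization_ref)


def zero_crossings(sweep: RomSweep, tol: float = ZERO_TOL) -> list[float]:
    """Angles (rad) where the moment arm changes sign, by linear interpolation.

    Samples exactly at zero are reported once, at their own angle.
    """
    th, r = sweep.angles, sweep.moment_arms
    if len(th) == 0:
        raise ValueError("empty sweep")
    out: list[float] = []
    for i in range(len(r)):
        if abs(r[i]) <= tol:
            if not out or not np.isclose(out[-1], th[i]):
                out.append(float(th[i]))
        elif i + 1 < len(r) and abs(r[i + 1]) > tol and r[i] * r[i + 1] < 0:
            frac = r[i] / (r[i] - r[i + 1])
            out.append(float(th[i] + frac * (th[i + 1] - th[i])))
    return out


def functional_map(
    model: SkeletonModel,
    muscles: dict[str, tuple[MusclePath, MuscleParams]],
    default_pose: Pose | None = None,
    n_samples: int = 50,
    epsilon: float = EPSILON_THRESHOLD,
) -> FunctionalMap:
    """Functional grouping of muscles by maximal moment arm and moment.

    For every muscle and every DoF it spans, the DoF is split into its two
    directions by the sign of r; max |r| and |tau| are recorded per
    direction and normalized within each (dof, direction) group by the
    group's dominant muscle.  Muscles spanning a joint with r identically
    zero get the grey-box ``zero_influence`` flag.
    """
    if not muscles:
        raise ValueError("need at least one muscle")
    entries: list[FunctionalEntry] = []
    for name, (path, params) in muscles.items():
        for dof in spanned_dofs(model, path):
            sweep = rom_sweep(
                model, path, params, dof, n_samples=n_samples,
                default_pose=default_pose,
            )
            r, tau = sweep.moment_arms, sweep.moments
            crossing = bool(r.max() > ZERO_TOL and r.min() < -ZERO_TOL)
            all_zero = bool(np.all(np.abs(r) <= ZERO_TOL))
            for direction, mask in (("positive", r > ZERO_TOL), ("negative", r < -ZERO_TOL)):
                entries.append(
                    FunctionalEntry(
                        muscle=name,
                        dof=dof,
                        direction=direction,
                        max_moment_arm=float(np.abs(r[mask]).max()) if mask.any() else 0.0,
                        max_moment=float(np.abs(tau[mask]).max()) if mask.any() else 0.0,
                        zero_influence=all_zero,
                        zero_crossing=crossing,
                    )
                )
    # normalize within (dof, direction) groups by the dominant muscle
    for key in {(e.dof, e.direction) for e in entries}:
        group = [e for e in entries if (e.dof, e.direction) == key]
        max_r = max(e.max_moment_arm for e in group)
        max_t = max(e.max_moment for e in group)
        for e in group:
            e.norm_moment_arm = e.max_moment_arm / max_r if max_r > 0 else 0.0
            e.norm_moment = e.max_moment / max_t if max_t > 0 else 0.0
            e.epsilon = 0.0 < e.norm_moment_arm <= epsilon
    return FunctionalMap(entries)


def fiber_length_range(
    model: SkeletonModel,
    path: MusclePath,
    params: MuscleParams,
    grid_per_dof: int = DEFAULT_GRID_PER_DOF,
    base_pose: Pose | None = None,
    cap: int = GRID_CAP,
    seed: int = 0,
    allow_subsample: bool = True,
) -> FiberRange:
    """Operating range of normalized fiber length over the full ROM grid.

    Evaluates l~m on the Cartesian grid of all spanned-DoF ranges
    (``grid_per_dof`` points each).  Beyond ``cap`` grid poses a seeded
    uniform subsample is taken; pass ``allow_subsample=False`` to make that
    an error instead.
    """
    if grid_per_dof < 2:
        raise ValueError("grid_per_dof must be >= 2")
    dofs = spanned_dofs(model, path)
    base = dict(base_pose.angles) if base_pose else {}
    axes = [np.linspace(*model.dof(d).range, grid_per_dof) for d in dofs]
    n_total = int(np.prod([len(a) for a in axes])) if dofs else 1
    if n_total > cap:
        if not allow_subsample:
            raise ValueError(
                f"{path.muscle}: {n_total} grid poses exceed cap {cap}; "
                "pass allow_subsample=True to subsample"
            )
        rng = np.random.default_rng(seed)
        combos = [
            tuple(rng.choice(a) for a in axes) for _ in range(cap)
        ]
    else:
        combos = itertools.product(*axes) if dofs else [()]
    lo = np.inf
    hi = -np.inf
    for angles in combos:
        pose = Pose({**base, **dict(zip(dofs, angles))})
        lmt = muscle_tendon_length(model, pose, path)
        l_norm = fiber_state_rigid_tendon(params, lmt).l_m_norm
        lo = min(lo, l_norm)
        hi = max(hi, l_norm)
    if hi <= 1.0:
        region = "active-only"
    elif lo > 1.0:
        region = "passive-only"
    else:
        region = "mixed"
    return FiberRange(path.muscle, float(lo), float(hi), region)
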