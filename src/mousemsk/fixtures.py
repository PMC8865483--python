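"""Synthetic test fixtures with closed-form references.

These small models exercise every geometric and muscle-mechanical code
path against analytic oracles, without any external geometry:

* :func:`pendulum_fixture` — two segments and one hinge; the muscle runs
  from a point at distance ``a`` from the hinge on the parent to a point
  at distance ``b`` on the child.  By the law of cosines
  ``lmt(theta) = sqrt(a^2 + b^2 + 2 a b cos(theta))`` (theta measured from
  the straight configuration), with the exact moment arm
  ``r(theta) = -a b sin(theta) / lmt``.
* :func:`two_dof_chain_fixture` — a three-segment chain with two hinges
  and one muscle spanning both, for multi-DoF estimation tests.
* :func:`scaled_model_fixture` — any fixture with all geometry multiplied
  by a factor ``k``; every lmt scales exactly by ``k``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from .model_io import LoadedModel, parse_model
from .muscle import MuscleParams
from .paths import MusclePath
from .skeleton import SkeletonModel

__all__ = [
    "Fixture",
    "pendulum_fixture",
    "two_dof_chain_fixture",
    "scaled_model_fixture",
]


@dataclass
class Fixture:
    name: str
    config: dict
    loaded: LoadedModel
    lmt_ref: Callable[..., float] | None = None
    r_ref: Callable[..., float] | None = None
    seed: int = 0

    @property
    def model(self) -> SkeletonModel:
        return self.loaded.skeleton

    @property
    def path(self) -> MusclePath:
        return next(iter(self.loaded.muscles.values()))[0]

    @property
    def params(self) -> MuscleParams:
        return next(iter(self.loaded.muscles.values()))[1]


def pendulum_fixture(
    a: float = 10.0,
    b: float = 10.0,
    range_deg: tuple[float, float] = (1.0, 179.0),
    params: dict | None = None,
) -> Fixture:
    """Two-segment hinge model with an ``a``/``b`` pendulum muscle.

    theta = 0 is the straight configuration (lmt = a + b); positive theta
    folds the child toward the origin attachment, shortening the muscle,
    so r(theta) < 0 on (0, 180 deg).
    """
    if a <= 0 or b <= 0:
        raise ValueError("lever distances a, b must be > 0")
    p = {"f_max_N": 1.0, "l_opt_mm": 8.0, "l_slack_mm": 6.0,
         "alpha_opt_deg": 0.0}
    p.update(params or {})
    config = {
        "name": "pendulum",
        "segments": [
            {"name": "parent", "origin_mm": [0.0, 0.0, 0.0]},
            {"name": "child", "origin_mm": [0.0, 0.0, 0.0]},
        ],
        "joints": [
            {
                "name": "hinge",
                "parent": "parent",
                "child": "child",
                "center_mm": [0.0, 0.0, 0.0],
                "dofs": [
                    {"name": "theta", "axis": [0, 0, 1],
                     "range_deg": list(range_deg)}
                ],
            }
        ],
        "muscles": [
            {
                "name": "pendulum_muscle",
                **p,
                "path": [
                    {"segment": "parent", "xyz_mm": [-a, 0.0, 0.0],
                     "role": "origin"},
                    {"segment": "child", "xyz_mm": [b, 0.0, 0.0],
                     "role": "insertion"},
                ],
            }
        ],
    }

    def lmt_ref(theta: float) -> float:
        return math.sqrt(a * a + b * b + 2 * a * b * math.cos(theta))

    def r_ref(theta: float) -> float:
        return -a * b * math.sin(theta) / lmt_ref(theta)

    return Fixture("pendulum", config, parse_model(config), lmt_ref, r_ref)


def two_dof_chain_fixture(
    link: float = 12.0,
    offset: float = 2.0,
    range_deg: tuple[float, float] = (-60.0, 60.0),
    params: dict | None = None,
) -> Fixture:
    """Three-segment serial chain, two hinges, one muscle spanning both.

    The muscle runs from the proximal link over a waypoint on the middle
    link to the distal link, offset ``offset`` mm laterally so both hinges
    see a nonzero moment arm.  No closed-form lmt; oracles are numeric.
    """
    p = {"f_max_N": 1.0, "l_opt_mm": 10.0, "l_slack_mm": 8.0,
         "alpha_opt_deg": 0.0}
    p.update(params or {})
    config = {
        "name": "two_dof_chain",
        "segments": [
            {"name": "base", "origin_mm": [0.0, 0.0, 0.0]},
            {"name": "mid", "origin_mm": [link, 0.0, 0.0]},
            {"name": "tip", "origin_mm": [link, 0.0, 0.0]},
        ],
        "joints": [
            {
                "name": "j1", "parent": "base", "child": "mid",
                "center_mm": [link, 0.0, 0.0],
                "dofs": [{"name": "q1", "axis": [0, 0, 1],
                          "range_deg": list(range_deg)}],
            },
            {
                "name": "j2", "parent": "mid", "child": "tip",
                "center_mm": [link, 0.0, 0.0],
                "dofs": [{"name": "q2", "axis": [0, 0, 1],
                          "range_deg": list(range_deg)}],
            },
        ],
        "muscles": [
            {
                "name": "chain_muscle",
                **p,
                "path": [
                    {"segment": "base", "xyz_mm": [link / 2, offset, 0.0],
                     "role": "origin"},
                    {"segment": "mid", "xyz_mm": [link / 2, offset, 0.0],
                     "role": "waypoint"},
                    {"segment": "tip", "xyz_mm": [link / 2, offset, 0.0],
                     "role": "insertion"},
                ],
            }
        ],
    }
    return Fixture("two_dof_chain", config, parse_model(config))


def _scale_vec(v, k):
    return [float(x) * k for x in v]


def scaled_model_fixture(base: Fixture, k: float) -> Fixture:
    """Copy of ``base`` with every length (placements, rotation centers,
    attachment coordinates) multiplied by ``k``; lmt scales exactly by
    ``k`` at every pose.  Muscle parameters are left unscaled — recovering
    their scale factors is the point of the estimation tests."""
    if k <= 0:
        raise ValueError("scale factor k must be > 0")
    import copy

    config = copy.deepcopy(base.config)
    config["name"] = f"{base.config.get('name', base.name)}_x{k:g}"
    for s in config.get("segments", []):
        if "origin_mm" in s:
            s["origin_mm"] = _scale_vec(s["origin_mm"], k)
    for j in config.get("joints", []):
        if "center_mm" in j:
            j["center_mm"] = _scale_vec(j["center_mm"], k)
    for m in config.get("muscles", []):
        for pt in m["path"]:
            pt["xyz_mm"] = _scale_vec(pt["xyz_mm"], k)
    lmt_ref = (lambda th, f=base.lmt_ref: k * f(th)) if base.lmt_ref else None
    r_ref = (lambda th, f=base.r_ref: k * f(th)) if base.r_ref else None
    return Fixture(config["name"], config, parse_model(config), lmt_ref, r_ref,
                   seed=base.seed)
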