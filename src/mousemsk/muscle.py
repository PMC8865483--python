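"""Rigid-tendon Hill-type muscle model.

A muscle-tendon unit is parameterized by maximum isometric force ``f_max``
(Fm0, N), optimal fiber length ``l_opt`` (lmo, mm), tendon slack length
``l_slack`` (lts, mm), pennation angle at optimum ``alpha_opt`` (deg) and
maximum fiber velocity ``v_max`` (in l_opt/s, default 10).  Under the
rigid-tendon assumption the tendon stays at its slack length, so fiber
geometry follows directly from the muscle-tendon length lmt via the
fixed-height pennation model (lm * sin(alpha) is constant):

    lm    = sqrt((lmt - lts)^2 + (l_opt * sin(alpha_opt))^2)
    alpha = atan2(l_opt * sin(alpha_opt), lmt - lts)

Force along the tendon line of action:

    F = Fm0 * (a * f_act(l~m) * f_v(v~) + f_pas(l~m)) * cos(alpha)

with l~m = lm / l_opt the normalized fiber length and v~ the normalized
fiber velocity.  The dimensionless curves f_act, f_pas, f_v live in
:class:`CurveSet`; all shape constants are in that one block so alternate
curve sets are drop-in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MuscleParams",
    "FiberState",
    "CurveSet",
    "DEFAULT_CURVES",
    "fiber_state_rigid_tendon",
    "muscle_force",
    "fm0_from_pcsa",
]

PENNATION_CAP_DEG = 89.0
MIN_FIBER_FRACTION = 0.01  # floor on lm as a fraction of l_opt


@dataclass(frozen=True)
class MuscleParams:
    name: str
    f_max: float  # Fm0, N
    l_opt: float  # lmo, mm
    l_slack: float  # lts, mm
    alpha_opt: float = 0.0  # deg
    v_max: float = 10.0  # l_opt / s
    group: str = ""

    def __post_init__(self) -> None:
        if self.f_max <= 0:
            raise ValueError(f"{self.name}: f_max must be > 0")
        if self.l_opt <= 0:
            raise ValueError(f"{self.name}: l_opt must be > 0")
        if self.l_slack < 0:
            raise ValueError(f"{self.name}: l_slack must be >= 0")
        if not 0.0 <= self.alpha_opt < 90.0:
            raise ValueError(f"{self.name}: alpha_opt must be in [0, 90)")
        if self.v_max <= 0:
            raise ValueError(f"{self.name}: v_max must be > 0")

    @property
    def alpha_opt_rad(self) -> float:
        return math.radians(self.alpha_opt)

    @property
    def pennation_height(self) -> float:
        """Constant h = l_opt * sin(alpha_opt) of the fixed-height model (mm)."""
        return self.l_opt * math.sin(self.alpha_opt_rad)


@dataclass(frozen=True)
class FiberState:
    l_m: float  # fiber length, mm
    alpha: float  # pennation, rad
    l_m_norm: float  # lm / l_opt
    l_t: float  # tendon length, mm (== l_slack under rigid tendon)
    slack: bool = False  # fiber was clamped at its minimum length


@dataclass(frozen=True)
class CurveSet:
    """Dimensionless Hill curves with all shape constants in one place.

    * Active force-length: sum of Gaussians, each (weight, center, width);
      the default single term peaks at l~m = 1 with f_act(1) = 1 exactly.
    * Passive force-length: exponential engaging at l~m = 1, reaching 1 at
      strain ``pas_strain`` (i.e. at l~m = 1 + pas_strain).
    * Force-velocity: Hill hyperbola for shortening, smooth saturating
      branch for lengthening with plateau ``fv_ecc_plateau`` and a slope
      matched at v~ = 0 (C1 continuity).
    """

    act_gaussians: tuple[tuple[float, float, float], ...] = ((1.0, 1.0, 0.45),)
    pas_strain: float = 0.6
    pas_shape: float = 4.0
    fv_shape: float = 0.25  # Hill a_f parameter
    fv_ecc_plateau: float = 1.4

    def f_act(self, l_norm):
        l = np.asarray(l_norm, dtype=float)
        out = np.zeros_like(l)
        for w, c, width in self.act_gaussians:
            out = out + w * np.exp(-((l - c) ** 2) / width)
        return out if out.ndim else float(out)

    def f_pas(self, l_norm):
        l = np.asarray(l_norm, dtype=float)
        k, e0 = self.pas_shape, self.pas_strain
        out = np.where(
            l > 1.0,
            (np.exp(k * np.clip(l - 1.0, 0.0, None) / e0) - 1.0) / (math.exp(k) - 1.0),
            0.0,
        )
        return out if out.ndim else float(out)

    def f_v(self, v_norm):
        v = np.asarray(v_norm, dtype=float)
        a = self.fv_shape
        fl = self.fv_ecc_plateau
        con = np.clip(1.0 + v, 0.0, None) / (1.0 - np.clip(v, None, 0.0) / a)
        slope0 = 1.0 + 1.0 / a  # concentric-side slope at v~ = 0
        c = (fl - 1.0) / slope0
        ecc = fl - (fl - 1.0) * c / (c + np.clip(v, 0.0, None))
        out = np.where(v < 0.0, con, ecc)
        return out if out.ndim else float(out)


DEFAULT_CURVES = CurveSet()


def fiber_state_rigid_tendon(params: MuscleParams, lmt: float) -> FiberState:
    """Fiber length and pennation from muscle-tendon length, rigid tendon.

    If the fiber would fall below ``MIN_FIBER_FRACTION * l_opt`` (a slack
    fiber, possible when lmt <= l_slack at zero pennation), the length is
    clamped there and the state is flagged ``slack=True``.
    """
    h = params.pennation_height
    proj = lmt - params.l_slack  # fiber length projected on the tendon line
    slack = proj <= 0.0
    l_m = math.sqrt(max(proj, 0.0) ** 2 + h * h)
    floor = MIN_FIBER_FRACTION * params.l_opt
    l_m = max(l_m, floor)
    alpha = math.atan2(h, max(proj, 0.0))
    alpha = min(alpha, math.radians(PENNATION_CAP_DEG))
    return FiberState(
        l_m=l_m,
        alpha=alpha,
        l_m_norm=l_m / params.l_opt,
        l_t=params.l_slack,
        slack=slack,
    )


def muscle_force(
    params: MuscleParams,
    activation: float,
    lmt: float,
    vmt: float = 0.0,
    curves: CurveSet = DEFAULT_CURVES,
) -> float:
    """Tendon-line force (N) at activation ``a``, length ``lmt`` and velocity ``vmt``.

    ``vmt`` is the muscle-tendon lengthening velocity in mm/s; under the
    rigid tendon all of it is taken up by the fiber, so the normalized
    fiber velocity is v~ = vmt / (v_max * l_opt * cos(alpha)).  Slack
    fibers transmit no force.
    """
    if not 0.0 <= activation <= 1.0:
        raise ValueError(f"activation must be in [0, 1], got {activation}")
    st = fiber_state_rigid_tendon(params, lmt)
    if st.slack:
        return 0.0
    cos_a = math.cos(st.alpha)
    v_norm = vmt / (params.v_max * params.l_opt * cos_a)
    f_norm = (
        activation * curves.f_act(st.l_m_norm) * curves.f_v(v_norm)
        + curves.f_pas(st.l_m_norm)
    )
    return max(params.f_max * f_norm * cos_a, 0.0)


def fm0_from_pcsa(pcsa: float, sigma: float = 0.3) -> float:
    """Maximum isometric force from PCSA (mm^2) at isometric stress sigma (N/mm^2)."""
    if pcsa <= 0:
        raise ValueError(f"pcsa must be > 0, got {pcsa}")
    return pcsa * sigma
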