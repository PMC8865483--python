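"""Landmark-based affine registration for attachment-point transfer.

Muscle attachment coordinates defined on one bone geometry are carried to
another by a 12-parameter affine transform estimated from manually picked
landmark pairs (>= 4 non-coplanar source points).  The estimate is the
least-squares minimizer of sum_i ||A s_i + t - d_i||^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LandmarkSet",
    "AffineTransform",
    "DegenerateLandmarksError",
    "estimate_affine",
    "transfer_points",
]

_COND_LIMIT = 1e10


class DegenerateLandmarksError(ValueError):
    """Source landmarks are coplanar or otherwise rank-deficient."""


@dataclass(frozen=True)
class LandmarkSet:
    source: np.ndarray  # (n, 3) mm
    target: np.ndarray  # (n, 3) mm

    def __post_init__(self) -> None:
        object.__setattr__(self, "source", np.asarray(self.source, float))
        object.__setattr__(self, "target", np.asarray(self.target, float))
        if self.source.shape != self.target.shape or self.source.ndim != 2:
            raise ValueError("source and target must be matching (n, 3) arrays")
        if len(self.source) < 4:
            raise ValueError("affine estimation needs >= 4 landmark pairs")


@dataclass(frozen=True)
class AffineTransform:
    matrix: np.ndarray  # (3, 4): [A | t]

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 3]

    def apply(self, points) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, float))
        out = p @ self.linear.T + self.translation
        return out if np.asarray(points).ndim == 2 else out[0]

    def inverse(self) -> "AffineTransform":
        A_inv = np.linalg.inv(self.linear)
        return AffineTransform(np.hstack([A_inv, (-A_inv @ self.translation)[:, None]]))


def estimate_affine(landmarks: LandmarkSet) -> tuple[AffineTransform, np.ndarray]:
    """Least-squares affine from landmark pairs.

    Returns the transform and the per-landmark residual norms (mm).  With
    exactly 4 non-degenerate pairs the fit interpolates (residuals ~ 0).
    Raises :class:`DegenerateLandmarksError` for coplanar source sets,
    reporting the design-matrix condition number.
    """
    S = np.hstack([landmarks.source, np.ones((len(landmarks.source), 1))])
    cond = np.linalg.cond(S)
    if np.linalg.matrix_rank(S, tol=None) < 4 or cond > _COND_LIMIT:
        raise DegenerateLandmarksError(
            f"source landmarks are coplanar/degenerate (condition number {cond:.3g})"
        )
    coef, *_ = np.linalg.lstsq(S, landmarks.target, rcond=None)  # (4, 3)
    transform = AffineTransform(coef.T)
    residuals = np.linalg.norm(
        transform.apply(landmarks.source) - landmarks.target, axis=1
    )
    return transform, residuals


def transfer_points(transform: AffineTransform, points) -> np.ndarray:
    """Apply ``A p + t`` elementwise to a list/array of 3-vectors."""
    return transform.apply(points)
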