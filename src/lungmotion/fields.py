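"""Closed-form deformation fields used as phantom ground truth.

A field maps expiration-frame world positions x (mm) to displacements u(x)
(mm); the forward transform is T(x) = x + u(x) into inspiration space.  Each
field exposes its Jacobian determinant det(∇T) (finite-difference fallback,
analytic where cheap) and a fixed-point inverse, which is all the phantom
builder needs to realise a mass-preserving warp exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FoldingFieldError


class AnalyticDeformation:
    """Base class: a smooth closed-form displacement field u(x) in mm."""

    def displacement(self, points: np.ndarray) -> np.ndarray:
        """Displacement (mm) at world points of shape (..., 3)."""
        raise NotImplementedError

    def transform(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points + self.displacement(points)

    def jacobian_det(self, points: np.ndarray, h: float = 0.25) -> np.ndarray:
        """det(I + ∇u) by central differences with step ``h`` mm."""
        pts = np.asarray(points, dtype=float)
        grad = np.empty(pts.shape[:-1] + (3, 3))
        for e in range(3):
            dp = np.zeros(3)
            dp[e] = h
            grad[..., :, e] = (
                self.displacement(pts + dp) - self.displacement(pts - dp)
            ) / (2.0 * h)
        eye = np.eye(3)
        return np.linalg.det(eye + grad)

    def invert(self, points: np.ndarray, iterations: int = 20) -> np.ndarray:
        """Solve T(x) = y for x by fixed-point iteration x <- y - u(x).

        Converges when the field's displacement gradient has norm < 1, which
        every shipped phantom field satisfies by construction.
        """
        y = np.asarray(points, dtype=float)
        x = y - self.displacement(y)
        for _ in range(iterations):
            x = y - self.displacement(x)
        return x

    def check_diffeomorphic(self, points: np.ndarray) -> None:
        j = self.jacobian_det(points)
        if np.any(j <= 0):
            raise FoldingFieldError("non-positive Jacobian determinant (folding field)")


@dataclass
class TranslationField(AnalyticDeformation):
    """Rigid translation: u(x) = t; J = 1 everywhere (trivially mass neutral)."""

    t: tuple[float, float, float]

    def displacement(self, points):
        points = np.asarray(points, dtype=float)
        return np.broadcast_to(np.asarray(self.t, dtype=float), points.shape).copy()

    def jacobian_det(self, points, h: float = 0.25):
        return np.ones(np.asarray(points).shape[:-1])


@dataclass
class LinearField(AnalyticDeformation):
    """Affine displacement u(x) = M (x - c) + t with constant J = det(I + M)."""

    M: np.ndarray
    t: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def displacement(self, points):
        pts = np.asarray(points, dtype=float)
        rel = pts - np.asarray(self.center, dtype=float)
        return rel @ np.asarray(self.M, dtype=float).T + np.asarray(self.t, dtype=float)

    def jacobian_det(self, points, h: float = 0.25):
        j = float(np.linalg.det(np.eye(3) + np.asarray(self.M, dtype=float)))
        return np.full(np.asarray(points).shape[:-1], j)


def smoothstep(w: np.ndarray) -> np.ndarray:
    """Cubic ramp 3w^2 - 2w^3 on clipped w in [0, 1]."""
    w = np.clip(w, 0.0, 1.0)
    return w * w * (3.0 - 2.0 * w)


def smoothstep_deriv(w: np.ndarray) -> np.ndarray:
    wc = np.clip(w, 0.0, 1.0)
    d = 6.0 * wc * (1.0 - wc)
    return np.where((w <= 0.0) | (w >= 1.0), 0.0, d)


@dataclass
class TaperedDomeField(AnalyticDeformation):
    """Dome-descent breathing field with a smooth apico-basal taper.

    The displacement amplitude follows a cubic ramp in depth from the lung
    apex plane ``z_top`` (zero displacement) to the basal reference plane
    ``z_bottom`` (full amplitude):

        w(z) = (z_top - z) / (z_top - z_bottom), clipped to [0, 1]
        u(x) = smoothstep(w) * (dx, dy, dz)

    ``dz < 0`` is diaphragm descent on inspiration.  Because u depends only on
    z, the Jacobian determinant reduces to 1 + d(u_z)/dz exactly, which stays
    positive whenever |dz| * 1.5 < z_top - z_bottom.
    """

    amplitudes: tuple[float, float, float]
    z_top: float
    z_bottom: float

    def __post_init__(self):
        if self.z_top <= self.z_bottom:
            raise ValueError("z_top must exceed z_bottom")

    def _ramp(self, z):
        return (self.z_top - np.asarray(z, dtype=float)) / (self.z_top - self.z_bottom)

    def displacement(self, points):
        pts = np.asarray(points, dtype=float)
        s = smoothstep(self._ramp(pts[..., 2]))
        return s[..., None] * np.asarray(self.amplitudes, dtype=float)

    def jacobian_det(self, points, h: float = 0.25):
        pts = np.asarray(points, dtype=float)
        w = self._ramp(pts[..., 2])
        height = self.z_top - self.z_bottom
        duz_dz = self.amplitudes[2] * smoothstep_deriv(w) * (-1.0 / height)
        return 1.0 + duz_dz
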