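"""Inter-camera 2D affine registration.

Each secondary camera is related to the reference camera by a 6-parameter
affine map estimated from matched bead localizations.  Transforms are always
stored in the secondary -> reference direction and every localization table
carries reference-frame coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .errors import RegistrationError

__all__ = ["AffineTransform2D", "match_points", "estimate_affine"]

_SINGULAR_TOL = 1e-12


@dataclass(frozen=True)
class AffineTransform2D:
    """p_ref = linear @ p_sec + translation, points as (x, y) pairs."""

    linear: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        lin = np.asarray(self.linear, dtype=float).reshape(2, 2)
        tr = np.asarray(self.translation, dtype=float).reshape(2)
        if abs(np.linalg.det(lin)) <= _SINGULAR_TOL:
            raise RegistrationError("affine linear part is singular")
        object.__setattr__(self, "linear", lin)
        object.__setattr__(self, "translation", tr)

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.eye(2), np.zeros(2))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return points @ self.linear.T + self.translation

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return AffineTransform2D(self.linear @ other.linear,
                                 self.linear @ other.translation + self.translation)

    def invert(self) -> "AffineTransform2D":
        inv = np.linalg.inv(self.linear)
        return AffineTransform2D(inv, -inv @ self.translation)

    @property
    def params(self) -> np.ndarray:
        """The 6 parameters (a11, a12, a21, a22, tx, ty)."""
        return np.concatenate([self.linear.ravel(), self.translation])


def match_points(points_a: np.ndarray, points_b: np.ndarray, max_dist: float):
    """Mutual-nearest-neighbour correspondences within ``max_dist`` pixels.

    Returns (idx_a, idx_b) index arrays; each point is used at most once.
    """
    if max_dist <= 0:
        raise RegistrationError("max_dist must be positive")
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise RegistrationError("empty point set")
    tree_a, tree_b = cKDTree(a), cKDTree(b)
    d_ab, nn_ab = tree_b.query(a, distance_upper_bound=max_dist)
    _, nn_ba = tree_a.query(b, distance_upper_bound=max_dist)
    pairs = [(i, int(j)) for i, j in enumerate(nn_ab)
             if j < len(b) and np.isfinite(d_ab[i]) and nn_ba[j] == i]
    if len(pairs) < 3:
        raise RegistrationError(
            f"only {len(pairs)} correspondences found; an affine needs at least 3")
    idx_a, idx_b = map(np.asarray, zip(*pairs))
    return idx_a, idx_b


def match_points_assignment(points_a, points_b, max_dist: float):
    """Globally optimal assignment (Hungarian) — the brute-force oracle for
    :func:`match_points` on clean data; exposed for validation studies."""
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    cost = np.linalg.norm(a[:, None] - b[None, :], axis=-1)
    big = 1e9
    cost = np.where(cost <= max_dist, cost, big)
    ia, ib = linear_sum_assignment(cost)
    keep = cost[ia, ib] < big
    return ia[keep], ib[keep]


def estimate_affine(points_sec: np.ndarray, points_ref: np.ndarray) -> tuple[AffineTransform2D, float]:
    """Least-squares affine mapping ``points_sec`` onto ``points_ref``.

    Returns the transform and the RMS residual (px) of the fit.
    """
    sec = np.atleast_2d(np.asarray(points_sec, dtype=float))
    ref = np.atleast_2d(np.asarray(points_ref, dtype=float))
    if sec.shape != ref.shape or len(sec) < 3:
        raise RegistrationError("need >= 3 paired points of identical shape")
    # collinearity check: rank of centred secondary cloud
    centred = sec - sec.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-9 * max(1.0, np.abs(sec).max())) < 2:
        raise RegistrationError("points are collinear; affine is underdetermined")
    design = np.column_stack([sec, np.ones(len(sec))])
    sol, *_ = np.linalg.lstsq(design, ref, rcond=None)
    linear = sol[:2].T
    translation = sol[2]
    t = AffineTransform2D(linear, translation)
    residual = t.apply(sec) - ref
    rms = float(np.sqrt(np.mean(np.sum(residual**2, axis=1))))
    return t, rms
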