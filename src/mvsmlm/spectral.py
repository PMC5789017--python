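"""Spectrally-resolved STORM color assignment.

Each localization's per-channel fitted signals are normalized into a
4-component vector of relative signal per color channel.  Dyes are then
assigned either by the vector's first moment along the channel axis (a single
scalar per localization) or by k-means clustering of the 4-vectors with
fractional rejection: after assigning every localization to its nearest
cluster mean, the globally worst fraction (by distance to the assigned mean)
is discarded, which trades a known fraction of the data for lower cross-talk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .errors import ConfigurationError, FitError

__all__ = ["ClusterModel", "channel_vector", "first_moment", "train_clusters",
           "classify", "crosstalk_matrix", "first_moment_classify"]


def channel_vector(plane_signals) -> tuple[np.ndarray | None, bool]:
    """Normalize per-channel signals to a unit-sum vector.

    Returns (vector, rejected): degenerate inputs (all-zero or any negative
    channel) yield (None, True) — a flag, not an exception, since they are a
    routine outcome of fitting dim localizations.
    """
    s = np.asarray(plane_signals, dtype=float)
    if s.ndim != 1 or s.size != 4:
        raise ConfigurationError("plane_signals must be a length-4 vector")
    total = s.sum()
    if total <= 0 or np.any(s < 0):
        return None, True
    return s / total, False


def channel_vectors(signals) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`channel_vector` over an (n, 4) array.

    Returns (vectors, rejected_mask); rejected rows are filled with NaN.
    """
    s = np.asarray(signals, dtype=float)
    total = s.sum(axis=1)
    rejected = (total <= 0) | np.any(s < 0, axis=1)
    out = np.full_like(s, np.nan)
    good = ~rejected
    out[good] = s[good] / total[good, None]
    return out, rejected


def first_moment(vector) -> float:
    """Mean channel index weighted by relative signal: sum_i i * v_i in [0, 3]."""
    v = np.asarray(vector, dtype=float)
    if v.ndim != 1 or v.size != 4:
        raise ConfigurationError("spectral vector must have 4 components")
    return float(np.dot(np.arange(4), v))


@dataclass(frozen=True)
class ClusterModel:
    """k cluster mean 4-vectors plus training metadata."""

    means: np.ndarray
    rejection_fraction: float
    n_training: int
    seed: int

    def __post_init__(self):
        means = np.atleast_2d(np.asarray(self.means, dtype=float))
        if means.shape[0] < 2:
            raise ConfigurationError("cluster model needs k >= 2 means")
        if not (0 <= self.rejection_fraction < 1):
            raise ConfigurationError("rejection fraction must be in [0, 1)")
        object.__setattr__(self, "means", means)

    @property
    def k(self) -> int:
        return self.means.shape[0]


def train_clusters(vectors: np.ndarray, k: int, seed: int,
                   rejection_fraction: float = 0.20) -> ClusterModel:
    """k-means on normalized spectral vectors with a fixed seed.

    Uses k-means++ initialization; an empty cluster triggers re-initialization
    with a derived seed, up to 10 restarts.
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    if len(vectors) < k:
        raise ConfigurationError(f"need at least k={k} vectors, got {len(vectors)}")
    for restart in range(10):
        km = KMeans(n_clusters=k, init="k-means++", n_init=1,
                    random_state=(seed + restart) % (2**31)).fit(vectors)
        counts = np.bincount(km.labels_, minlength=k)
        if counts.min() > 0:
            # order clusters by their first moment so labels are reproducible
            order = np.argsort([first_moment(m) for m in km.cluster_centers_])
            return ClusterModel(km.cluster_centers_[order], rejection_fraction,
                                len(vectors), seed)
    raise FitError("k-means produced an empty cluster in 10 seeded restarts")


def classify(model: ClusterModel, vectors: np.ndarray,
             rejection_fraction: float | None = None):
    """Nearest-mean assignment with global fractional rejection.

    Every vector is assigned to the Euclidean-nearest cluster mean; the top
    ``rejection_fraction`` of assignments ranked by that distance are then
    discarded globally (distance ties broken toward keeping the lower index).

    Returns (labels, rejected_mask); rejected entries keep their label but are
    flagged.
    """
    if rejection_fraction is None:
        rejection_fraction = model.rejection_fraction
    if not (0 <= rejection_fraction < 1):
        raise ConfigurationError("rejection fraction must be in [0, 1)")
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    d = np.linalg.norm(vectors[:, None, :] - model.means[None, :, :], axis=-1)
    labels = np.argmin(d, axis=1)
    nearest = d[np.arange(len(vectors)), labels]
    n_reject = int(np.floor(rejection_fraction * len(vectors) + 1e-9))
    rejected = np.zeros(len(vectors), dtype=bool)
    if n_reject > 0:
        # sort by distance descending, ties by higher index first (keep lower)
        order = np.lexsort((np.arange(len(vectors)), nearest))[::-1]
        rejected[order[:n_reject]] = True
    return labels, rejected


def first_moment_classify(vectors: np.ndarray, training_vectors: np.ndarray,
                          training_labels: np.ndarray):
    """Classify by first moment with cuts at midpoints between the per-dye
    moment medians of a labelled training set.

    Returns (labels, thresholds); labels refer to dyes ordered by median
    moment.
    """
    moments = np.array([first_moment(v) for v in np.atleast_2d(vectors)])
    tm = np.array([first_moment(v) for v in np.atleast_2d(training_vectors)])
    classes = np.unique(training_labels)
    medians = np.array([np.median(tm[training_labels == c]) for c in classes])
    order = np.argsort(medians)
    classes, medians = classes[order], medians[order]
    thresholds = 0.5 * (medians[:-1] + medians[1:])
    idx = np.searchsorted(thresholds, moments)
    return classes[idx], thresholds


def crosstalk_matrix(true_labels, assigned_labels, k: int):
    """Row-normalized confusion matrix and its maximum off-diagonal entry.

    Entry (i, j) is the fraction of true-class-i localizations assigned to
    class j; rejected localizations must already be excluded.  An empty true
    class yields a NaN row (flagged, not an error).
    """
    true_labels = np.asarray(true_labels, dtype=int)
    assigned_labels = np.asarray(assigned_labels, dtype=int)
    if true_labels.shape != assigned_labels.shape:
        raise ConfigurationError("label arrays must be aligned")
    counts = np.zeros((k, k))
    np.add.at(counts, (true_labels, assigned_labels), 1.0)
    rowsum = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        matrix = np.where(rowsum > 0, counts / rowsum, np.nan)
    off = matrix.copy()
    np.fill_diagonal(off, 0.0)
    max_off = float(np.nanmax(off)) if np.isfinite(off).any() else np.nan
    return matrix, max_off
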