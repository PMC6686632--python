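"""Point-cloud container used throughout the liana extraction pipeline.

A :class:`PointCloud` holds TLS returns as an ``(N, 3)`` array of xyz
coordinates in meters, optionally together with per-point class labels
(``1`` = liana woody point, ``2`` = everything else: tree wood, foliage,
ground, noise) and per-point probabilities of being a liana woody point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PointCloud", "ValidationError", "LIANA", "OTHER"]

#: Class label for liana woody points (the positive / minority class).
LIANA = 1
#: Class label for all other returns (tree wood, leaves, ground, noise).
OTHER = 2


class ValidationError(ValueError):
    """Raised when point-cloud data violates a structural invariant."""


def _as_coords(value) -> np.ndarray:
    coords = np.asarray(value, dtype=np.float64)
    if coords.size == 0:
        return coords.reshape(0, 3)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValidationError(f"coords must have shape (N, 3), got {coords.shape}")
    if not np.isfinite(coords).all():
        raise ValidationError("coords contain non-finite values")
    return coords


@dataclass
class PointCloud:
    """TLS point cloud with optional labels and class-1 probabilities.

    Parameters
    ----------
    coords : (N, 3) float array
        Point coordinates in meters.
    labels : (N,) int array, optional
        Per-point class labels in ``{1, 2}``.
    probs : (N,) float array, optional
        Per-point probability of class 1 (liana wood), in ``[0, 1]``.
    source_id : str, optional
        Plot / scene identifier (e.g. ``"NOU_4"``).
    """

    coords: np.ndarray
    labels: np.ndarray | None = None
    probs: np.ndarray | None = None
    source_id: str | None = field(default=None)

    def __post_init__(self) -> None:
        self.coords = _as_coords(self.coords)
        n = len(self.coords)
        if self.labels is not None:
            labels = np.asarray(self.labels)
            if labels.shape != (n,):
                raise ValidationError(f"labels must have shape ({n},), got {labels.shape}")
            if labels.size and not np.isin(labels, (LIANA, OTHER)).all():
                bad = np.unique(labels[~np.isin(labels, (LIANA, OTHER))])
                raise ValidationError(f"labels must be in {{1, 2}}; found {bad.tolist()}")
            self.labels = labels.astype(np.int64)
        if self.probs is not None:
            probs = np.asarray(self.probs, dtype=np.float64)
            if probs.shape != (n,):
                raise ValidationError(f"probs must have shape ({n},), got {probs.shape}")
            if probs.size and (not np.isfinite(probs).all() or probs.min() < 0 or probs.max() > 1):
                raise ValidationError("probs must lie in [0, 1]")
            self.probs = probs

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def has_labels(self) -> bool:
        return self.labels is not None

    def select(self, index) -> "PointCloud":
        """Return the sub-cloud at ``index`` (any numpy fancy index)."""
        return PointCloud(
            coords=self.coords[index],
            labels=None if self.labels is None else self.labels[index],
            probs=None if self.probs is None else self.probs[index],
            source_id=self.source_id,
        )

    def with_labels(self, labels) -> "PointCloud":
        return PointCloud(self.coords, labels=labels, probs=self.probs, source_id=self.source_id)

    def with_probs(self, probs) -> "PointCloud":
        return PointCloud(self.coords, labels=self.labels, probs=probs, source_id=self.source_id)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounding box as ``(min_corner, max_corner)``."""
        if len(self) == 0:
            raise ValidationError("empty cloud has no bounds")
        return self.coords.min(axis=0), self.coords.max(axis=0)

    def equals(self, other: "PointCloud", coord_tol: float = 0.0) -> bool:
        if len(self) != len(other):
            return False
        if coord_tol == 0.0:
            if not np.array_equal(self.coords, other.coords):
                return False
        elif not np.allclose(self.coords, other.coords, rtol=0.0, atol=coord_tol):
            return False
        for a, b in ((self.labels, other.labels), (self.probs, other.probs)):
            if (a is None) != (b is None):
                return False
            if a is not None and not np.array_equal(a, b):
                return False
        return True
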