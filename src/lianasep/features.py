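"""Multi-scale normalized eigenvalue features.

For every point, a sphere of radius *r* is drawn around it at each of a set
of spatial scales (default 0.1, 0.25, 0.5, 0.75, 1.0 m). The eigenvalues of
the 3x3 covariance matrix of the point together with its in-sphere
neighbors, sorted descending and divided by their sum, describe the local
shape at that scale: a thin liana stem is close to (1, 0, 0) (one dominant
direction of variance), a planar patch close to (0.5, 0.5, 0), and diffuse
foliage close to (1/3, 1/3, 1/3). Concatenating the triple over five scales
gives the 15-dimensional predictor vector of the classifier.

Neighbor search uses a k-d tree with exact closed-ball semantics (distance
<= r, target point included) and is evaluated in chunks to bound memory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .cloud import PointCloud, ValidationError

__all__ = [
    "ScaleSet",
    "FeatureMatrix",
    "DEGENERATE_TRIPLE",
    "neighborhood",
    "local_eigenvalues",
    "compute_features",
]

#: Neutral fallback for degenerate neighborhoods (fewer than 3 points or
#: zero total variance); the accompanying valid mask records the fallback.
DEGENERATE_TRIPLE = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)

_MIN_NEIGHBORS = 3  # covariance of < 3 points cannot span a useful shape


@dataclass(frozen=True)
class ScaleSet:
    """Ordered spherical-neighborhood radii, meters."""

    radii: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75, 1.0)

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.radii)
        if not radii:
            raise ValidationError("ScaleSet needs at least one radius")
        if any(r <= 0 for r in radii):
            raise ValidationError("radii must all be > 0")
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValidationError("radii must be strictly increasing")
        object.__setattr__(self, "radii", radii)

    def __len__(self) -> int:
        return len(self.radii)

    @property
    def n_features(self) -> int:
        return 3 * len(self.radii)

    def column_names(self) -> list[str]:
        return [f"l{k}_r{r:.2f}" for r in self.radii for k in (1, 2, 3)]


@dataclass
class FeatureMatrix:
    """Per-point normalized eigenvalue triples across scales.

    ``values[i, 3*s:3*s+3]`` holds (lambda1, lambda2, lambda3) of point *i*
    at scale *s*; within each valid triple the values are descending,
    non-negative and sum to 1. ``valid_mask[i]`` is False when any scale's
    neighborhood of point *i* was degenerate (the triple is then the neutral
    fallback 1/3, 1/3, 1/3).
    """

    values: np.ndarray
    valid_mask: np.ndarray
    scales: ScaleSet

    def __len__(self) -> int:
        return len(self.values)

    def to_dataframe(self, cloud: PointCloud | None = None) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.scales.column_names())
        if cloud is not None:
            for j, axis in enumerate("xyz"):
                frame.insert(j, axis, cloud.coords[:, j])
        frame["valid"] = self.valid_mask
        return frame


def neighborhood(cloud: PointCloud, index: int, radius: float) -> np.ndarray:
    """Indices of all points within ``radius`` (inclusive) of point ``index``.

    The target point itself is always part of its own neighborhood.
    """
    if radius <= 0:
        raise ValidationError("radius must be > 0")
    tree = cKDTree(cloud.coords)
    idx = tree.query_ball_point(cloud.coords[index], radius)
    return np.sort(np.asarray(idx, dtype=np.intp))


def local_eigenvalues(points: np.ndarray) -> tuple[float, float, float]:
    """Normalized covariance eigenvalues of a neighborhood, descending.

    Uses the population covariance (divisor M); the divisor cancels under
    the normalization, which divides each eigenvalue by the sum of all
    three. Raises for degenerate input (fewer than 3 points, or all points
    coincident so the total variance is zero).
    """
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if len(pts) < _MIN_NEIGHBORS:
        raise ValidationError(f"need at least {_MIN_NEIGHBORS} points, got {len(pts)}")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    eig = np.linalg.eigvalsh(cov)[::-1]
    eig = np.clip(eig, 0.0, None)
    total = eig.sum()
    if total <= 0.0:
        raise ValidationError("zero total variance (all points coincident)")
    lam = eig / total
    return float(lam[0]), float(lam[1]), float(lam[2])


def compute_features(
    cloud: PointCloud,
    scales: ScaleSet = ScaleSet(),
    chunk_size: int = 2048,
) -> FeatureMatrix:
    """Compute the multi-scale eigenvalue features for every point.

    Degenerate neighborhoods at any scale yield the neutral fallback triple
    for that scale and clear the point's entry in the valid mask.
    ``chunk_size`` bounds how many query points are expanded into neighbor
    lists at once (memory control; the result is exact regardless).
    """
    n = len(cloud)
    if n == 0:
        raise ValidationError("cannot compute features of an empty cloud")
    coords = cloud.coords
    tree = cKDTree(coords)
    values = np.empty((n, scales.n_features))
    valid = np.ones(n, dtype=bool)
    for s, radius in enumerate(scales.radii):
        cols = slice(3 * s, 3 * s + 3)
        for start in range(0, n, chunk_size):
            stop = min(start + chunk_size, n)
            triples, ok = _eigen_chunk(tree, coords, start, stop, radius)
            values[start:stop, cols] = triples
            valid[start:stop] &= ok
    return FeatureMatrix(values=values, valid_mask=valid, scales=scales)


def _eigen_chunk(
    tree: cKDTree, coords: np.ndarray, start: int, stop: int, radius: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized covariance eigenvalues for points [start, stop)."""
    query = coords[start:stop]
    lists = tree.query_ball_point(query, radius)
    counts = np.fromiter((len(l) for l in lists), dtype=np.int64, count=len(lists))
    m = len(query)
    triples = np.full((m, 3), 1.0 / 3.0)
    ok = counts >= _MIN_NEIGHBORS
    if not ok.any():
        return triples, ok
    flat = np.concatenate([lists[i] for i in np.flatnonzero(ok)])
    cnt = counts[ok]
    bounds = np.concatenate([[0], np.cumsum(cnt)[:-1]])
    # shift to the chunk centroid: covariance is translation-invariant and
    # the shift avoids cancellation in the moment sums far from the origin
    pts = coords[flat] - query.mean(axis=0)
    # per-neighborhood first and second moments via segmented sums
    s1 = np.empty((len(cnt), 3))
    for j in range(3):
        s1[:, j] = np.add.reduceat(pts[:, j], bounds)
    mean = s1 / cnt[:, None]
    cov = np.empty((len(cnt), 3, 3))
    for a in range(3):
        for b in range(a, 3):
            s2 = np.add.reduceat(pts[:, a] * pts[:, b], bounds)
            c = s2 / cnt - mean[:, a] * mean[:, b]
            cov[:, a, b] = c
            cov[:, b, a] = c
    eig = np.linalg.eigvalsh(cov)[:, ::-1]
    eig = np.clip(eig, 0.0, None)
    totals = eig.sum(axis=1)
    nonzero = totals > 0.0
    lam = np.full_like(eig, 1.0 / 3.0)
    lam[nonzero] = eig[nonzero] / totals[nonzero, None]
    triples[ok] = lam
    ok2 = ok.copy()
    ok2[np.flatnonzero(ok)[~nonzero]] = False
    return triples, ok2
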