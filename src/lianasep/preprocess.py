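"""Voxel-grid downsampling and statistical outlier removal (SOR).

Both operate on real returns only: the voxel filter keeps one *input* point
per occupied cell (never a synthesized centroid), so label and probability
columns stay attached to actual measurements, and SOR partitions the input
into a kept and a removed set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud, ValidationError

__all__ = ["SORParams", "voxel_downsample", "sor_filter"]


@dataclass(frozen=True)
class SORParams:
    """Statistical-outlier-removal settings.

    ``n_points`` nearest neighbors (excluding the point itself) define each
    point's mean neighbor distance d_i; points with
    ``d_i > mean(d) + n_sigma * sd(d)`` are removed. Defaults follow the
    CloudCompare SOR defaults used for noise filtering of predicted liana
    points: 6 neighbors, 1.0 standard deviations.
    """

    n_points: int = 6
    n_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValidationError("n_points must be a positive integer")
        if self.n_sigma < 0:
            raise ValidationError("n_sigma must be non-negative")


def voxel_downsample(cloud: PointCloud, voxel_size: float) -> PointCloud:
    """Keep at most one point per occupied voxel of an axis-aligned grid.

    The grid is aligned to integer multiples of ``voxel_size`` (the cell
    containing the cloud's minimum corner anchors it), which makes the
    filter idempotent: points that each already occupy distinct cells are
    returned unchanged. Within a cell the retained point is the input point
    nearest the centroid of the cell's points.
    """
    if voxel_size <= 0:
        raise ValidationError("voxel_size must be > 0")
    n = len(cloud)
    if n == 0:
        return cloud.select(np.empty(0, dtype=np.intp))
    keys = np.floor(cloud.coords / voxel_size).astype(np.int64)
    _, inverse, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    n_voxels = len(counts)
    sums = np.zeros((n_voxels, 3))
    np.add.at(sums, inverse, cloud.coords)
    centroids = sums / counts[:, None]
    dist2 = np.einsum("ij,ij->i", cloud.coords - centroids[inverse], cloud.coords - centroids[inverse])
    # first point per voxel in (voxel, distance, index) order is the representative
    order = np.lexsort((np.arange(n), dist2, inverse))
    first = np.zeros(n_voxels, dtype=np.intp)
    first[inverse[order[::-1]]] = order[::-1]  # overwrite so earliest order wins
    keep = np.sort(first)
    return cloud.select(keep)


def sor_filter(
    cloud: PointCloud, params: SORParams = SORParams()
) -> tuple[PointCloud, np.ndarray]:
    """Remove points whose mean k-NN distance is anomalously large.

    Returns ``(kept_cloud, removed_indices)``; the two index sets partition
    the input. Removal uses the strict inequality ``d_i > mu + n_sigma * sd``
    so that a perfectly regular lattice (sd = 0) is left intact.
    """
    n = len(cloud)
    if n <= params.n_points:
        raise ValidationError(
            f"SOR needs more than n_points={params.n_points} points, got {n}; "
            "reduce n_points"
        )
    tree = cKDTree(cloud.coords)
    dists, _ = tree.query(cloud.coords, k=params.n_points + 1)
    mean_dist = dists[:, 1:].mean(axis=1)  # drop self (distance 0)
    mu = mean_dist.mean()
    sigma = mean_dist.std()
    removed_mask = mean_dist > mu + params.n_sigma * sigma
    removed = np.flatnonzero(removed_mask)
    return cloud.select(~removed_mask), removed
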