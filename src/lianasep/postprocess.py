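"""Four-step correction of the classifier's predictions.

The raw random-forest output has high precision but misses liana points
(low recall). The correction chain is:

1. SOR-filter the predicted liana points (drops ghost/noise false
   positives; removed points are relabelled class 2).
2. Apply an optional removal mask — a scriptable stand-in for interactive
   polygon editing — relabelling the masked class-1 points to class 2.
3. DBSCAN-cluster the predicted class-2 points.
4. Relabel to class 1 every class-2 cluster whose minimum point distance to
   a cluster of the corrected liana points is within the DBSCAN eps (the
   condition under which DBSCAN would merge the two clusters); this
   recovers contiguous liana segments the model missed. Noise points are
   never recovered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

from .cloud import LIANA, OTHER, PointCloud, ValidationError
from .preprocess import SORParams, sor_filter

__all__ = [
    "DBSCANParams",
    "ClusterAssignment",
    "dbscan",
    "apply_mask",
    "mask_indices",
    "load_mask",
    "recover_false_negatives",
    "run_postprocess",
]


@dataclass(frozen=True)
class DBSCANParams:
    """Density-clustering settings; defaults suit a 0.04 m point spacing.

    ``eps`` is the neighborhood radius in meters and ``min_pts`` the number
    of points (counting the point itself) required within eps for a core
    point.
    """

    eps: float = 0.05
    min_pts: int = 5

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValidationError("eps must be > 0")
        if self.min_pts < 1:
            raise ValidationError("min_pts must be a positive integer")


@dataclass
class ClusterAssignment:
    """Per-point cluster ids: 0..C-1 for clusters, -1 for noise."""

    cluster_id: np.ndarray

    @property
    def n_clusters(self) -> int:
        ids = self.cluster_id
        return int(ids.max()) + 1 if ids.size and ids.max() >= 0 else 0

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.cluster_id == cluster)


def dbscan(cloud: PointCloud, params: DBSCANParams = DBSCANParams()) -> ClusterAssignment:
    """Standard DBSCAN over the cloud's coordinates.

    Border points reachable from several clusters go to the first cluster
    reached in the index-ordered scan, making the assignment deterministic.
    """
    if len(cloud) < 1:
        raise ValidationError("dbscan needs at least one point")
    labels = DBSCAN(eps=params.eps, min_samples=params.min_pts).fit_predict(cloud.coords)
    return ClusterAssignment(cluster_id=labels.astype(np.int64))


def load_mask(path):
    """Load a removal mask: JSON list of {min,max} boxes, or one index per line."""
    text = Path(path).read_text().strip()
    if text.startswith("["):
        boxes = json.loads(text)
        for box in boxes:
            if set(box) != {"min", "max"} or len(box["min"]) != 3 or len(box["max"]) != 3:
                raise ValidationError(f"{path}: boxes need 3-element 'min' and 'max'")
        return boxes
    if not text:
        return np.empty(0, dtype=np.intp)
    try:
        return np.array([int(line) for line in text.splitlines() if line.strip()],
                        dtype=np.intp)
    except ValueError as exc:
        raise ValidationError(f"{path}: not an index list or JSON boxes: {exc}") from None


def mask_indices(cloud: PointCloud, mask) -> np.ndarray:
    """Resolve a mask (index list or box list) to point indices of ``cloud``."""
    if mask is None:
        return np.empty(0, dtype=np.intp)
    if isinstance(mask, (list, tuple)) and mask and isinstance(mask[0], dict):
        hit = np.zeros(len(cloud), dtype=bool)
        for box in mask:
            lo = np.asarray(box["min"], dtype=np.float64)
            hi = np.asarray(box["max"], dtype=np.float64)
            hit |= np.all((cloud.coords >= lo) & (cloud.coords <= hi), axis=1)
        return np.flatnonzero(hit)
    idx = np.asarray(mask, dtype=np.intp).ravel()
    if idx.size and (idx.min() < 0 or idx.max() >= len(cloud)):
        raise ValidationError(
            f"mask index out of range for cloud of {len(cloud)} points"
        )
    return idx


def apply_mask(cloud: PointCloud, mask) -> PointCloud:
    """Remove the masked points (indices or axis-aligned boxes) from the cloud."""
    idx = mask_indices(cloud, mask)
    keep = np.ones(len(cloud), dtype=bool)
    keep[idx] = False
    return cloud.select(keep)


def recover_false_negatives(
    class2_cloud: PointCloud,
    liana_cloud: PointCloud,
    params: DBSCANParams = DBSCANParams(),
) -> np.ndarray:
    """Indices of class-2 points in clusters adjacent to a liana cluster.

    Both clouds are clustered independently; a class-2 cluster is recovered
    iff its minimum inter-point distance to any liana cluster is <= eps.
    DBSCAN noise points on either side never take part.
    """
    if len(class2_cloud) == 0 or len(liana_cloud) == 0:
        raise ValidationError("both clouds must be non-empty")
    c2 = dbscan(class2_cloud, params)
    c1 = dbscan(liana_cloud, params)
    liana_clustered = c1.cluster_id >= 0
    if not liana_clustered.any():
        return np.empty(0, dtype=np.intp)
    tree = cKDTree(liana_cloud.coords[liana_clustered])
    candidate = c2.cluster_id >= 0
    if not candidate.any():
        return np.empty(0, dtype=np.intp)
    cand_idx = np.flatnonzero(candidate)
    dist, _ = tree.query(class2_cloud.coords[cand_idx], k=1,
                         distance_upper_bound=params.eps * (1 + 1e-9))
    touching = dist <= params.eps
    recovered_clusters = np.unique(c2.cluster_id[cand_idx[touching]])
    return np.flatnonzero(np.isin(c2.cluster_id, recovered_clusters) & candidate)


def run_postprocess(
    cloud: PointCloud,
    pred_labels,
    mask=None,
    sor: SORParams = SORParams(),
    db: DBSCANParams = DBSCANParams(),
) -> tuple[np.ndarray, dict]:
    """Run the full correction chain; returns (corrected labels, change log).

    The change log records, per step, how many points changed label and
    their indices into ``cloud``.
    """
    labels = np.asarray(pred_labels).copy()
    if labels.shape != (len(cloud),):
        raise ValidationError("pred_labels must align with the cloud")
    log: dict = {}

    # Step 1: SOR on the predicted liana points; outliers become class 2
    idx1 = np.flatnonzero(labels == LIANA)
    step1: np.ndarray = np.empty(0, dtype=np.intp)
    if len(idx1) > sor.n_points:
        _, removed = sor_filter(cloud.select(idx1), sor)
        step1 = idx1[removed]
        labels[step1] = OTHER
    log["step1_sor"] = {"relabelled": int(len(step1)), "indices": step1.tolist()}

    # Step 2: masked class-1 points become class 2
    midx = mask_indices(cloud, mask)
    step2 = midx[labels[midx] == LIANA] if midx.size else np.empty(0, dtype=np.intp)
    labels[step2] = OTHER
    log["step2_mask"] = {"relabelled": int(len(step2)), "indices": step2.tolist()}

    # Steps 3-4: cluster the class-2 points and recover those connected to
    # the corrected liana clusters
    idx2 = np.flatnonzero(labels == OTHER)
    idx1 = np.flatnonzero(labels == LIANA)
    step34: np.ndarray = np.empty(0, dtype=np.intp)
    if len(idx2) and len(idx1):
        recovered = recover_false_negatives(cloud.select(idx2), cloud.select(idx1), db)
        step34 = idx2[recovered]
        labels[step34] = LIANA
    log["step34_recovered"] = {"relabelled": int(len(step34)), "indices": step34.tolist()}
    return labels, log
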