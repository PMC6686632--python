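"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (all-pairs loops, explicit
covariance assembly, literal threshold sweeps) and shares no code with the
package's optimized paths.
"""

from __future__ import annotations

import numpy as np


def brute_neighborhood(coords: np.ndarray, index: int, radius: float) -> np.ndarray:
    """All-pairs closed-ball neighborhood (self included)."""
    out = []
    for j in range(len(coords)):
        d = np.sqrt(((coords[index] - coords[j]) ** 2).sum())
        if d <= radius:
            out.append(j)
    return np.array(sorted(out), dtype=np.intp)


def brute_eigen_triple(points: np.ndarray) -> tuple[float, float, float]:
    """Hand-assembled covariance (explicit outer-product loop) -> eigenvalues."""
    pts = np.asarray(points, dtype=np.float64)
    mean = pts.sum(axis=0) / len(pts)
    cov = np.zeros((3, 3))
    for p in pts:
        d = p - mean
        cov += np.outer(d, d)
    cov /= len(pts)
    eig = sorted(np.linalg.eigvalsh(cov), reverse=True)
    eig = [max(e, 0.0) for e in eig]
    total = sum(eig)
    return tuple(e / total for e in eig)


def brute_features(coords: np.ndarray, radii) -> tuple[np.ndarray, np.ndarray]:
    """Per-point multi-scale triples via the naive oracles above."""
    n = len(coords)
    values = np.full((n, 3 * len(radii)), 1.0 / 3.0)
    valid = np.ones(n, dtype=bool)
    for i in range(n):
        for s, r in enumerate(radii):
            nbr = brute_neighborhood(coords, i, r)
            if len(nbr) < 3:
                valid[i] = False
                continue
            pts = coords[nbr]
            if np.allclose(pts, pts[0]):
                valid[i] = False
                continue
            values[i, 3 * s : 3 * s + 3] = brute_eigen_triple(pts)
    return values, valid


def brute_sor(coords: np.ndarray, n_points: int, n_sigma: float) -> np.ndarray:
    """Removed indices via an all-pairs mean-kNN-distance computation."""
    n = len(coords)
    mean_d = np.empty(n)
    for i in range(n):
        dists = sorted(
            np.sqrt(((coords[i] - coords[j]) ** 2).sum())
            for j in range(n) if j != i
        )
        mean_d[i] = np.mean(dists[:n_points])
    mu = mean_d.mean()
    sigma = mean_d.std()
    return np.flatnonzero(mean_d > mu + n_sigma * sigma)


def brute_dbscan(coords: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Classic DBSCAN with an index-ordered scan and core-point expansion."""
    n = len(coords)
    nbrs = [
        [j for j in range(n) if np.sqrt(((coords[i] - coords[j]) ** 2).sum()) <= eps]
        for i in range(n)
    ]
    core = [len(nbrs[i]) >= min_pts for i in range(n)]
    labels = np.full(n, -1, dtype=np.int64)
    cluster = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        labels[i] = cluster
        frontier = [i]
        while frontier:
            p = frontier.pop()
            for q in nbrs[p]:
                if labels[q] == -1:
                    labels[q] = cluster
                    if core[q]:
                        frontier.append(q)
        cluster += 1
    return labels


def canonical_clustering(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by first occurrence so partitions compare exactly."""
    out = np.full(len(labels), -1, dtype=np.int64)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab == -1:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def brute_ap(probs: np.ndarray, true_labels: np.ndarray) -> float:
    """Literal recall-increment-weighted precision sum over all thresholds."""
    thresholds = sorted(set(probs), reverse=True)
    n_pos = int(np.sum(true_labels == 1))
    ap = 0.0
    prev_recall = 0.0
    for t in thresholds:
        pred_pos = probs >= t
        tp = int(np.sum(pred_pos & (true_labels == 1)))
        precision = tp / int(pred_pos.sum())
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap
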