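"""Synthetic TLS-like forest plots with known liana/other labels.

The generator emulates the geometric and class-imbalance structure the
classifier relies on, at desk scale: vertical tapered cylinders for tree
stems (diameter > 10 cm), thin tubes for liana stems (diameter <= 10 cm)
that either spiral up a host tree or follow a looping 3D spline that dips
toward the ground before ascending, isotropic scatter blobs for foliage, a
ground layer, and a handful of uniform "ghost" returns. Surfaces are
sampled area-uniformly at roughly the voxel spacing of a downsampled TLS
cloud; Gaussian jitter models ranging noise. Liana tube points carry class
1, everything else class 2, which puts the class-1 fraction in the few-
percent range typical of real plots.

Lianas keep a standoff from host bark, foliage and ground so that the
density-based post-processing's connectivity condition (clusters within
eps of each other merge) behaves as it does in real scans at 0.04 m
spacing; see the methods note for what this does and does not emulate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .cloud import LIANA, OTHER, PointCloud, ValidationError

__all__ = ["SceneConfig", "LabeledScene", "generate_scene", "perturb_labels"]

_GROUND_CLEARANCE = 0.25  # min liana centerline height above ground, m
_CROWN_BASE = 0.65        # leaf blobs occupy the top (1 - _CROWN_BASE) of a tree
_HELIX_TOP = 0.55         # helix climbs to this fraction of host height
_HELIX_PITCH = 1.5        # m of height per helix turn


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic plot; all lengths in meters."""

    plot_extent: tuple[float, float] = (6.0, 6.0)
    n_trees: int = 4
    tree_dbh_range: tuple[float, float] = (0.15, 0.60)
    tree_height_range: tuple[float, float] = (5.0, 8.0)
    n_lianas: int = 3
    liana_diameter_range: tuple[float, float] = (0.01, 0.08)
    liana_path: str = "helix_on_tree"  # or "looping_spline"
    liana_standoff: float = 0.10
    leaf_blob_count: int = 4  # per tree
    leaf_blob_radius: float = 0.35
    ground: bool = True
    surface_point_spacing: float = 0.04
    noise_sigma: float = 0.005
    ghost_point_count: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.liana_path not in ("helix_on_tree", "looping_spline"):
            raise ValidationError(
                f"liana_path must be helix_on_tree or looping_spline, got {self.liana_path!r}"
            )
        if self.n_lianas > 0 and self.liana_path == "helix_on_tree" and self.n_trees == 0:
            raise ValidationError("helix_on_tree lianas need at least one host tree")
        if self.surface_point_spacing <= 0:
            raise ValidationError("surface_point_spacing must be > 0")
        if min(self.plot_extent) <= 0:
            raise ValidationError("plot_extent must be positive")


@dataclass
class LabeledScene:
    """A labeled synthetic plot plus per-point provenance.

    ``provenance[i]`` names the primitive that produced point *i*
    (``tree_0``, ``liana_1``, ``leaf_0_2``, ``ground``, ``ghost``);
    ``liana_param[i]`` is the arclength along the generating centerline for
    liana points (NaN otherwise), and ``centerlines`` maps each liana name
    to its centerline polyline for distance checks.
    """

    cloud: PointCloud
    provenance: np.ndarray
    liana_param: np.ndarray
    centerlines: dict[str, np.ndarray]
    config: SceneConfig

    def stats(self) -> dict:
        labels = self.cloud.labels
        names, counts = np.unique(self.provenance, return_counts=True)
        n = len(self.cloud)
        return {
            "n_points": int(n),
            "n_class1": int(np.sum(labels == LIANA)),
            "class1_fraction_pct": float(100.0 * np.mean(labels == LIANA)) if n else 0.0,
            "per_primitive": {str(k): int(v) for k, v in zip(names, counts)},
            "seed": self.config.seed,
        }

    def stats_to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(self.stats(), handle, indent=2)


# ---------------------------------------------------------------------------
# primitive samplers


def _sample_ground(cfg: SceneConfig, rng) -> np.ndarray:
    s = cfg.surface_point_spacing
    xs = np.arange(s / 2, cfg.plot_extent[0], s)
    ys = np.arange(s / 2, cfg.plot_extent[1], s)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    n = gx.size
    jitter = rng.uniform(-0.45 * s, 0.45 * s, size=(n, 2))
    pts = np.column_stack([gx.ravel() + jitter[:, 0], gy.ravel() + jitter[:, 1],
                           np.zeros(n)])
    return pts


def _tree_positions(cfg: SceneConfig, rng) -> np.ndarray:
    margin = 0.8
    min_sep = 1.5
    lo = np.array([margin, margin])
    hi = np.array(cfg.plot_extent) - margin
    if np.any(hi <= lo):
        raise ValidationError("plot too small to place trees 0.8 m from the edge")
    placed: list[np.ndarray] = []
    for _ in range(cfg.n_trees):
        for _attempt in range(200):
            pos = rng.uniform(lo, hi)
            if all(np.linalg.norm(pos - p) >= min_sep for p in placed):
                placed.append(pos)
                break
        else:
            raise ValidationError(
                f"could not place {cfg.n_trees} trees >= {min_sep} m apart in "
                f"{cfg.plot_extent[0]} x {cfg.plot_extent[1]} m"
            )
    return np.array(placed).reshape(-1, 2)


def _sample_tapered_cylinder(center, r_base, r_top, height, spacing, rng) -> np.ndarray:
    """Area-uniform sample of a vertical tapered cylinder's lateral surface."""
    slant = np.hypot(height, r_base - r_top)
    area = np.pi * (r_base + r_top) * slant
    n = max(8, int(round(area / spacing**2)))
    # radius varies linearly with z; sample z with density proportional to r(z)
    u = rng.uniform(size=n)
    if abs(r_base - r_top) < 1e-12:
        z = u * height
    else:
        a, b = r_base, (r_top - r_base) / height
        # invert the CDF of pdf ~ a + b z on [0, height]
        total = a * height + 0.5 * b * height**2
        z = (-a + np.sqrt(a**2 + 2 * b * u * total)) / b
    r = r_base + (r_top - r_base) * z / height
    theta = rng.uniform(0, 2 * np.pi, size=n)
    return np.column_stack(
        [center[0] + r * np.cos(theta), center[1] + r * np.sin(theta), z]
    )


def _sample_blob(center, radius, spacing, rng) -> np.ndarray:
    """Isotropic Gaussian scatter truncated at 2 sigma (sigma = radius/2)."""
    n = max(20, int(round(4.0 * (radius / spacing) ** 2)))
    sigma = radius / 2
    pts = np.empty((0, 3))
    while len(pts) < n:
        cand = rng.normal(0.0, sigma, size=(2 * n, 3))
        cand = cand[np.linalg.norm(cand, axis=1) <= 2 * sigma]
        pts = np.vstack([pts, cand])
    return center + pts[:n]


def _resample_polyline(points: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at equal arclength steps; returns (points, arclength)."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(0.0, arc[-1], step)
    out = np.column_stack(
        [np.interp(targets, arc, points[:, j]) for j in range(3)]
    )
    return out, targets


def _tube_surface(
    centerline: np.ndarray, arclength: np.ndarray, radius: float, spacing: float, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Rings of points around a centerline; returns (points, per-point arclength)."""
    tangents = np.gradient(centerline, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    ref = np.array([0.0, 0.0, 1.0])
    n1 = np.cross(tangents, ref)
    norms = np.linalg.norm(n1, axis=1)
    vertical = norms < 1e-6
    n1[vertical] = [1.0, 0.0, 0.0]
    n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
    n2 = np.cross(tangents, n1)
    k = max(3, int(round(2 * np.pi * radius / spacing)))
    phase = rng.uniform(0, 2 * np.pi, size=len(centerline))
    angles = phase[:, None] + np.linspace(0, 2 * np.pi, k, endpoint=False)[None, :]
    pts = (
        centerline[:, None, :]
        + radius * np.cos(angles)[:, :, None] * n1[:, None, :]
        + radius * np.sin(angles)[:, :, None] * n2[:, None, :]
    ).reshape(-1, 3)
    params = np.repeat(arclength, k)
    return pts, params


def _helix_centerline(cfg: SceneConfig, host_xy, r_base, r_top, height, r_liana, rng):
    z_top = _HELIX_TOP * height
    z = np.arange(_GROUND_CLEARANCE + 0.05, z_top, 0.01)
    taper = r_base + (r_top - r_base) * z / height
    radius = taper + cfg.liana_standoff + r_liana
    theta = rng.uniform(0, 2 * np.pi) + 2 * np.pi * z / _HELIX_PITCH
    return np.column_stack(
        [host_xy[0] + radius * np.cos(theta), host_xy[1] + radius * np.sin(theta), z]
    )


def _spline_centerline(cfg: SceneConfig, tree_xy, tree_radii, z_cap, rng):
    margin = 0.5
    lo = np.array([margin, margin])
    hi = np.array(cfg.plot_extent) - margin
    n_ctrl = 8
    xy = np.empty((n_ctrl, 2))
    xy[0] = rng.uniform(lo, hi)
    for i in range(1, n_ctrl):
        xy[i] = np.clip(xy[i - 1] + rng.uniform(-1.5, 1.5, size=2), lo, hi)
    peaks = rng.uniform(0.6 * z_cap, z_cap, size=4)
    z = np.array([0.4, peaks[0], 0.5, peaks[1], 0.45, peaks[2], 0.5, peaks[3]])
    ctrl = np.column_stack([xy, z])
    spline = CubicSpline(np.arange(n_ctrl), ctrl, axis=0)
    dense = spline(np.linspace(0, n_ctrl - 1, 1200))
    dense[:, 2] = np.clip(dense[:, 2], _GROUND_CLEARANCE + 0.05, z_cap)
    # keep clear of tree trunks: push centerline radially away where too close
    for (cx, cy), r_tree in zip(tree_xy, tree_radii):
        delta = dense[:, :2] - (cx, cy)
        dist = np.linalg.norm(delta, axis=1)
        min_dist = r_tree + cfg.liana_standoff + 0.1
        close = dist < min_dist
        if close.any():
            safe = np.where(dist[close] > 1e-9, dist[close], 1e-9)
            dense[close, :2] = (cx, cy) + delta[close] / safe[:, None] * min_dist
    return dense


# ---------------------------------------------------------------------------


def generate_scene(config: SceneConfig = SceneConfig()) -> LabeledScene:
    """Generate one labeled plot; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    s = config.surface_point_spacing
    chunks: list[np.ndarray] = []
    names: list[np.ndarray] = []
    params: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    centerlines: dict[str, np.ndarray] = {}

    def add(pts, name, label, param=None):
        chunks.append(pts)
        names.append(np.full(len(pts), name, dtype=object))
        labels.append(np.full(len(pts), label, dtype=np.int64))
        params.append(np.full(len(pts), np.nan) if param is None else param)

    tree_xy = _tree_positions(config, rng) if config.n_trees else np.empty((0, 2))
    dbh = rng.uniform(*config.tree_dbh_range, size=config.n_trees)
    heights = rng.uniform(*config.tree_height_range, size=config.n_trees)
    r_base = dbh / 2
    r_top = 0.4 * r_base

    for k in range(config.n_trees):
        add(
            _sample_tapered_cylinder(tree_xy[k], r_base[k], r_top[k], heights[k], s, rng),
            f"tree_{k}", OTHER,
        )
        for j in range(config.leaf_blob_count):
            offset = rng.uniform(0.15, 0.5)
            angle = rng.uniform(0, 2 * np.pi)
            center = np.array(
                [tree_xy[k, 0] + offset * np.cos(angle),
                 tree_xy[k, 1] + offset * np.sin(angle),
                 rng.uniform(_CROWN_BASE * heights[k], 0.95 * heights[k])]
            )
            add(_sample_blob(center, config.leaf_blob_radius, s, rng), f"leaf_{k}_{j}", OTHER)

    z_cap = _HELIX_TOP * float(heights.min()) if config.n_trees else 3.0
    for k in range(config.n_lianas):
        r_liana = rng.uniform(*config.liana_diameter_range) / 2
        if config.liana_path == "helix_on_tree":
            host = k % config.n_trees
            dense = _helix_centerline(
                config, tree_xy[host], r_base[host], r_top[host], heights[host], r_liana, rng
            )
        else:
            dense = _spline_centerline(config, tree_xy, r_base, z_cap, rng)
        centerline, arc = _resample_polyline(dense, s)
        pts, par = _tube_surface(centerline, arc, r_liana, s, rng)
        name = f"liana_{k}"
        centerlines[name] = centerline
        add(pts, name, LIANA, par)

    if config.ground:
        add(_sample_ground(config, rng), "ground", OTHER)

    if config.ghost_point_count:
        top = float(heights.max()) if config.n_trees else 5.0
        ghosts = rng.uniform(
            [0.0, 0.0, 0.0],
            [config.plot_extent[0], config.plot_extent[1], top],
            size=(config.ghost_point_count, 3),
        )
        add(ghosts, "ghost", OTHER)

    if not chunks:
        raise ValidationError("scene config produced no points")
    coords = np.vstack(chunks)
    if config.noise_sigma > 0:
        coords = coords + rng.normal(0.0, config.noise_sigma, size=coords.shape)
    cloud = PointCloud(
        coords,
        labels=np.concatenate(labels),
        source_id=f"synthetic_seed{config.seed}",
    )
    return LabeledScene(
        cloud=cloud,
        provenance=np.concatenate(names),
        liana_param=np.concatenate(params),
        centerlines=centerlines,
        config=config,
    )


def perturb_labels(
    scene: LabeledScene,
    fn_segment_fraction: float = 0.0,
    fp_count: int = 0,
    seed: int = 0,
) -> np.ndarray:
    """Simulated model predictions with the classifier's known error modes.

    For each liana, a contiguous run of the tube (a window of the
    centerline arclength covering ``fn_segment_fraction`` of its length) is
    flipped to class 2 — mimicking thick straight sections that look like
    tree wood. ``fp_count`` isolated class-2 points (ghost returns first,
    then random other points) are flipped to class 1. Deterministic given
    ``seed``.
    """
    if not 0 <= fn_segment_fraction <= 1:
        raise ValidationError("fn_segment_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = scene.cloud.labels.copy()
    if fn_segment_fraction > 0:
        for name in scene.centerlines:
            member = scene.provenance == name
            par = scene.liana_param[member]
            lo, hi = par.min(), par.max()
            span = (hi - lo) * fn_segment_fraction
            start = rng.uniform(lo, hi - span) if hi - lo > span else lo
            window = member.copy()
            window[member] = (par >= start) & (par <= start + span)
            labels[window] = OTHER
    if fp_count:
        class2 = np.flatnonzero(labels == OTHER)
        if fp_count > len(class2):
            raise ValidationError(f"fp_count={fp_count} exceeds class-2 points")
        ghosts = class2[scene.provenance[class2] == "ghost"]
        others = class2[scene.provenance[class2] != "ghost"]
        rng.shuffle(ghosts)
        rng.shuffle(others)
        chosen = np.concatenate([ghosts, others])[:fp_count]
        labels[chosen] = LIANA
    return labels
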