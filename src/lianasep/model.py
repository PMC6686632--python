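"""Random-forest classification of liana woody points.

Covers class-imbalance handling (majority under-sampling), training and
prediction, the hyperparameter grid search, and the three spatial
cross-validation schemes (self-site, cross-site, mixed-site) in which
validation folds are spatially disjoint sub-areas rather than random point
subsets, so that spatial autocorrelation cannot leak between train and
validation data.

The public front end is :class:`LianaForestModel` /
:class:`LianaForestResults` (construct from features+labels or directly
from labeled clouds, ``fit`` and inspect); the module-level functions
implement the individual pipeline operations the model and the CLI build
on.
"""

from __future__ import annotations

from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .cloud import LIANA, OTHER, PointCloud, ValidationError
from .evaluate import EvaluationReport, aggregate_reports, evaluate_predictions
from .features import ScaleSet, compute_features

__all__ = [
    "RFParams",
    "TrainedClassifier",
    "SpatialFoldPlan",
    "FoldGeometry",
    "undersample_majority",
    "make_spatial_folds",
    "grid_search",
    "train",
    "predict",
    "LianaForestModel",
    "LianaForestResults",
    "DEFAULT_TREE_GRID",
    "DEFAULT_FEATURE_GRID",
]

#: Hyperparameter grids explored for the ensemble: 10, 20, ... 100 trees
#: by 2..8 random features per split.
DEFAULT_TREE_GRID = tuple(range(10, 101, 10))
DEFAULT_FEATURE_GRID = tuple(range(2, 9))


@dataclass(frozen=True)
class RFParams:
    """Random-forest hyperparameters.

    ``n_features_per_split="all"`` lets every split see all 15 features,
    the final-model default; an integer restricts the candidate features
    per split as in the grid search.
    """

    n_trees: int = 50
    n_features_per_split: int | str = "all"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValidationError("n_trees must be positive")
        if self.n_features_per_split != "all" and (
            not isinstance(self.n_features_per_split, (int, np.integer))
            or self.n_features_per_split < 1
        ):
            raise ValidationError('n_features_per_split must be a positive int or "all"')

    @property
    def max_features(self):
        return None if self.n_features_per_split == "all" else int(self.n_features_per_split)


@dataclass
class TrainedClassifier:
    """Fitted ensemble together with the feature schema it expects."""

    params: RFParams
    estimator: RandomForestClassifier
    feature_schema: ScaleSet

    def save(self, path) -> None:
        """Persist schema + ensemble to a single archive file."""
        joblib.dump(
            {"params": self.params, "estimator": self.estimator,
             "feature_schema": self.feature_schema},
            path,
        )

    @classmethod
    def load(cls, path) -> "TrainedClassifier":
        payload = joblib.load(path)
        return cls(
            params=payload["params"],
            estimator=payload["estimator"],
            feature_schema=payload["feature_schema"],
        )


def undersample_majority(labels, fraction: float, seed: int) -> np.ndarray:
    """Retain all minority-class points and a random fraction of the majority.

    Returns sorted indices into ``labels``. The retained majority count is
    ``round(fraction * majority_count)``; sampling is uniform without
    replacement and deterministic given ``seed``.
    """
    lab = np.asarray(labels)
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must lie in (0, 1]")
    classes = np.unique(lab)
    if len(classes) < 2:
        raise ValidationError("under-sampling needs both classes present")
    n1 = int(np.sum(lab == LIANA))
    n2 = int(np.sum(lab == OTHER))
    majority = OTHER if n2 >= n1 else LIANA
    major_idx = np.flatnonzero(lab == majority)
    minor_idx = np.flatnonzero(lab != majority)
    n_keep = int(np.floor(fraction * len(major_idx) + 0.5))
    rng = np.random.default_rng(seed)
    kept_major = rng.choice(major_idx, size=n_keep, replace=False)
    return np.sort(np.concatenate([minor_idx, kept_major]))


# ---------------------------------------------------------------------------
# Spatial cross-validation fold plans


@dataclass
class FoldGeometry:
    """How plots are carved into spatially disjoint validation areas.

    ``split=(nx, ny)`` partitions each plot's xy extent into an nx-by-ny
    grid of rectangles (e.g. ``(2, 2)`` turns a 15x15 m plot into four
    7.5x7.5 m quadrants). ``sites`` assigns each cloud to a site for the
    cross-site and mixed-site schemes; in the mixed scheme only plots of
    ``split_site`` are subdivided, the other site's plots are validated
    whole. ``min_cell_extent`` is the smallest admissible sub-area edge.
    """

    split: tuple[int, int] | None = None
    sites: list[str] | None = None
    split_site: str | None = None
    min_cell_extent: float = 1.0


@dataclass
class SpatialFoldPlan:
    """Folds over the concatenation of the input clouds.

    ``folds`` holds (train, validation) global index arrays into the
    concatenated point set; ``offsets[i]`` is where cloud *i* starts.
    """

    scheme: str
    folds: list[tuple[np.ndarray, np.ndarray]]
    offsets: np.ndarray
    geometry: str

    def __len__(self) -> int:
        return len(self.folds)


def _subarea_masks(cloud: PointCloud, split: tuple[int, int], min_cell: float):
    """Boolean masks of the nx-by-ny rectangular partition of the xy extent."""
    lo, hi = cloud.bounds()
    nx, ny = split
    wx = (hi[0] - lo[0]) / nx
    wy = (hi[1] - lo[1]) / ny
    if wx < min_cell or wy < min_cell:
        raise ValidationError(
            f"plot extent {hi[0] - lo[0]:.2f} x {hi[1] - lo[1]:.2f} m too small for a "
            f"{nx}x{ny} split; each sub-area needs at least {min_cell:.2f} m per side "
            f"(minimum extent {nx * min_cell:.2f} x {ny * min_cell:.2f} m)"
        )
    ix = np.minimum(((cloud.coords[:, 0] - lo[0]) / wx).astype(int), nx - 1)
    iy = np.minimum(((cloud.coords[:, 1] - lo[1]) / wy).astype(int), ny - 1)
    cell = ix * ny + iy
    return [cell == c for c in range(nx * ny)]


def make_spatial_folds(
    clouds: list[PointCloud],
    scheme: str,
    geometry: FoldGeometry | None = None,
) -> SpatialFoldPlan:
    """Build the fold plan for one of the three spatial CV schemes.

    self_site
        With ``geometry.split`` set: every sub-area of every plot is
        validated once against all remaining sub-areas (two 15x15 m plots
        with a 2x2 split give the eightfold plan). Without a split:
        leave-one-plot-out.
    cross_site
        Two folds: train on all plots of one site, validate on the other.
    mixed_site
        Plots of ``geometry.split_site`` are subdivided (default 2x3);
        fold j validates sub-area j of each subdivided plot together with
        plot j of the other site.
    """
    if not clouds:
        raise ValidationError("need at least one cloud")
    geometry = geometry or FoldGeometry()
    sizes = np.array([len(c) for c in clouds])
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    total = int(sizes.sum())
    all_idx = np.arange(total)

    def globalize(cloud_i: int, mask: np.ndarray) -> np.ndarray:
        return offsets[cloud_i] + np.flatnonzero(mask)

    folds: list[tuple[np.ndarray, np.ndarray]] = []
    if scheme == "self_site":
        if geometry.split is not None:
            val_sets = [
                globalize(i, mask)
                for i, cloud in enumerate(clouds)
                for mask in _subarea_masks(cloud, geometry.split, geometry.min_cell_extent)
            ]
            desc = (
                f"{len(clouds)} plot(s) x {geometry.split[0]}x{geometry.split[1]} "
                "sub-areas, one sub-area validated per fold"
            )
        else:
            val_sets = [offsets[i] + np.arange(sizes[i]) for i in range(len(clouds))]
            desc = f"leave-one-plot-out over {len(clouds)} plots"
        for val in val_sets:
            train = np.setdiff1d(all_idx, val, assume_unique=True)
            folds.append((train, val))
    elif scheme == "cross_site":
        sites = geometry.sites
        if sites is None or len(sites) != len(clouds):
            raise ValidationError("cross_site needs geometry.sites, one per cloud")
        uniq = sorted(set(sites))
        if len(uniq) != 2:
            raise ValidationError(f"cross_site needs exactly 2 sites, got {uniq}")
        groups = {
            s: np.concatenate([offsets[i] + np.arange(sizes[i])
                               for i in range(len(clouds)) if sites[i] == s])
            for s in uniq
        }
        folds = [(groups[uniq[0]], groups[uniq[1]]),
                 (groups[uniq[1]], groups[uniq[0]])]
        desc = f"train {uniq[0]} -> validate {uniq[1]} and vice versa"
    elif scheme == "mixed_site":
        sites = geometry.sites
        if sites is None or len(sites) != len(clouds):
            raise ValidationError("mixed_site needs geometry.sites, one per cloud")
        split = geometry.split or (2, 3)
        split_site = geometry.split_site or sorted(set(sites))[0]
        a_plots = [i for i, s in enumerate(sites) if s == split_site]
        b_plots = [i for i, s in enumerate(sites) if s != split_site]
        if not a_plots or not b_plots:
            raise ValidationError("mixed_site needs plots on both sites")
        k = split[0] * split[1]
        if len(b_plots) != k:
            raise ValidationError(
                f"mixed_site pairs each of the {k} sub-areas with one whole plot of "
                f"the other site; got {len(b_plots)} such plots"
            )
        a_masks = {
            i: _subarea_masks(clouds[i], split, geometry.min_cell_extent)
            for i in a_plots
        }
        for j in range(k):
            val_parts = [globalize(i, a_masks[i][j]) for i in a_plots]
            val_parts.append(offsets[b_plots[j]] + np.arange(sizes[b_plots[j]]))
            val = np.concatenate(val_parts)
            folds.append((np.setdiff1d(all_idx, val, assume_unique=True), val))
        desc = (
            f"{len(a_plots)} plot(s) of site {split_site!r} split "
            f"{split[0]}x{split[1]}; fold j = sub-area j + whole plot j of the other site"
        )
    else:
        raise ValidationError(
            f"unknown scheme {scheme!r}; expected self_site, cross_site or mixed_site"
        )
    return SpatialFoldPlan(scheme=scheme, folds=folds, offsets=offsets, geometry=desc)


# ---------------------------------------------------------------------------
# Training / prediction


def _check_schema(features: np.ndarray, schema: ScaleSet) -> None:
    if features.ndim != 2 or features.shape[1] != schema.n_features:
        raise ValidationError(
            f"feature matrix has {features.shape[1] if features.ndim == 2 else '?'} "
            f"columns but the model was trained on scales {schema.radii} "
            f"({schema.n_features} features)"
        )


def train(
    features: np.ndarray,
    labels,
    params: RFParams = RFParams(),
    scales: ScaleSet = ScaleSet(),
) -> TrainedClassifier:
    """Fit the random forest on feature rows with {1,2} labels."""
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    _check_schema(X, scales)
    if len(np.unique(y)) < 2:
        raise ValidationError("training needs both classes present")
    estimator = RandomForestClassifier(
        n_estimators=params.n_trees,
        max_features=params.max_features,
        random_state=params.seed,
        n_jobs=1,
    )
    estimator.fit(X, y)
    return TrainedClassifier(params=params, estimator=estimator, feature_schema=scales)


def _vote_probability(estimator: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Class-1 probability as the fraction of trees voting class 1."""
    # sub-estimators predict indices into classes_, not the original labels
    liana_index = int(np.flatnonzero(estimator.classes_ == LIANA)[0])
    votes = np.zeros(len(X))
    for tree in estimator.estimators_:
        votes += tree.predict(X).astype(int) == liana_index
    return votes / len(estimator.estimators_)


def predict(
    model: TrainedClassifier, features: np.ndarray, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Hard labels and class-1 probabilities for feature rows.

    A point is labelled 1 (liana wood) when its probability is >= the
    threshold.
    """
    if not 0 < threshold < 1:
        raise ValidationError("threshold must lie strictly between 0 and 1")
    X = np.asarray(features, dtype=np.float64)
    _check_schema(X, model.feature_schema)
    probs = _vote_probability(model.estimator, X)
    labels = np.where(probs >= threshold, LIANA, OTHER)
    return labels, probs


def _run_fold(
    X: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    params: RFParams,
    scales: ScaleSet,
    undersample_fraction: float,
    threshold: float,
) -> EvaluationReport:
    sub = undersample_majority(y[train_idx], undersample_fraction, params.seed)
    rows = train_idx[sub]
    model = train(X[rows], y[rows], params, scales)
    pred, probs = predict(model, X[val_idx], threshold)
    return evaluate_predictions(pred, y[val_idx], probs)


def grid_search(
    features: np.ndarray,
    labels,
    folds: SpatialFoldPlan,
    tree_grid=DEFAULT_TREE_GRID,
    feature_grid=DEFAULT_FEATURE_GRID,
    scales: ScaleSet = ScaleSet(),
    undersample_fraction: float = 0.1,
    threshold: float = 0.5,
    seed: int = 0,
) -> tuple[RFParams, pd.DataFrame]:
    """Exhaustive grid search scored by mean F1 across the fold plan.

    Returns the winning :class:`RFParams` (ties broken toward fewer trees,
    then fewer features per split) and the full score table (rows = tree
    counts, columns = features per split).
    """
    if not len(tree_grid) or not len(feature_grid):
        raise ValidationError("grids must be non-empty")
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    table = pd.DataFrame(
        index=pd.Index(list(tree_grid), name="n_trees"),
        columns=pd.Index(list(feature_grid), name="n_features_per_split"),
        dtype=float,
    )
    best: tuple[float, int, int] | None = None
    for n_trees in sorted(tree_grid):
        for n_feat in sorted(feature_grid):
            params = RFParams(n_trees=n_trees, n_features_per_split=int(n_feat), seed=seed)
            scores = [
                _run_fold(X, y, tr, va, params, scales, undersample_fraction, threshold).f1
                for tr, va in folds.folds
            ]
            mean_f1 = float(np.mean(scores))
            table.loc[n_trees, n_feat] = mean_f1
            if best is None or mean_f1 > best[0]:
                best = (mean_f1, n_trees, n_feat)
    assert best is not None
    winner = RFParams(n_trees=best[1], n_features_per_split=best[2], seed=seed)
    return winner, table


# ---------------------------------------------------------------------------
# Model / Results front end


class LianaForestModel:
    """Liana woody-point classifier on multi-scale eigenvalue features.

    Parameters
    ----------
    features : (N, 3*len(scales)) array
        Normalized eigenvalue features per point.
    labels : (N,) array of {1, 2}
        Ground-truth classes (1 = liana wood).
    scales : ScaleSet
        Radii the features were computed at.
    params : RFParams
        Ensemble hyperparameters.
    undersample_fraction : float
        Fraction of the majority class retained for training (default 0.1;
        all minority points are always kept). Set to 1.0 to disable.
    drop_invalid : bool
        Drop rows whose feature neighborhoods were degenerate instead of
        training on their neutral fallback triples (default keeps them:
        they are still real returns).
    """

    def __init__(
        self,
        features,
        labels,
        scales: ScaleSet = ScaleSet(),
        params: RFParams = RFParams(),
        undersample_fraction: float = 0.1,
        valid_mask=None,
        drop_invalid: bool = False,
        plot_sizes: list[int] | None = None,
    ) -> None:
        X = np.asarray(features, dtype=np.float64)
        y = np.asarray(labels)
        _check_schema(X, scales)
        if y.shape != (len(X),):
            raise ValidationError("labels must align with feature rows")
        if drop_invalid and valid_mask is not None:
            keep = np.asarray(valid_mask, dtype=bool)
            X, y = X[keep], y[keep]
            plot_sizes = None  # row/plot correspondence is lost
        self.features = X
        self.labels = y
        self.scales = scales
        self.params = params
        self.undersample_fraction = undersample_fraction
        self.plot_sizes = plot_sizes

    @classmethod
    def from_clouds(
        cls,
        clouds: list[PointCloud],
        scales: ScaleSet = ScaleSet(),
        params: RFParams = RFParams(),
        undersample_fraction: float = 0.1,
        voxel_size: float | None = 0.04,
        chunk_size: int = 2048,
        drop_invalid: bool = False,
    ) -> "LianaForestModel":
        """Build the design matrix from labeled clouds (downsample + features)."""
        from .preprocess import voxel_downsample

        prepared = []
        for cloud in clouds:
            if cloud.labels is None:
                raise ValidationError(
                    f"cloud {cloud.source_id!r} has no labels; training needs labeled data"
                )
            prepared.append(
                voxel_downsample(cloud, voxel_size) if voxel_size else cloud
            )
        mats = [compute_features(c, scales, chunk_size) for c in prepared]
        X = np.vstack([m.values for m in mats])
        mask = np.concatenate([m.valid_mask for m in mats])
        y = np.concatenate([c.labels for c in prepared])
        return cls(
            X, y, scales=scales, params=params,
            undersample_fraction=undersample_fraction, valid_mask=mask,
            drop_invalid=drop_invalid, plot_sizes=[len(c) for c in prepared],
        )

    def fit(self) -> "LianaForestResults":
        """Under-sample the majority class and fit the ensemble."""
        keep = undersample_majority(
            self.labels, self.undersample_fraction, self.params.seed
        ) if self.undersample_fraction < 1.0 else np.arange(len(self.labels))
        classifier = train(
            self.features[keep], self.labels[keep], self.params, self.scales
        )
        return LianaForestResults(self, classifier, keep)


class LianaForestResults:
    """Fitted liana classifier: predictions, diagnostics and summary."""

    def __init__(
        self,
        model: LianaForestModel,
        classifier: TrainedClassifier,
        training_rows: np.ndarray,
    ) -> None:
        self.model = model
        self.classifier = classifier
        self.training_rows = training_rows

    @property
    def feature_importances(self) -> pd.DataFrame:
        """Mean impurity-based importance per feature, with sd across trees."""
        est = self.classifier.estimator
        per_tree = np.array([t.feature_importances_ for t in est.estimators_])
        return pd.DataFrame(
            {
                "importance": per_tree.mean(axis=0),
                "sd": per_tree.std(axis=0, ddof=1) if len(per_tree) > 1 else 0.0,
            },
            index=self.model.scales.column_names(),
        )

    def predict(self, features, threshold: float = 0.5):
        """Hard labels and class-1 probabilities for new feature rows."""
        return predict(self.classifier, features, threshold)

    def evaluate(self, features, true_labels, threshold: float = 0.5) -> EvaluationReport:
        pred, probs = self.predict(features, threshold)
        return evaluate_predictions(pred, true_labels, probs)

    def cross_validate(
        self, plan: SpatialFoldPlan, threshold: float = 0.5
    ) -> tuple[list[EvaluationReport], dict]:
        """Refit per fold of a spatial plan; per-fold reports + aggregate.

        The majority under-sample is re-drawn from each fold's training
        indices.
        """
        reports = [
            _run_fold(
                self.model.features, self.model.labels, tr, va,
                self.model.params, self.model.scales,
                self.model.undersample_fraction, threshold,
            )
            for tr, va in plan.folds
        ]
        return reports, aggregate_reports(reports)

    def summary(self) -> str:
        """Plain-text summary of the fit."""
        m = self.model
        in_sample = self.evaluate(
            m.features[self.training_rows], m.labels[self.training_rows]
        )
        lines = [
            "Liana woody-point random forest",
            "=" * 46,
            f"points (total / trained on): {len(m.labels)} / {len(self.training_rows)}",
            f"class-1 (liana) fraction:    {np.mean(m.labels == LIANA):.3f}",
            f"trees: {m.params.n_trees}   features/split: {m.params.n_features_per_split}"
            f"   seed: {m.params.seed}",
            f"scales (m): {', '.join(f'{r:g}' for r in m.scales.radii)}",
            f"majority under-sample fraction: {m.undersample_fraction:g}",
            "",
            "In-sample (training rows):",
            f"  precision {in_sample.precision:.3f}  recall {in_sample.recall:.3f}"
            f"  F1 {in_sample.f1:.3f}  FPR {in_sample.fpr:.4f}",
            "",
            "Feature importances (mean +/- sd across trees):",
        ]
        imp = self.feature_importances
        for name, row in imp.iterrows():
            lines.append(f"  {name:<10} {row['importance']:.4f} +/- {row['sd']:.4f}")
        return "\n".join(lines)
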