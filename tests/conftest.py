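import numpy as np
import pytest

import lianasep as ls
from lianasep.preprocess import voxel_downsample


@pytest.fixture
def rng():
    return np.random.default_rng(0xC0FFEE)


@pytest.fixture(scope="session")
def default_scene():
    """One default-configuration synthetic plot."""
    return ls.generate_scene(ls.SceneConfig(seed=11))


@pytest.fixture(scope="session")
def spline_scene():
    """A plot whose lianas follow looping splines instead of helices."""
    return ls.generate_scene(
        ls.SceneConfig(seed=17, liana_path="looping_spline", ghost_point_count=60)
    )


@pytest.fixture(scope="session")
def five_scene_cv():
    """Five seeded default scenes with leave-one-plot-out spatial CV.

    Shared session-wide because feature extraction dominates the cost.
    """
    scenes = [ls.generate_scene(ls.SceneConfig(seed=s)) for s in range(5)]
    clouds = [s.cloud for s in scenes]
    model = ls.LianaForestModel.from_clouds(clouds)
    plan = ls.make_spatial_folds(
        [voxel_downsample(c, 0.04) for c in clouds], "self_site"
    )
    results = model.fit()
    reports, aggregate = results.cross_validate(plan)
    return {
        "scenes": scenes,
        "model": model,
        "results": results,
        "plan": plan,
        "reports": reports,
        "aggregate": aggregate,
    }


@pytest.fixture
def separable_features(rng):
    """A small, cleanly separable 15-feature binary problem."""
    n = 200
    scales = ls.ScaleSet()
    lin = np.tile([0.95, 0.04, 0.01], (n // 2, len(scales)))
    iso = np.tile([0.4, 0.35, 0.25], (n // 2, len(scales)))
    X = np.vstack([lin, iso]) + rng.normal(0, 0.01, size=(n, scales.n_features))
    y = np.array([1] * (n // 2) + [2] * (n // 2))
    perm = rng.permutation(n)
    return X[perm], y[perm], scales
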