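import numpy as np
import pytest

from lianasep import (
    DBSCANParams,
    PointCloud,
    SORParams,
    ValidationError,
    apply_mask,
    dbscan,
    recover_false_negatives,
    run_postprocess,
)
from lianasep.postprocess import load_mask, mask_indices
from _oracles import brute_dbscan, canonical_clustering


def blob(center, n, rng, sigma=0.01):
    return np.asarray(center) + rng.normal(0, sigma, size=(n, 3))


class TestDBSCAN:
    def test_two_separated_blobs(self, rng):
        coords = np.vstack([blob([0, 0, 0], 20, rng), blob([1, 0, 0], 20, rng)])
        result = dbscan(PointCloud(coords), DBSCANParams(eps=0.05, min_pts=5))
        assert result.n_clusters == 2
        assert (result.cluster_id[:20] == result.cluster_id[0]).all()
        assert result.cluster_id[0] != result.cluster_id[20]

    def test_chain_spacing_edge_case(self):
        # 10-point chain at 0.04 m spacing: each point sees only 3 points
        # (self + 2) within eps=0.05, below min_pts=5, so everything is noise
        coords = np.column_stack([np.arange(10) * 0.04, np.zeros(10), np.zeros(10)])
        result = dbscan(PointCloud(coords), DBSCANParams(eps=0.05, min_pts=5))
        oracle = brute_dbscan(coords, 0.05, 5)
        assert (result.cluster_id == -1).all()
        assert np.array_equal(result.cluster_id, oracle)

    def test_chain_with_min_pts_three_is_one_cluster(self):
        coords = np.column_stack([np.arange(10) * 0.04, np.zeros(10), np.zeros(10)])
        result = dbscan(PointCloud(coords), DBSCANParams(eps=0.05, min_pts=3))
        assert result.n_clusters == 1
        assert (result.cluster_id == 0).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_reachability_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # mixture of tight blobs and sparse background to exercise borders
        coords = np.vstack(
            [blob(rng.uniform(0, 0.5, 3), 30, rng, sigma=0.015) for _ in range(4)]
            + [rng.uniform(0, 0.5, size=(80, 3))]
        )
        params = DBSCANParams(eps=0.05, min_pts=5)
        mine = canonical_clustering(dbscan(PointCloud(coords), params).cluster_id)
        oracle = canonical_clustering(brute_dbscan(coords, 0.05, 5))
        assert np.array_equal(mine, oracle)


class TestMask:
    def test_empty_mask_is_identity(self, rng):
        cloud = PointCloud(rng.uniform(0, 1, (10, 3)))
        assert apply_mask(cloud, None).equals(cloud)
        assert apply_mask(cloud, []).equals(cloud)

    def test_box_covering_everything_empties_cloud(self, rng):
        cloud = PointCloud(rng.uniform(0, 1, (10, 3)))
        box = [{"min": [-1, -1, -1], "max": [2, 2, 2]}]
        assert len(apply_mask(cloud, box)) == 0

    def test_box_covering_three_of_ten(self):
        coords = np.column_stack([np.arange(10) / 10, np.zeros(10), np.zeros(10)])
        box = [{"min": [0.0, -1, -1], "max": [0.25, 1, 1]}]
        assert len(apply_mask(PointCloud(coords), box)) == 7

    def test_out_of_range_index_rejected(self, rng):
        cloud = PointCloud(rng.uniform(0, 1, (5, 3)))
        with pytest.raises(ValidationError):
            mask_indices(cloud, [7])

    def test_load_mask_both_dialects(self, tmp_path):
        idx_file = tmp_path / "mask.txt"
        idx_file.write_text("3\n5\n")
        assert list(load_mask(idx_file)) == [3, 5]
        box_file = tmp_path / "mask.json"
        box_file.write_text('[{"min": [0,0,0], "max": [1,1,1]}]')
        boxes = load_mask(box_file)
        assert boxes[0]["max"] == [1, 1, 1]


def tube(start, direction, length, rng, spacing=0.01, radius=0.01):
    t = np.arange(0, length, spacing)
    direction = np.asarray(direction) / np.linalg.norm(direction)
    line = np.asarray(start) + t[:, None] * direction
    return line + rng.normal(0, radius / 2, size=(len(t), 3))


class TestRecoverFalseNegatives:
    def test_distant_cluster_not_recovered(self, rng):
        liana = PointCloud(tube([0, 0, 0], [0, 0, 1], 1.0, rng))
        far = PointCloud(blob([5, 5, 1], 30, rng))
        recovered = recover_false_negatives(far, liana, DBSCANParams())
        assert recovered.size == 0

    def test_touching_cluster_recovered(self, rng):
        liana = PointCloud(tube([0, 0, 0], [0, 0, 1], 1.0, rng))
        # segment continuing the tube, 0.04 m past its last ring (z = 0.99)
        segment = PointCloud(tube([0, 0, 1.03], [0, 0, 1], 0.5, rng))
        recovered = recover_false_negatives(segment, liana, DBSCANParams())
        assert len(recovered) == len(segment)

    def test_noise_points_never_recovered(self, rng):
        liana = PointCloud(tube([0, 0, 0], [0, 0, 1], 1.0, rng))
        # single isolated point right next to the liana: noise for DBSCAN
        lone = PointCloud(np.array([[0.0, 0.02, 0.5]]))
        assert recover_false_negatives(lone, liana, DBSCANParams()).size == 0

    def test_midsection_recovered_detached_blob_untouched(self, rng):
        # a liana whose middle third was mislabelled class 2, plus a leaf
        # blob far away: only the contiguous mid-section comes back
        full = tube([0, 0, 0], [0, 0, 1], 3.0, rng)
        mid = (full[:, 2] > 1.0) & (full[:, 2] < 2.0)
        class2 = PointCloud(np.vstack([full[mid], blob([2, 2, 2], 40, rng)]))
        liana = PointCloud(full[~mid])
        recovered = recover_false_negatives(class2, liana, DBSCANParams())
        n_mid = int(mid.sum())
        # the contiguous mid-section comes back (ends may drop off the
        # cluster when jitter stretches the chain), the blob never does
        assert recovered.size >= 0.9 * n_mid
        assert recovered.max() < n_mid
        # brute-force check that the recovered cluster really touches the liana
        gap = np.min(
            np.linalg.norm(class2.coords[:n_mid, None, :] - liana.coords[None], axis=2)
        )
        assert gap <= 0.05

    def test_empty_inputs_rejected(self, rng):
        cloud = PointCloud(rng.uniform(0, 1, (10, 3)))
        with pytest.raises(ValidationError):
            recover_false_negatives(cloud, PointCloud(np.empty((0, 3))))


class TestRunPostprocess:
    def test_clean_predictions_are_fixed_point(self, rng):
        # closed liana loops (no chain ends, so no SOR end-effects) plus a
        # distant class-2 blob: nothing to remove, mask, or recover
        def circle(radius, spacing, z):
            n = int(round(2 * np.pi * radius / spacing))
            theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
            return np.column_stack(
                [radius * np.cos(theta), radius * np.sin(theta), np.full(n, z)]
            )

        liana = np.vstack([circle(1.0, 0.02, 0.5), circle(1.5, 0.024, 2.0)])
        far = blob([6, 6, 1], 50, rng)
        coords = np.vstack([liana, far])
        labels = np.array([1] * len(liana) + [2] * len(far))
        cloud = PointCloud(coords)
        corrected, log = run_postprocess(cloud, labels)
        assert np.array_equal(corrected, labels)
        assert log["step1_sor"]["relabelled"] == 0
        assert log["step34_recovered"]["relabelled"] == 0
        # and re-running on its own output stays a no-op
        corrected2, log2 = run_postprocess(cloud, corrected)
        assert np.array_equal(corrected2, corrected)

    def test_ghost_dropped_and_segment_recovered(self, rng):
        # fixture built to trigger exactly one change in step 1 and steps 3-4
        base = tube([0, 0, 0.5], [0, 0, 1], 2.0, rng)
        detached = tube([0, 0, 2.53], [0, 0, 1], 0.6, rng)  # 0.04 m past z=2.49
        ghost = np.array([[3.0, 3.0, 3.0]])
        far_leaf = blob([2, 2, 1], 40, rng)
        coords = np.vstack([base, detached, ghost, far_leaf])
        pred = np.concatenate([
            np.full(len(base), 1),       # correctly predicted liana
            np.full(len(detached), 2),   # missed contiguous segment
            np.full(1, 1),               # ghost false positive
            np.full(len(far_leaf), 2),   # true class 2, detached
        ])
        cloud = PointCloud(coords)
        corrected, log = run_postprocess(cloud, pred)
        ghost_idx = len(base) + len(detached)
        assert log["step1_sor"]["relabelled"] >= 1
        assert ghost_idx in log["step1_sor"]["indices"]
        assert corrected[ghost_idx] == 2
        seg = slice(len(base), len(base) + len(detached))
        assert (corrected[seg] == 1).all()
        assert (corrected[ghost_idx + 1 :] == 2).all()

    def test_mask_relabels_class1_points(self, rng):
        coords = np.vstack([blob([0, 0, 0], 30, rng), blob([1, 0, 0], 30, rng)])
        pred = np.full(60, 1)
        box = [{"min": [0.8, -1, -1], "max": [1.2, 1, 1]}]
        corrected, log = run_postprocess(
            PointCloud(coords), pred, mask=box,
            sor=SORParams(n_points=6, n_sigma=1e9),
            db=DBSCANParams(eps=0.01, min_pts=5),
        )
        assert log["step2_mask"]["relabelled"] == 30
        assert (corrected[30:] == 2).all() and (corrected[:30] == 1).all()

    def test_recovery_never_lowers_recall(self, rng, default_scene):
        import lianasep as ls

        labels = ls.perturb_labels(default_scene, fn_segment_fraction=0.3, seed=3)
        before = ls.evaluate_predictions(labels, default_scene.cloud.labels)
        corrected, _ = run_postprocess(default_scene.cloud, labels)
        after = ls.evaluate_predictions(corrected, default_scene.cloud.labels)
        assert after.recall >= before.recall
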