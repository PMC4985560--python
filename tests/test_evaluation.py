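import numpy as np
import pytest

import braincode as bc
from conftest import random_condensed, singleton_clustering


class TestOverlap:
    def test_identical_labelings_recover_everything(self):
        truth = np.array([1, 1, 2, 2, 3])
        rep = bc.overlap(truth, truth)
        assert np.allclose(np.diag(rep.dice.loc[[1, 2, 3], [1, 2, 3]]), 1.0)
        assert rep.recovered == 3

    def test_half_shared(self):
        labels = np.array([0] * 10 + [1] * 10)
        truth = np.array([1] * 5 + [2] * 5 + [1] * 5 + [2] * 5)
        rep = bc.overlap(labels, truth)
        assert rep.dice.loc[0, 1] == pytest.approx(2 * 5 / (10 + 10))

    def test_structure_split_across_two_clusters(self):
        # structure of 10 voxels split evenly over two clusters of size 5
        labels = np.array([0] * 5 + [1] * 5)
        truth = np.ones(10, dtype=int)
        rep = bc.overlap(labels, truth)
        assert rep.dice.loc[0, 1] == pytest.approx(2 / 3)
        assert rep.dice.loc[1, 1] == pytest.approx(2 / 3)

    def test_recovered_monotone_in_tau(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 5, 200)
        truth = rng.integers(1, 5, 200)
        rec = [bc.overlap(labels, truth, tau=t).recovered for t in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert rec == sorted(rec, reverse=True)

    def test_disjoint_domains_rejected(self):
        with pytest.raises(bc.ConsistencyError):
            bc.overlap(np.zeros(3), np.ones(4))


class TestAdjustedRand:
    def test_hand_examples(self):
        a = np.array([0, 0, 1, 1])
        assert bc.adjusted_rand(a, a) == pytest.approx(1.0)
        assert bc.adjusted_rand(a, np.array([0, 1, 0, 1])) == pytest.approx(-0.5)
        assert bc.adjusted_rand(a, np.zeros(4)) == pytest.approx(0.0)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(8)
        a = rng.integers(0, 4, 50)
        b = rng.integers(0, 4, 50)
        perm = np.array([2, 3, 0, 1])
        assert bc.adjusted_rand(a, b) == pytest.approx(bc.adjusted_rand(perm[a], b))

    def test_length_mismatch(self):
        with pytest.raises(bc.ConsistencyError):
            bc.adjusted_rand(np.zeros(3), np.zeros(4))


def mirrored_pair_scene():
    """Two 10-voxel mirror-symmetric clusters on a 6x5x2 grid, then one
    voxel of cluster 0 relabeled into cluster 1."""
    shape = (6, 5, 2)
    coords = []
    labels = []
    for y in range(5):  # cluster 0: x in {0,5}; cluster 1: x in {1,4}
        for x, cl in ((0, 0), (5, 0), (1, 1), (4, 1)):
            coords.append([x, y, 0])
            labels.append(cl)
    vox = bc.VoxelTable(np.array(coords))
    labels = np.array(labels)[np.lexsort((np.array(coords)[:, 0],
                                          np.array(coords)[:, 1],
                                          np.array(coords)[:, 2]))]
    return shape, vox, labels


def brute_force_symmetry(labels, vox, shape):
    scores = {}
    coords = {tuple(c): i for i, c in enumerate(vox.coords.tolist())}
    for cl in np.unique(labels):
        num = den = 0
        for i in np.flatnonzero(labels == cl):
            x, y, z = vox.coords[i]
            j = coords.get((shape[0] - 1 - x, y, z))
            if j is None:
                continue
            den += 1
            num += labels[j] == cl
        scores[int(cl)] = num / den if den else None
    return scores


class TestSymmetryScore:
    def test_perfect_mirror_scores_one(self):
        shape, vox, labels = mirrored_pair_scene()
        assert all(v == 1.0 for v in bc.symmetry_score(labels, vox, shape).values())

    def test_one_sided_cluster_scores_zero(self):
        vox = bc.VoxelTable(np.array([[0, 0, 0], [3, 0, 0]]))
        labels = np.array([0, 1])
        scores = bc.symmetry_score(labels, vox, (4, 1, 1))
        assert scores == {0: 0.0, 1: 0.0}

    def test_single_relabeled_voxel_matches_brute_force(self):
        shape, vox, labels = mirrored_pair_scene()
        # move the voxel at (0, 0, 0) from cluster 0 into cluster 1
        i = int(np.flatnonzero((vox.coords == [0, 0, 0]).all(axis=1))[0])
        labels = labels.copy()
        labels[i] = 1
        expected = brute_force_symmetry(labels, vox, shape)
        scores = bc.symmetry_score(labels, vox, shape)
        assert scores == pytest.approx(expected)
        assert scores[0] == pytest.approx(8 / 9)    # donor: partner mirror mismatches
        assert scores[1] == pytest.approx(10 / 11)  # recipient gained one mismatch

    def test_mirror_outside_region_reported_absent(self):
        vox = bc.VoxelTable(np.array([[0, 0, 0]]))
        labels = np.array([0])
        scores = bc.symmetry_score(labels, vox, (4, 1, 1))
        assert scores == {0: None}


class TestCompactness:
    def test_solid_blob(self):
        vox = bc.VoxelTable(np.argwhere(np.ones((3, 3, 3), dtype=bool)))
        assert bc.compactness(np.zeros(27), vox, (3, 3, 3)) == {0: 1.0}

    def test_two_equal_blobs(self):
        grid = np.zeros((7, 2, 2), dtype=bool)
        grid[:2] = True
        grid[5:] = True
        vox = bc.VoxelTable(np.argwhere(grid))
        assert bc.compactness(np.zeros(len(vox)), vox, grid.shape) == {0: 0.5}

    def test_nine_plus_isolated(self):
        grid = np.zeros((9, 3, 1), dtype=bool)
        grid[:3, :3, 0] = True  # 9-voxel plate
        grid[8, 0, 0] = True    # isolated voxel
        vox = bc.VoxelTable(np.argwhere(grid))
        assert bc.compactness(np.zeros(10), vox, grid.shape) == {0: 0.9}


class TestRunConsistency:
    def test_identical_and_permuted(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 4, 60)
        s = bc.run_consistency(a, a)
        assert s.mean_dice == pytest.approx(1.0) and s.ari == pytest.approx(1.0)
        perm = np.array([3, 2, 1, 0])
        sp = bc.run_consistency(a, perm[a])
        assert sp.mean_dice == pytest.approx(1.0) and sp.ari == pytest.approx(1.0)

    def test_hand_example(self):
        s = bc.run_consistency(np.array([0, 0, 1, 1]), np.array([0, 0, 0, 1]))
        by_a = {ca: d for ca, _, d in s.matches}
        assert by_a[0] == pytest.approx(0.8)
        assert by_a[1] == pytest.approx(2 / 3)
        assert s.mean_dice == pytest.approx((0.8 + 2 / 3) / 2)

    def test_voxel_mismatch(self):
        with pytest.raises(bc.ConsistencyError):
            bc.run_consistency(np.zeros(3), np.zeros(4))


class TestSplitFidelity:
    def test_split_siblings_merge_first(self):
        # 3 singletons: 0 and 1 are halves of unit 1, 2 is unit 2
        d = bc.CondensedDistances(3, np.array([0.1, 0.8, 0.9]))
        tree = bc.agglomerate(singleton_clustering(3), d)
        n_split, n_rep = bc.split_fidelity(tree, np.array([1, 1, 2]))
        assert (n_split, n_rep) == (1, 1)

    def test_split_across_foreign_merge_not_repaired(self):
        # unit 1's halves (0, 2) are far apart; 1 belongs to unit 2
        d = bc.CondensedDistances(3, np.array([0.1, 0.9, 0.8]))
        tree = bc.agglomerate(singleton_clustering(3), d)
        n_split, n_rep = bc.split_fidelity(tree, np.array([1, 2, 1]))
        assert (n_split, n_rep) == (1, 0)
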