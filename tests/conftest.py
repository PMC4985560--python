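import numpy as np
import pytest

import braincode as bc


def matrix_from_sets(line_sets: list[set]) -> bc.ExpressionMatrix:
    """ExpressionMatrix with one voxel per entry of ``line_sets``; voxel i
    sits at coordinate (i, 0, 0)."""
    lines = sorted(set().union(*line_sets))
    occ = np.array([[l in s for s in line_sets] for l in lines], dtype=bool)
    coords = np.array([[i, 0, 0] for i in range(len(line_sets))])
    return bc.ExpressionMatrix(line_ids=lines, occupancy=occ, voxels=bc.VoxelTable(coords))


def singleton_clustering(n: int) -> bc.Clustering:
    """Each voxel its own singleton cluster (labels = medoids = identity)."""
    return bc.Clustering(
        labels=np.arange(n), medoids=np.arange(n), cost=0.0, k=n, seed=0, n_iter=0
    )


def random_condensed(n: int, rng: np.random.Generator) -> bc.CondensedDistances:
    vals = rng.random(n * (n - 1) // 2)
    return bc.CondensedDistances(n, vals)


@pytest.fixture
def triad_distances() -> bc.CondensedDistances:
    """6 voxels in two tight triads: within-triad d=0.1, cross-triad d=0.9."""
    D = np.full((6, 6), 0.9)
    for g in ((0, 1, 2), (3, 4, 5)):
        for i in g:
            for j in g:
                D[i, j] = 0.1
    np.fill_diagonal(D, 0.0)
    return bc.CondensedDistances.from_square(D)


@pytest.fixture(scope="session")
def tiny_zero_noise():
    """Small noise-free phantom plus its expression matrix (shared: read-only)."""
    spec = bc.PhantomSpec(
        shape=(12, 12, 12), K=3, L=40, p_incl=0.3, f_broad=0.0,
        p_fp=0.0, p_fn=0.0, intensity_sd=0.0, jitter_sd=0.0, seed=7,
    )
    ds = bc.generate(spec)
    m = bc.filter_voxels(bc.build_matrix(ds.volumes, ds.line_ids, ds.mask))
    return ds, m
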