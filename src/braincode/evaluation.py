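"""Quantitative validation of a parcellation.

Implements the four checks a credible co-expression parcellation should
pass: spatial compactness (clusters are connected bodies, not scattered
voxels), mirror symmetry (for a bilaterally symmetric region, a cluster's
voxels sit at mirror-symmetric positions), correspondence with known
structures (voxel-set Dice overlap against a labeled ground truth), and
consistency across repeated runs or independent line collections (greedy
cluster matching plus the adjusted Rand index).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.metrics import adjusted_rand_score

from .agglomeration import MergeTree
from .errors import ConsistencyError, ParameterError
from .volumes import VoxelTable

log = logging.getLogger("braincode")

DEFAULT_TAU = 0.5


@dataclass
class OverlapReport:
    """Cluster x structure Dice overlaps against a labeled ground truth."""

    dice: pd.DataFrame        # index: cluster labels, columns: structure labels
    best_match: pd.DataFrame  # per structure: best cluster + its Dice
    recovered: int            # structures with best Dice >= tau
    tau: float


@dataclass
class ConsistencySummary:
    """Greedy one-to-one cluster matching between two runs."""

    matches: list[tuple[int, int, float]]  # (cluster_a, cluster_b, dice)
    mean_dice: float
    ari: float


def labels_from_volume(grid: np.ndarray, voxels: VoxelTable) -> np.ndarray:
    """Per-voxel values of a label volume at the analysis voxels."""
    x, y, z = voxels.coords.T
    return np.asarray(grid)[x, y, z]


def _dice_table(a: np.ndarray, b: np.ndarray) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Pairwise voxel-set Dice between the groups of two labelings."""
    ua, ub = np.unique(a), np.unique(b)
    counts = (
        pd.crosstab(pd.Series(a, name="a"), pd.Series(b, name="b"))
        .reindex(index=ua, columns=ub, fill_value=0)
        .to_numpy(dtype=np.float64)
    )
    sa = counts.sum(axis=1)
    sb = counts.sum(axis=0)
    dice = 2.0 * counts / (sa[:, None] + sb[None, :])
    return pd.DataFrame(dice, index=ua, columns=ub), ua, ub


def overlap(labels: np.ndarray, truth: np.ndarray, tau: float = DEFAULT_TAU) -> OverlapReport:
    """Dice(cluster, structure) = 2|c n g| / (|c| + |g|) over the analysis
    voxels; truth value 0 marks background and defines no structure."""
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    if labels.shape != truth.shape:
        raise ConsistencyError(
            f"labels cover {labels.shape} voxels, truth covers {truth.shape}"
        )
    structures = np.unique(truth)
    structures = structures[structures > 0]
    if len(structures) == 0:
        raise ParameterError("ground truth has no labeled structure")
    dice, clusters, _ = _dice_table(labels, truth)
    dice = dice[structures]
    best_idx = dice.to_numpy().argmax(axis=0)  # ties -> lowest cluster id
    best = pd.DataFrame(
        {
            "structure": structures,
            "cluster": clusters[best_idx],
            "dice": dice.to_numpy().max(axis=0),
        }
    ).set_index("structure")
    recovered = int((best["dice"] >= tau).sum())
    return OverlapReport(dice=dice, best_match=best, recovered=recovered, tau=tau)


def adjusted_rand(a: np.ndarray, b: np.ndarray) -> float:
    """Chance-corrected partition agreement in (-1, 1]."""
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ConsistencyError(f"label lengths differ: {a.shape} vs {b.shape}")
    if len(a) < 2:
        raise ParameterError("need at least 2 elements")
    return float(adjusted_rand_score(a, b))


def symmetry_score(
    labels: np.ndarray,
    voxels: VoxelTable,
    shape: tuple[int, int, int],
    mirror=None,
) -> dict[int, float | None]:
    """Per-cluster fraction of voxels whose mirror image carries the same
    label.

    ``mirror`` maps an (n, 3) coordinate array to mirrored coordinates; the
    default reflects about the x midplane, x -> W-1-x. Mirrored coordinates
    outside the analysis voxel set are excluded from the denominator; a
    cluster whose voxels all mirror outside gets ``None``.
    """
    labels = np.asarray(labels)
    coords = voxels.coords
    if mirror is None:
        mirrored = coords.copy()
        mirrored[:, 0] = shape[0] - 1 - coords[:, 0]
    else:
        mirrored = np.asarray(mirror(coords), dtype=np.int64)
    inside = np.all((mirrored >= 0) & (mirrored < np.asarray(shape)), axis=1)
    idx = voxels.index_grid(shape)
    partner = np.full(len(coords), -1, dtype=np.int64)
    mi = mirrored[inside]
    partner[inside] = idx[mi[:, 0], mi[:, 1], mi[:, 2]]

    out: dict[int, float | None] = {}
    n_excluded = 0
    for cl in np.unique(labels):
        members = np.flatnonzero(labels == cl)
        p = partner[members]
        valid = p >= 0
        n_excluded += int((~valid).sum())
        if not valid.any():
            out[int(cl)] = None
            continue
        out[int(cl)] = float(np.mean(labels[p[valid]] == cl))
    if n_excluded:
        log.info("symmetry_score: %d voxels mirror outside the region", n_excluded)
    return out


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def compactness(
    labels: np.ndarray, voxels: VoxelTable, shape: tuple[int, int, int]
) -> dict[int, float]:
    """Per-cluster fraction of voxels in its largest 26-connected component."""
    labels = np.asarray(labels)
    x, y, z = voxels.coords.T
    out: dict[int, float] = {}
    for cl in np.unique(labels):
        members = labels == cl
        grid = np.zeros(shape, dtype=bool)
        grid[x[members], y[members], z[members]] = True
        comp, n_comp = ndimage.label(grid, structure=_CONN26)
        if n_comp <= 1:
            out[int(cl)] = 1.0
        else:
            sizes = np.bincount(comp.ravel())[1:]
            out[int(cl)] = float(sizes.max() / sizes.sum())
    return out


def run_consistency(a: np.ndarray, b: np.ndarray) -> ConsistencySummary:
    """Greedy one-to-one matching of clusters across two runs by descending
    voxel-set Dice, with the ARI of the two partitions."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ConsistencyError(f"label lengths differ: {a.shape} vs {b.shape}")
    dice, ua, ub = _dice_table(a, b)
    d = dice.to_numpy()
    pairs = sorted(
        ((float(d[i, j]), int(ua[i]), int(ub[j]))
         for i in range(len(ua)) for j in range(len(ub))),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches: list[tuple[int, int, float]] = []
    for score, ca, cb in pairs:
        if ca in used_a or cb in used_b:
            continue
        matches.append((ca, cb, score))
        used_a.add(ca)
        used_b.add(cb)
        if len(matches) == min(len(ua), len(ub)):
            break
    mean_dice = float(np.mean([s for _, _, s in matches]))
    return ConsistencySummary(matches=matches, mean_dice=mean_dice, ari=adjusted_rand(a, b))


# ---------------------------------------------------------------------------
# split / re-merge fidelity
# ---------------------------------------------------------------------------

def majority_units(labels: np.ndarray, truth: np.ndarray, k: int) -> np.ndarray:
    """Per-singleton dominant ground-truth unit (ties -> lowest unit id);
    -1 for clusters dominated by background."""
    out = np.full(k, -1, dtype=np.int64)
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    for j in range(k):
        vals = truth[labels == j]
        if len(vals) == 0:
            continue
        units, counts = np.unique(vals, return_counts=True)
        out[j] = int(units[int(np.argmax(counts))])
    return out


def split_fidelity(tree: MergeTree, leaf_units: np.ndarray) -> tuple[int, int]:
    """How often an oversplit unit is repaired by the first merges.

    ``leaf_units`` maps each singleton to its dominant true unit. For every
    unit split across exactly two singletons, the split is "repaired" when
    the node at which the two siblings first join contains no singleton of
    any other unit. Returns (number of split units, number repaired).
    """
    leaf_units = np.asarray(leaf_units)
    if len(leaf_units) != tree.k:
        raise ConsistencyError("leaf_units length must equal tree.k")
    n_split = 0
    n_repaired = 0
    for unit in np.unique(leaf_units[leaf_units > 0]):
        leaves = np.flatnonzero(leaf_units == unit)
        if len(leaves) != 2:
            continue
        n_split += 1
        nid, _ = tree.join_node(int(leaves[0]), int(leaves[1]))
        sub = tree.leaves_under(nid)
        if all(leaf_units[l] == unit for l in sub):
            n_repaired += 1
    return n_split, n_repaired
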