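"""Hierarchical agglomeration of singleton clusters (UPGMA).

The k clusters from k-medoids ("singletons", named C00..C(k-1)) are merged
successively: at each step the pair of active clusters with the smallest
mean cross-pair voxel Dice distance joins into a new cluster, numbered
onward from k (C60, C61, ... in a k=60 run). Average linkage guarantees
monotone merge heights on a semimetric and reproduces the
oversplit-then-merge behaviour that motivates the hierarchy: when a true
anatomical unit is split across two singletons, those siblings sit at a
much smaller linkage distance from each other than from any other unit and
are joined by the first merges.

Ties in the minimal linkage break on the lexicographically smallest
(id_a, id_b) pair; children are stored as (smaller id, larger id).
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .clustering import Clustering, CondensedDistances
from .errors import ConsistencyError, ParameterError

__all__ = [
    "MergeTree",
    "cluster_name",
    "linkage_distance",
    "agglomerate",
    "cut_tree",
    "cut_voxel_labels",
]


def cluster_name(i: int) -> str:
    """Cluster naming convention: C00..C(k-1) singletons, C(k).. merged."""
    return f"C{i:02d}"


@dataclass
class MergeTree:
    """Merge order of the k singletons; merges are (a, b, height, new_id)."""

    k: int
    merges: list[tuple[int, int, float, int]]

    def __post_init__(self) -> None:
        if len(self.merges) != self.k - 1:
            raise ParameterError(
                f"expected {self.k - 1} merges for k={self.k}, got {len(self.merges)}"
            )
        self.merges = [(int(a), int(b), float(h), int(nid)) for a, b, h, nid in self.merges]
        used = [c for a, b, _, _ in self.merges for c in (a, b)]
        if len(set(used)) != len(used):
            raise ParameterError("every cluster id may be merged away only once")
        heights = [h for _, _, h, _ in self.merges]
        if any(h2 < h1 - 1e-12 for h1, h2 in zip(heights, heights[1:])):
            raise ParameterError("merge heights must be non-decreasing")

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h, _ in self.merges])

    def leaves_under(self, node: int) -> set[int]:
        """Singleton ids in the subtree rooted at ``node``."""
        children = {nid: (a, b) for a, b, _, nid in self.merges}
        stack, leaves = [node], set()
        while stack:
            x = stack.pop()
            if x < self.k:
                leaves.add(x)
            else:
                stack.extend(children[x])
        return leaves

    def join_node(self, a: int, b: int) -> tuple[int, float]:
        """(id, height) of the first merged cluster containing both leaves."""
        for ca, cb, h, nid in self.merges:
            leaves = self.leaves_under(nid)
            if a in leaves and b in leaves:
                return nid, h
        raise ParameterError(f"leaves {a}, {b} never join")

    # -- serialization ------------------------------------------------------

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({"k": self.k, "merges": self.merges}))

    @classmethod
    def from_json(cls, path) -> "MergeTree":
        d = json.loads(Path(path).read_text())
        return cls(k=int(d["k"]), merges=[tuple(m) for m in d["merges"]])

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights (leaves at 0)."""
        height = {i: 0.0 for i in range(self.k)}
        text = {i: cluster_name(i) for i in range(self.k)}
        for a, b, h, nid in self.merges:
            height[nid] = h
            text[nid] = (
                f"({text[a]}:{h - height[a]:.10g},{text[b]}:{h - height[b]:.10g})"
                f"{cluster_name(nid)}"
            )
        root = self.merges[-1][3]
        return text[root] + ";"


# ---------------------------------------------------------------------------
# linkage
# ---------------------------------------------------------------------------

def linkage_distance(d: CondensedDistances, members_a, members_b) -> float:
    """Mean of all cross-pair voxel distances between two disjoint voxel sets."""
    a = np.asarray(sorted(set(int(i) for i in members_a)), dtype=np.int64)
    b = np.asarray(sorted(set(int(i) for i in members_b)), dtype=np.int64)
    if len(a) == 0 or len(b) == 0:
        raise ParameterError("member sets must be non-empty")
    if np.intersect1d(a, b).size:
        raise ParameterError("member sets must be disjoint")
    D = d.square()
    return float(D[np.ix_(a, b)].mean())


def agglomerate(c: Clustering, d: CondensedDistances) -> MergeTree:
    """UPGMA over the k singleton clusters on voxel-level Dice distances."""
    if len(c.labels) != d.n:
        raise ConsistencyError(
            f"clustering covers {len(c.labels)} voxels, distances cover {d.n}"
        )
    k = c.k
    if k < 2:
        raise ParameterError(f"need at least 2 singleton clusters, got {k}")

    D = d.square()
    onehot = np.zeros((k, d.n))
    onehot[c.labels, np.arange(d.n)] = 1.0
    sizes_arr = onehot.sum(axis=1)
    cross = onehot @ D @ onehot.T  # sums of cross-pair distances

    size = {j: float(sizes_arr[j]) for j in range(k)}
    dist: dict[tuple[int, int], float] = {}
    for a in range(k):
        for b in range(a + 1, k):
            dist[(a, b)] = cross[a, b] / (sizes_arr[a] * sizes_arr[b])

    merges: list[tuple[int, int, float, int]] = []
    for step in range(k - 1):
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        new = k + step
        merges.append((a, b, float(h), new))
        dist.pop((a, b))
        for other in list(size):
            if other in (a, b):
                continue
            da = dist.pop((min(a, other), max(a, other)))
            db = dist.pop((min(b, other), max(b, other)))
            merged = (size[a] * da + size[b] * db) / (size[a] + size[b])
            dist[(other, new)] = merged
        size[new] = size[a] + size[b]
        del size[a], size[b]
    return MergeTree(k=k, merges=merges)


# ---------------------------------------------------------------------------
# cutting
# ---------------------------------------------------------------------------

def cut_tree(t: MergeTree, n_clusters: int) -> np.ndarray:
    """Per-singleton group labels after stopping at ``n_clusters`` groups.

    Groups are numbered 0..n_clusters-1 in order of their smallest singleton
    id, so the result is deterministic.
    """
    if not 1 <= n_clusters <= t.k:
        raise ParameterError(f"n_clusters={n_clusters} outside 1..{t.k}")
    groups: dict[int, set[int]] = {i: {i} for i in range(t.k)}
    for a, b, _, nid in t.merges[: t.k - n_clusters]:
        groups[nid] = groups.pop(a) | groups.pop(b)
    labels = np.empty(t.k, dtype=np.int64)
    for gi, gid in enumerate(sorted(groups, key=lambda g: min(groups[g]))):
        for leaf in groups[gid]:
            labels[leaf] = gi
    return labels


def cut_voxel_labels(t: MergeTree, c: Clustering, n_clusters: int) -> np.ndarray:
    """Voxel labels after cutting the tree at ``n_clusters`` groups."""
    return cut_tree(t, n_clusters)[c.labels]
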