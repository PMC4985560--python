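"""Dice-based voxel distances and seeded k-medoids partitioning.

The similarity between two analysis voxels u and v is the Dice coefficient
of their driver-line sets, ``s(u, v) = 2|L_u n L_v| / (|L_u| + |L_v|)``;
clustering runs on the distance ``d = 1 - s``, a semimetric bounded in
[0, 1]. Voxels inside one functional unit share most of their active
enhancers, so their mutual distance is small.

k-medoids here is the alternating (Voronoi-style) iteration with seeded
uniform initialization: assign every voxel to its nearest medoid, then move
each medoid to the cluster member minimizing total within-cluster distance,
until the assignment is stable. All tie-breaks go to the lowest index so a
(distances, k, seed) triple maps to exactly one clustering. A PAM
(BUILD + SWAP) mode is available for small problems where the extra
O(k (n-k)^2) sweep cost is affordable.

If a medoid wins no voxel during assignment (typical when two medoids land
on voxels with identical line sets), the redundant medoid is reseeded at
the voxel farthest from its assigned medoid. This keeps every cluster
non-empty, never increases the cost, and lets redundant medoids migrate to
uncovered territory.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import squareform

from .errors import ParameterError
from .volumes import ExpressionMatrix

__all__ = [
    "CondensedDistances",
    "Clustering",
    "dice_distance",
    "pairwise_distances",
    "kmedoids",
]


@dataclass
class CondensedDistances:
    """Upper-triangle pairwise voxel distances in scipy's condensed layout."""

    n: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        expect = self.n * (self.n - 1) // 2
        if self.values.shape != (expect,):
            raise ParameterError(
                f"condensed vector has length {self.values.shape}, expected {expect}"
            )

    def square(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    @classmethod
    def from_square(cls, d: np.ndarray) -> "CondensedDistances":
        d = np.asarray(d, dtype=np.float64)
        return cls(d.shape[0], squareform(d, checks=False))


@dataclass
class Clustering:
    """Result of one k-medoids run over the analysis voxels."""

    labels: np.ndarray
    medoids: np.ndarray
    cost: float
    k: int
    seed: int
    n_iter: int
    cost_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.medoids = np.asarray(self.medoids, dtype=np.int64)
        if len(self.medoids) != self.k:
            raise ParameterError("number of medoids != k")
        if len(np.unique(self.medoids)) != self.k:
            raise ParameterError("medoids must be distinct")
        if not np.array_equal(self.labels[self.medoids], np.arange(self.k)):
            raise ParameterError("every medoid must belong to its own cluster")
        if len(np.unique(self.labels)) != self.k:
            raise ParameterError("every cluster must be non-empty")

    def to_json(self, path) -> None:
        payload = {
            "labels": self.labels.tolist(),
            "medoids": self.medoids.tolist(),
            "cost": self.cost,
            "k": self.k,
            "seed": self.seed,
            "n_iter": self.n_iter,
            "cost_trace": list(self.cost_trace),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "Clustering":
        d = json.loads(Path(path).read_text())
        return cls(
            labels=np.array(d["labels"]),
            medoids=np.array(d["medoids"]),
            cost=float(d["cost"]),
            k=int(d["k"]),
            seed=int(d["seed"]),
            n_iter=int(d["n_iter"]),
            cost_trace=[float(c) for c in d.get("cost_trace", [])],
        )


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def dice_distance(m: ExpressionMatrix, u: int, v: int) -> float:
    """``1 - 2|L_u n L_v| / (|L_u| + |L_v|)`` for voxels u, v."""
    a = m.occupancy[:, u]
    b = m.occupancy[:, v]
    na = int(np.count_nonzero(a))
    nb = int(np.count_nonzero(b))
    if na == 0 or nb == 0:
        raise ParameterError(
            f"voxel with empty line set (u={u}: {na} lines, v={v}: {nb}); "
            "run filter_voxels first"
        )
    inter = int(np.count_nonzero(a & b))
    return 1.0 - 2.0 * inter / (na + nb)


def pairwise_distances(m: ExpressionMatrix, block_size: int = 2048) -> CondensedDistances:
    """All n(n-1)/2 Dice distances.

    Intersections are integer counts accumulated via float32 matrix
    products (exact up to 2^24 lines), the final division runs in float64,
    so the result is independent of the blocking.
    """
    n = m.n_voxels
    if n < 2:
        raise ParameterError(f"need at least 2 voxels, got {n}")
    deg = m.occupancy.sum(axis=0).astype(np.int64)
    if (deg == 0).any():
        raise ParameterError("voxels with empty line sets; run filter_voxels first")
    occ = m.occupancy.astype(np.float32)
    D = np.empty((n, n), dtype=np.float64)
    denom = deg[None, :].astype(np.float64)
    for i0 in range(0, n, block_size):
        i1 = min(i0 + block_size, n)
        inter = (occ[:, i0:i1].T @ occ).astype(np.float64)
        D[i0:i1] = 1.0 - 2.0 * inter / (deg[i0:i1, None] + denom)
    np.fill_diagonal(D, 0.0)
    return CondensedDistances(n, squareform(D, checks=False))


# ---------------------------------------------------------------------------
# k-medoids
# ---------------------------------------------------------------------------

def _assign(D: np.ndarray, medoids: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-medoid assignment with deterministic empty-cluster repair."""
    n = D.shape[0]
    medoids = medoids.copy()
    labels = None
    for _ in range(k + 1):
        A = D[medoids]
        labels = np.argmin(A, axis=0)  # ties -> lowest medoid index
        sizes = np.bincount(labels, minlength=k)
        empties = np.flatnonzero(sizes == 0)
        if not len(empties):
            break
        # the redundant medoid restarts at the worst-served voxel
        dist = A[labels, np.arange(n)].copy()
        dist[medoids] = -1.0
        medoids[empties[0]] = int(np.argmax(dist))
    # a medoid is distance 0 from itself, so pinning it to its own cluster
    # only resolves exact ties and never changes the cost
    labels[medoids] = np.arange(k)
    return labels, medoids


def _run_alternate(
    D: np.ndarray, k: int, rng: np.random.Generator, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, int, list[float]]:
    n = D.shape[0]
    medoids = np.sort(rng.choice(n, size=k, replace=False))
    labels, medoids = _assign(D, medoids, k)
    cost = float(D[medoids[labels], np.arange(n)].sum())
    trace = [cost]
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        new_medoids = medoids.copy()
        for j in range(k):
            members = np.flatnonzero(labels == j)
            within = D[np.ix_(members, members)].sum(axis=0)
            new_medoids[j] = members[int(np.argmin(within))]  # ties -> lowest voxel
        new_labels, new_medoids = _assign(D, new_medoids, k)
        cost = float(D[new_medoids[new_labels], np.arange(n)].sum())
        trace.append(cost)
        if np.array_equal(new_labels, labels) and np.array_equal(new_medoids, medoids):
            break
        labels, medoids = new_labels, new_medoids
    return labels, medoids, cost, n_iter, trace


def _run_pam(D: np.ndarray, k: int, max_iter: int):
    """Greedy BUILD then best-improvement SWAP; deterministic."""
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        cur = D[medoids].min(axis=0)
        gains = np.maximum(cur[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -1.0
        medoids.append(int(np.argmax(gains)))
    medoids = np.sort(np.array(medoids))
    cost = float(D[medoids].min(axis=0).sum())
    trace = [cost]
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        best = (0.0, None)
        non_medoids = np.setdiff1d(np.arange(n), medoids)
        for mi in range(k):
            trial = medoids.copy()
            for c in non_medoids:
                trial[mi] = c
                tc = float(D[trial].min(axis=0).sum())
                if cost - tc > best[0] + 1e-15:
                    best = (cost - tc, (mi, int(c)))
        if best[1] is None:
            break
        mi, c = best[1]
        medoids[mi] = c
        medoids = np.sort(medoids)
        cost = float(D[medoids].min(axis=0).sum())
        trace.append(cost)
    labels, medoids = _assign(D, medoids, k)
    cost = float(D[medoids[labels], np.arange(n)].sum())
    return labels, medoids, cost, n_iter, trace


def kmedoids(
    d: CondensedDistances,
    k: int,
    seed: int = 0,
    max_iter: int = 100,
    n_restarts: int = 1,
    method: str = "alternate",
) -> Clustering:
    """Partition n voxels into k clusters around medoid voxels.

    Parameters
    ----------
    d
        Precomputed pairwise distances.
    k
        Number of clusters (the method's main knob; 60 in typical
        whole-region runs).
    seed
        Seeds the medoid initialization. Restart r uses the independent
        stream ``default_rng([seed, r])``; the lowest-cost restart wins
        (ties -> lowest restart index). Identical arguments give bit-for-bit
        identical results.
    method
        ``"alternate"`` (default) or ``"pam"``.
    """
    n = d.n
    if not 1 <= k <= n:
        raise ParameterError(f"k={k} outside valid range 1..{n}")
    if max_iter < 1:
        raise ParameterError(f"max_iter must be >= 1, got {max_iter}")
    if n_restarts < 1:
        raise ParameterError(f"n_restarts must be >= 1, got {n_restarts}")
    if method not in ("alternate", "pam"):
        raise ParameterError(f"unknown method '{method}'")

    D = d.square()
    best = None
    for r in range(n_restarts):
        if method == "pam":
            out = _run_pam(D, k, max_iter)
        else:
            rng = np.random.default_rng([seed, r])
            out = _run_alternate(D, k, rng, max_iter)
        if best is None or out[2] < best[2]:
            best = out
        if method == "pam":
            break  # deterministic, restarts are identical
    labels, medoids, cost, n_iter, trace = best
    return Clustering(
        labels=labels,
        medoids=medoids,
        cost=cost,
        k=k,
        seed=seed,
        n_iter=n_iter,
        cost_trace=trace,
    )
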