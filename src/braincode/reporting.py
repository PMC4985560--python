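"""Per-cluster driver-line scoring, selection, and average images.

For a cluster and a line, ``coverage_in`` is the fraction of the cluster's
voxels where the line expresses and ``coverage_out`` the fraction of region
voxels outside the cluster where it expresses. Specificity is
``coverage_in * (1 - coverage_out)``: bounded in [0, 1], maximal for a line
filling the cluster and nothing else, and exactly zero for a fully broad
line. Selected ("strongly expressing, not broad") lines default to
coverage_in >= 0.5 and coverage_out <= 0.1 and feed the cluster's average
image, the voxelwise mean of the selected lines' full stacks (averaging the
whole template, not only the region, preserves features such as midline
symmetry outside the analyzed region).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agglomeration import MergeTree, cluster_name, cut_voxel_labels
from .clustering import Clustering
from .errors import ConsistencyError, ParameterError
from .volumes import IntensityVolume, VoxelTable

log = logging.getLogger("braincode")

DEFAULT_MIN_IN = 0.5
DEFAULT_MAX_OUT = 0.1


@dataclass
class LineScore:
    line_id: str
    coverage_in: float
    coverage_out: float

    @property
    def specificity(self) -> float:
        return self.coverage_in * (1.0 - self.coverage_out)


@dataclass
class ClusterReport:
    cluster_id: str
    scores: list[LineScore]           # ranked by specificity desc, ties by line_id
    selected: list[str]
    average_image: IntensityVolume | None = None

    def to_frame(self) -> pd.DataFrame:
        sel = set(self.selected)
        return pd.DataFrame(
            {
                "cluster": self.cluster_id,
                "line_id": [s.line_id for s in self.scores],
                "coverage_in": [s.coverage_in for s in self.scores],
                "coverage_out": [s.coverage_out for s in self.scores],
                "specificity": [s.specificity for s in self.scores],
                "selected": [s.line_id in sel for s in self.scores],
            }
        )


def score_lines(m, c: Clustering, cluster: int) -> list[LineScore]:
    """One ranked LineScore per driver line for the given cluster index."""
    if not 0 <= cluster < c.k:
        raise ParameterError(f"cluster {cluster} outside 0..{c.k - 1}")
    inside = c.labels == cluster
    n_in = int(inside.sum())
    n_out = int((~inside).sum())
    if n_in == 0:
        raise ParameterError(f"cluster {cluster} is empty")
    occ = m.occupancy
    cov_in = occ[:, inside].sum(axis=1) / n_in
    cov_out = (
        occ[:, ~inside].sum(axis=1) / n_out if n_out else np.zeros(m.n_lines)
    )
    scores = [
        LineScore(lid, float(ci), float(co))
        for lid, ci, co in zip(m.line_ids, cov_in, cov_out)
    ]
    scores.sort(key=lambda s: (-s.specificity, s.line_id))
    return scores


def select_lines(
    scores: list[LineScore],
    min_in: float = DEFAULT_MIN_IN,
    max_out: float = DEFAULT_MAX_OUT,
) -> list[str]:
    """Line ids with coverage_in >= min_in and coverage_out <= max_out
    (inclusive bounds); ranking order preserved. May be empty."""
    if not 0 <= min_in <= 1 or not 0 <= max_out <= 1:
        raise ParameterError("min_in and max_out must be fractions in [0, 1]")
    out = [s.line_id for s in scores if s.coverage_in >= min_in and s.coverage_out <= max_out]
    if not out:
        log.info("select_lines: no line passed min_in=%g, max_out=%g", min_in, max_out)
    return out


def average_image(
    volumes: dict[str, IntensityVolume], selected: list[str]
) -> IntensityVolume | None:
    """Voxelwise mean of the selected lines' full stacks; None if empty."""
    if not selected:
        return None
    grids = []
    voxel_size = None
    shape = None
    for lid in selected:
        vol = volumes[lid]
        if shape is None:
            shape, voxel_size = vol.shape, vol.voxel_size
        elif vol.shape != shape:
            raise ConsistencyError(f"line '{lid}' shape {vol.shape} != {shape}")
        grids.append(np.asarray(vol.grid, dtype=np.float64))
    return IntensityVolume(np.mean(grids, axis=0), voxel_size)


def cluster_report(
    m,
    c: Clustering,
    cluster: int,
    volumes: dict[str, IntensityVolume] | None = None,
    min_in: float = DEFAULT_MIN_IN,
    max_out: float = DEFAULT_MAX_OUT,
) -> ClusterReport:
    scores = score_lines(m, c, cluster)
    selected = select_lines(scores, min_in=min_in, max_out=max_out)
    avg = average_image(volumes, selected) if volumes is not None else None
    return ClusterReport(cluster_name(cluster), scores, selected, avg)


def export_labels(
    c: Clustering,
    voxels: VoxelTable,
    shape: tuple[int, int, int],
    tree: MergeTree | None = None,
    cut_levels: tuple[int, ...] = (),
) -> tuple[np.ndarray, pd.DataFrame, dict[int, np.ndarray]]:
    """Integer label volume (0 background, singleton c -> c+1) plus a value
    -> C-name table, and one extra volume per requested tree cut level."""
    if len(c.labels) != len(voxels):
        raise ConsistencyError(
            f"clustering covers {len(c.labels)} voxels, table has {len(voxels)}"
        )
    x, y, z = voxels.coords.T
    if len(x) and (x.max() >= shape[0] or y.max() >= shape[1] or z.max() >= shape[2]):
        raise ConsistencyError(f"voxel coordinates exceed grid shape {shape}")
    grid = np.zeros(shape, dtype=np.int32)
    grid[x, y, z] = c.labels + 1
    names = pd.DataFrame(
        {"value": np.arange(1, c.k + 1), "cluster": [cluster_name(j) for j in range(c.k)]}
    )
    cuts: dict[int, np.ndarray] = {}
    for level in cut_levels:
        if tree is None:
            raise ParameterError("cut levels requested without a merge tree")
        cut = np.zeros(shape, dtype=np.int32)
        cut[x, y, z] = cut_voxel_labels(tree, c, level) + 1
        cuts[level] = cut
    return grid, names, cuts
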