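"""Synthetic driver-line collections with known functional units.

The generator emulates the statistical structure co-expression parcellation
relies on: a region is tiled by compact units (space-filling Voronoi cells,
like densely packed olfactory glomeruli, or dispersed ellipsoidal blobs
with buffer gaps, like optic glomeruli); each synthetic driver line
expresses in a random subset of units (plus a fraction of broad lines
expressing everywhere); voxel-level false positives/negatives, Gaussian
intensity variation, and a per-line integer-voxel translation (emulating
the few-micrometre registration error of real template alignments) corrupt
the ideal patterns. Everything is deterministic given the seed.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import PackingError, ParameterError
from .volumes import (
    IntensityVolume,
    RegionMask,
    write_manifest,
    write_mask,
    write_labels,
    write_volume,
)

__all__ = ["PhantomSpec", "PhantomDataset", "make_units", "make_lines", "generate", "write_dataset"]


@dataclass
class PhantomSpec:
    """Study conditions for one synthetic collection.

    Defaults describe a desk-scale stand-in for a genome-scale collection:
    a 40^3 region split into K=10 units, L=300 lines each expressing in a
    random ~20% of units, 5% broad lines, 2% voxel false positives, 10%
    false negatives, and 1 voxel of registration jitter.
    """

    shape: tuple[int, int, int] = (40, 40, 40)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mode: str = "voronoi"          # "voronoi" | "blobs"
    K: int = 10                    # number of functional units
    mirror: bool = False           # build one half, reflect across x midplane
    L: int = 300                   # number of driver lines
    p_incl: float = 0.2            # per-unit inclusion probability per line
    f_broad: float = 0.05          # fraction of lines expressing in all units
    p_fp: float = 0.02             # voxelwise false-positive rate
    p_fn: float = 0.1              # voxelwise false-negative rate
    intensity_on: float = 100.0    # mean intensity inside expression
    intensity_off: float = 0.0     # mean background intensity
    intensity_sd: float = 10.0     # Gaussian intensity noise sd
    jitter_sd: float = 1.0         # per-line translation sd, micrometres
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("voronoi", "blobs"):
            raise ParameterError(f"unknown unit mode '{self.mode}'")
        if self.K < 1 or self.L < 1:
            raise ParameterError("K and L must be >= 1")
        for name in ("p_incl", "f_broad", "p_fp", "p_fn"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.mirror and self.shape[0] % 2:
            raise ParameterError("mirror mode needs an even grid width")
        self.shape = tuple(int(s) for s in self.shape)
        self.voxel_size = tuple(float(s) for s in self.voxel_size)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown phantom spec keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["shape"] = list(d["shape"])
        d["voxel_size"] = list(d["voxel_size"])
        return d


@dataclass
class PhantomDataset:
    line_ids: list[str]
    volumes: list[IntensityVolume]
    mask: RegionMask
    truth: np.ndarray                  # unit ids 1..K, 0 background
    membership: np.ndarray             # L x K boolean line-to-unit table
    spec: PhantomSpec = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# units
# ---------------------------------------------------------------------------

def _coord_grids(shape):
    return np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")


def _voronoi_half(shape, K, rng) -> np.ndarray:
    W, H, D = shape
    if K > W * H * D:
        raise PackingError(f"cannot place {K} centers on a {shape} grid")
    flat = rng.choice(W * H * D, size=K, replace=False)
    centers = np.column_stack(np.unravel_index(np.sort(flat), shape))
    X, Y, Z = _coord_grids(shape)
    best_d = np.full(shape, np.inf)
    labels = np.zeros(shape, dtype=np.int32)
    for i, c in enumerate(centers):
        d2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
        closer = d2 < best_d  # ties -> earlier (lower-id) center
        best_d[closer] = d2[closer]
        labels[closer] = i + 1
    return labels


def _blobs_half(shape, K, rng, max_tries_per_unit: int = 300) -> np.ndarray:
    X, Y, Z = _coord_grids(shape)
    truth = np.zeros(shape, dtype=np.int32)
    placed = 0
    tries = 0
    lim = np.asarray(shape, dtype=float)
    while placed < K:
        if tries >= max_tries_per_unit * K:
            raise PackingError(
                f"placed only {placed} of {K} blobs on {shape} after {tries} tries"
            )
        tries += 1
        semi = rng.uniform(2.5, min(6.0, lim.min() / 4.0), size=3)
        lo = semi + 1.5
        hi = lim - 1.5 - semi
        if (hi <= lo).any():
            raise PackingError(f"grid {shape} too small for blob units")
        c = rng.uniform(lo, hi)
        grown = (
            ((X - c[0]) / (semi[0] + 1.5)) ** 2
            + ((Y - c[1]) / (semi[1] + 1.5)) ** 2
            + ((Z - c[2]) / (semi[2] + 1.5)) ** 2
        ) <= 1.0
        if (grown & (truth > 0)).any():
            continue
        blob = (
            ((X - c[0]) / semi[0]) ** 2
            + ((Y - c[1]) / semi[1]) ** 2
            + ((Z - c[2]) / semi[2]) ** 2
        ) <= 1.0
        truth[blob] = placed + 1
        placed += 1
    return truth


def make_units(spec: PhantomSpec, rng: np.random.Generator | None = None):
    """Ground-truth unit labels plus the region mask.

    In mirror mode one half is generated and reflected across the x
    midplane; paired units share an id, so the truth volume is invariant
    under the mirror map.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    build = _voronoi_half if spec.mode == "voronoi" else _blobs_half
    if spec.mirror:
        half_shape = (spec.shape[0] // 2,) + spec.shape[1:]
        half = build(half_shape, spec.K, rng)
        truth = np.concatenate([half, half[::-1]], axis=0)
    else:
        truth = build(spec.shape, spec.K, rng)
    mask = RegionMask(np.ones(spec.shape, dtype=bool), name="phantom")
    return truth, mask


# ---------------------------------------------------------------------------
# lines
# ---------------------------------------------------------------------------

def _shift_int(a: np.ndarray, offset: np.ndarray) -> np.ndarray:
    """Translate by integer voxels with zero fill."""
    out = np.zeros_like(a)
    src = []
    dst = []
    for ax, off in enumerate(offset):
        n = a.shape[ax]
        off = int(off)
        if abs(off) >= n:
            return out
        if off >= 0:
            dst.append(slice(off, n))
            src.append(slice(0, n - off))
        else:
            dst.append(slice(0, n + off))
            src.append(slice(-off, n))
    out[tuple(dst)] = a[tuple(src)]
    return out


def make_lines(
    spec: PhantomSpec,
    truth: np.ndarray,
    mask: RegionMask,
    rng: np.random.Generator,
):
    """Synthesize the L expression stacks and the line-to-unit table."""
    shape = spec.shape
    broad = rng.random(spec.L) < spec.f_broad
    membership = rng.random((spec.L, spec.K)) < spec.p_incl
    membership[broad] = True

    jitter_vox = np.asarray(spec.jitter_sd) / np.asarray(spec.voxel_size)
    volumes: list[IntensityVolume] = []
    for l in range(spec.L):
        member_ids = np.flatnonzero(membership[l]) + 1
        support = np.isin(truth, member_ids) & mask.grid
        if spec.p_fp > 0 or spec.p_fn > 0:
            u = rng.random(shape)
            occ = np.where(support, u >= spec.p_fn, u < spec.p_fp) & mask.grid
        else:
            occ = support
        inten = np.where(occ, spec.intensity_on, spec.intensity_off)
        if spec.intensity_sd > 0:
            inten = inten + rng.normal(0.0, spec.intensity_sd, shape)
        inten = np.clip(inten, 0.0, None)
        if spec.jitter_sd > 0:
            offset = np.rint(rng.normal(0.0, jitter_vox)).astype(int)
            inten = _shift_int(inten, offset)
        volumes.append(IntensityVolume(inten.astype(np.float32), spec.voxel_size))
    return volumes, membership


def generate(spec: PhantomSpec, line_seed: int | None = None) -> PhantomDataset:
    """Units plus lines; ``line_seed`` draws an independent line collection
    over the same ground-truth units (cross-collection experiments)."""
    rng = np.random.default_rng(spec.seed)
    truth, mask = make_units(spec, rng)
    line_rng = rng if line_seed is None else np.random.default_rng(line_seed)
    volumes, membership = make_lines(spec, truth, mask, line_rng)
    ids = [f"line_{i:04d}" for i in range(spec.L)]
    return PhantomDataset(
        line_ids=ids, volumes=volumes, mask=mask, truth=truth,
        membership=membership, spec=spec,
    )


def write_dataset(ds: PhantomDataset, out_dir) -> Path:
    """Write NRRD volumes, mask, truth, manifest TSV and membership TSV;
    returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vs = ds.volumes[0].voxel_size if ds.volumes else (1.0, 1.0, 1.0)
    paths = []
    for lid, vol in zip(ds.line_ids, ds.volumes):
        p = f"{lid}.nrrd"
        write_volume(vol, out / p)
        paths.append(p)
    write_mask(ds.mask, out / "mask.nrrd", vs)
    write_labels(ds.truth, out / "truth.nrrd", vs)
    manifest = out / "manifest.tsv"
    write_manifest(manifest, ds.line_ids, paths)
    pd.DataFrame(
        ds.membership,
        index=ds.line_ids,
        columns=[f"unit_{g + 1}" for g in range(ds.membership.shape[1])],
    ).to_csv(out / "membership.tsv", sep="\t")
    if ds.spec is not None:
        (out / "spec.yaml").write_text(yaml.safe_dump(ds.spec.to_dict()))
    return manifest
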