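"""Volume I/O and construction of the driver-line x voxel expression matrix.

A collection of GAL4 driver-line expression stacks, all registered to one
template brain, is reduced to a boolean occupancy matrix: entry (l, u) says
whether line l expresses above an intensity threshold at analysis voxel u.
The analysis voxels are the template-grid positions inside a region mask,
optionally after integer-factor mean-pooling to a coarser analysis grid
(full acquisition resolution is finer than the scale at which co-expression
is informative, and pairwise-distance cost grows with the square of the
voxel count).

Conventions
-----------
Grids are indexed ``grid[x, y, z]``: x lateral, y dorsoventral,
z anteroposterior. Coordinates are 0-based. NRRD headers carry voxel
spacing in micrometres; TIFF stacks default to unit spacing. Label and mask
volumes use the same axis order as intensity volumes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import SimpleITK as sitk
import tifffile

from .errors import (
    EmptyRegionError,
    FormatError,
    ParameterError,
    RegistrationError,
)

log = logging.getLogger("braincode")

#: default global binarization threshold on an 8-bit intensity scale
DEFAULT_THRESHOLD = 20.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class IntensityVolume:
    """A single-channel 3D stack on the template grid.

    Parameters
    ----------
    grid
        3D array of non-negative intensities, axes (x, y, z).
    voxel_size
        Voxel edge lengths (dx, dy, dz) in micrometres.
    """

    grid: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise FormatError(f"expected a 3D grid, got {self.grid.ndim}D")
        if self.grid.size and float(self.grid.min()) < 0:
            raise FormatError("intensity volumes must be non-negative")
        self.voxel_size = tuple(float(s) for s in self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape


@dataclass
class RegionMask:
    """Boolean analysis-region mask on the template grid."""

    grid: np.ndarray
    name: str = "region"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.ndim != 3:
            raise FormatError(f"expected a 3D mask, got {self.grid.ndim}D")
        if not self.grid.any():
            raise EmptyRegionError(f"mask '{self.name}' has no true voxel")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape


@dataclass
class VoxelTable:
    """Ordered (x, y, z) coordinates of the analysis voxels.

    Index i of every downstream labels / occupancy array refers to row i
    here. Rows are unique and sorted lexicographically by (z, y, x).
    """

    coords: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=np.int64)
        if c.ndim != 2 or c.shape[1] != 3:
            raise FormatError("voxel table must be an (n, 3) integer array")
        order = np.lexsort((c[:, 0], c[:, 1], c[:, 2]))
        if not np.array_equal(order, np.arange(len(c))):
            c = c[order]
        if len(np.unique(c, axis=0)) != len(c):
            raise FormatError("voxel coordinates must be unique")
        self.coords = c

    @classmethod
    def from_mask(cls, mask_grid: np.ndarray) -> "VoxelTable":
        return cls(np.argwhere(np.asarray(mask_grid, dtype=bool)))

    def __len__(self) -> int:
        return len(self.coords)

    def index_grid(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Dense coordinate -> voxel-index lookup; -1 outside the table."""
        idx = np.full(shape, -1, dtype=np.int64)
        x, y, z = self.coords.T
        idx[x, y, z] = np.arange(len(self.coords))
        return idx


@dataclass
class ExpressionMatrix:
    """Boolean lines x voxels occupancy of driver-line expression.

    Column u is the voxel's line set L_u: the drivers expressing above
    threshold at analysis voxel u. ``mean_intensity`` optionally keeps the
    underlying (pooled) intensities on the same layout.
    """

    line_ids: list[str]
    occupancy: np.ndarray
    voxels: VoxelTable
    mean_intensity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.line_ids = [str(l) for l in self.line_ids]
        if len(set(self.line_ids)) != len(self.line_ids):
            raise FormatError("line_ids must be unique")
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        expect = (len(self.line_ids), len(self.voxels))
        if self.occupancy.shape != expect:
            raise FormatError(
                f"occupancy shape {self.occupancy.shape} != lines x voxels {expect}"
            )
        if self.mean_intensity is not None:
            self.mean_intensity = np.asarray(self.mean_intensity, dtype=np.float32)
            if self.mean_intensity.shape != expect:
                raise FormatError("mean_intensity shape mismatch")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _is_tiff(path) -> bool:
    return str(path).lower().endswith((".tif", ".tiff"))


def read_volume(path) -> IntensityVolume:
    """Read a single-channel 3D NRRD or multi-page TIFF stack.

    NRRD voxel spacing is honored; TIFF stacks get unit spacing with a
    logged warning. Raises :class:`FormatError` for multi-channel data and
    ``OSError`` for unreadable files.
    """
    if _is_tiff(path):
        try:
            arr = tifffile.imread(str(path))
        except (tifffile.TiffFileError, ValueError, OSError) as exc:
            raise OSError(f"cannot read TIFF '{path}': {exc}") from None
        if arr.ndim == 4:
            raise FormatError(
                f"'{path}': expected single-channel data, got {arr.shape[-1]} channels"
            )
        if arr.ndim != 3:
            raise FormatError(f"'{path}': expected a 3D stack, got {arr.ndim}D")
        log.warning("no voxel size in TIFF '%s'; assuming (1, 1, 1) um", path)
        # tifffile yields (pages=z, y, x)
        return IntensityVolume(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise OSError(f"cannot read '{path}': {exc}") from None
    ncomp = img.GetNumberOfComponentsPerPixel()
    if ncomp != 1:
        raise FormatError(
            f"'{path}': expected single-channel data, got {ncomp} channels"
        )
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    if arr.ndim != 3:
        raise FormatError(f"'{path}': expected a 3D stack, got {arr.ndim}D")
    spacing = tuple(float(s) for s in img.GetSpacing())
    return IntensityVolume(np.ascontiguousarray(arr.transpose(2, 1, 0)), spacing)


def write_volume(vol: IntensityVolume, path) -> None:
    """Write an intensity volume as NRRD (spacing in header) or TIFF."""
    arr = np.ascontiguousarray(np.asarray(vol.grid).transpose(2, 1, 0))
    if _is_tiff(path):
        tifffile.imwrite(str(path), arr)
        return
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(float(s) for s in vol.voxel_size))
    sitk.WriteImage(img, str(path), useCompression=False)


def read_labels(path) -> np.ndarray:
    """Read an integer label volume, axes (x, y, z)."""
    return np.asarray(read_volume(path).grid).astype(np.int32)


def write_labels(grid: np.ndarray, path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    write_volume(IntensityVolume(np.asarray(grid, dtype=np.int32), voxel_size), path)


def read_mask(path, name: str = "region") -> RegionMask:
    return RegionMask(read_labels(path) > 0, name=name)


def write_mask(mask: RegionMask, path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    write_labels(mask.grid.astype(np.uint8), path, voxel_size)


# ---------------------------------------------------------------------------
# manifest (TSV: line_id <TAB> path)
# ---------------------------------------------------------------------------

def write_manifest(path, line_ids: Sequence[str], volume_paths: Sequence[str]) -> None:
    pd.DataFrame({"line_id": list(line_ids), "path": list(volume_paths)}).to_csv(
        path, sep="\t", index=False
    )


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"line_id", "path"} <= set(df.columns):
        raise FormatError(f"manifest '{path}' must have columns line_id and path")
    return df


def load_collection(manifest_path) -> tuple[list[str], Iterator[IntensityVolume]]:
    """Line ids plus a lazy volume iterator; relative paths resolve against
    the manifest's directory."""
    df = read_manifest(manifest_path)
    base = Path(manifest_path).parent

    def _iter() -> Iterator[IntensityVolume]:
        for p in df["path"]:
            q = Path(p)
            yield read_volume(q if q.is_absolute() else base / q)

    return df["line_id"].tolist(), _iter()


# ---------------------------------------------------------------------------
# downsampling
# ---------------------------------------------------------------------------

def _check_factor(factor) -> int:
    if int(factor) != factor or factor < 1:
        raise ParameterError(f"downsample factor must be a positive integer, got {factor}")
    return int(factor)


def _block_reduce(a: np.ndarray, f: int, mean: bool = True) -> np.ndarray:
    """Per-axis reduceat block sum/mean; trailing partial blocks use the
    voxels available (counts factorize across axes, so sequential per-axis
    means equal the true block mean)."""
    a = np.asarray(a, dtype=np.float64)
    for ax in range(3):
        idx = np.arange(0, a.shape[ax], f)
        sums = np.add.reduceat(a, idx, axis=ax)
        if mean:
            counts = np.minimum(idx + f, a.shape[ax]) - idx
            shape = [1, 1, 1]
            shape[ax] = len(idx)
            sums = sums / counts.reshape(shape)
        a = sums
    return a


def downsample(vol: IntensityVolume, factor: int) -> IntensityVolume:
    """Mean-pool by an integer factor; voxel size scales accordingly."""
    f = _check_factor(factor)
    if f == 1:
        return IntensityVolume(vol.grid.copy(), vol.voxel_size)
    return IntensityVolume(
        _block_reduce(vol.grid, f), tuple(s * f for s in vol.voxel_size)
    )


def downsample_mask(mask: RegionMask, factor: int) -> RegionMask:
    """A pooled voxel belongs to the region when >= 50% of its block does."""
    f = _check_factor(factor)
    if f == 1:
        return RegionMask(mask.grid.copy(), mask.name)
    frac = _block_reduce(mask.grid.astype(np.float64), f)
    return RegionMask(frac >= 0.5, mask.name)


def downsample_labels(grid: np.ndarray, factor: int) -> np.ndarray:
    """Majority-vote pooling of an integer label volume (ties -> smaller
    label)."""
    f = _check_factor(factor)
    grid = np.asarray(grid)
    if f == 1:
        return grid.copy()
    values = np.unique(grid)
    best_count = None
    best_label = None
    for val in values:  # ascending, so strict > keeps the smaller label on ties
        cnt = _block_reduce((grid == val).astype(np.float64), f, mean=False)
        if best_count is None:
            best_count = cnt
            best_label = np.full(cnt.shape, val, dtype=grid.dtype)
        else:
            take = cnt > best_count
            best_count = np.where(take, cnt, best_count)
            best_label = np.where(take, val, best_label)
    return best_label


# ---------------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------------

def build_matrix(
    volumes: Iterable[IntensityVolume],
    line_ids: Sequence[str],
    mask: RegionMask,
    threshold: float = DEFAULT_THRESHOLD,
    downsample_factor: int = 1,
) -> ExpressionMatrix:
    """Threshold every line's stack over the region to a boolean occupancy row.

    Volumes may be a lazy iterator (one stack in memory at a time). Each
    stack must share the mask's grid; a mismatch raises
    :class:`RegistrationError` naming the offending line.
    """
    if threshold < 0:
        raise ParameterError(f"threshold must be >= 0, got {threshold}")
    f = _check_factor(downsample_factor)
    ds_mask = downsample_mask(mask, f)
    voxels = VoxelTable.from_mask(ds_mask.grid)
    x, y, z = voxels.coords.T

    occ_rows: list[np.ndarray] = []
    int_rows: list[np.ndarray] = []
    ids = list(line_ids)
    for lid, vol in zip(ids, volumes, strict=True):
        if vol.shape != mask.shape:
            raise RegistrationError(
                f"line '{lid}': volume shape {vol.shape} does not match "
                f"mask shape {mask.shape}"
            )
        ds = downsample(vol, f)
        vals = ds.grid[x, y, z]
        occ_rows.append(vals >= threshold)
        int_rows.append(vals.astype(np.float32))

    if not occ_rows:
        raise ParameterError("empty volume collection")
    return ExpressionMatrix(
        line_ids=ids,
        occupancy=np.asarray(occ_rows),
        voxels=voxels,
        mean_intensity=np.asarray(int_rows),
    )


def filter_voxels(m: ExpressionMatrix, min_lines: int = 1) -> ExpressionMatrix:
    """Drop voxels expressed by fewer than ``min_lines`` drivers.

    Guarantees the Dice denominator is never zero downstream. Raises
    :class:`EmptyRegionError` if nothing survives.
    """
    if min_lines < 1:
        raise ParameterError(f"min_lines must be >= 1, got {min_lines}")
    counts = m.occupancy.sum(axis=0)
    keep = counts >= min_lines
    n_drop = int((~keep).sum())
    if not keep.any():
        raise EmptyRegionError(
            f"all {len(keep)} voxels have fewer than {min_lines} expressing lines"
        )
    if n_drop:
        log.info(
            "filter_voxels: dropped %d of %d voxels with < %d expressing lines",
            n_drop, len(keep), min_lines,
        )
    return ExpressionMatrix(
        line_ids=m.line_ids,
        occupancy=m.occupancy[:, keep],
        voxels=VoxelTable(m.voxels.coords[keep]),
        mean_intensity=None if m.mean_intensity is None else m.mean_intensity[:, keep],
    )
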