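"""Streamline and volume data model, coordinate handling, resampling, and file I/O.

Canonical coordinates are world millimetres (RASMM) throughout the package;
voxel indices appear only at format boundaries and in occupancy rasterization.
A voxel's spatial extent is the half-open unit cube centred on its world
coordinate, i.e. world point ``p`` falls in voxel ``floor(A^-1 p + 0.5)``
for affine ``A`` (0-based indexing).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np
import nibabel as nib
from nibabel.streamlines import Tractogram
from nibabel.streamlines.tck import TckFile
from nibabel.streamlines.trk import TrkFile

logger = logging.getLogger(__name__)

VolumeKind = Literal["intensity", "binary_mask", "label_map", "occupancy"]


class DegenerateStreamlineError(ValueError):
    """Raised for zero-length or sub-2-point streamlines."""


class TractogramFormatError(ValueError):
    """Raised when a tractogram file cannot be parsed."""


class GridMismatchError(ValueError):
    """Raised when two volumes do not share a grid/affine."""


# ---------------------------------------------------------------------------
# Streamlines


def as_streamline(points: Sequence) -> np.ndarray:
    """Validate and return a streamline as a float64 (K, 3) array.

    A streamline is an ordered polyline of K >= 2 finite 3-D points in
    world mm.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"streamline must be (K, 3), got shape {pts.shape}")
    if pts.shape[0] < 2:
        raise DegenerateStreamlineError("streamline needs at least 2 points")
    if not np.all(np.isfinite(pts)):
        raise ValueError("streamline contains non-finite coordinates")
    return pts


def streamline_length(points: np.ndarray) -> float:
    """Total arc length (mm) of a polyline."""
    pts = np.asarray(points, dtype=np.float64)
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


@dataclass
class StreamlineSet:
    """A bundle: list of (K_i, 3) world-mm point arrays plus a reference affine.

    The affine is the voxel->world transform of the grid the bundle is
    associated with (used when writing TRK and when rasterizing).
    """

    streamlines: list[np.ndarray] = field(default_factory=list)
    reference_affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    reference_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.streamlines = [as_streamline(s) for s in self.streamlines]
        self.reference_affine = np.asarray(self.reference_affine, dtype=np.float64)
        if self.reference_affine.shape != (4, 4):
            raise ValueError("reference_affine must be 4x4")

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.streamlines)

    def __getitem__(self, i):
        return self.streamlines[i]

    @property
    def n_points(self) -> int | None:
        """Common point count K, or None if members disagree."""
        ks = {len(s) for s in self.streamlines}
        return ks.pop() if len(ks) == 1 else None

    def lengths(self) -> np.ndarray:
        return np.array([streamline_length(s) for s in self.streamlines])

    def as_array(self) -> np.ndarray:
        """Stack into (N, K, 3); requires a common K."""
        if len(self.streamlines) == 0:
            return np.empty((0, 0, 3))
        if self.n_points is None:
            raise ValueError("streamlines have differing point counts; resample first")
        return np.stack(self.streamlines)

    def resampled(self, k: int) -> "StreamlineSet":
        return StreamlineSet(
            [resample_streamline(s, k) for s in self.streamlines],
            reference_affine=self.reference_affine,
            reference_shape=self.reference_shape,
        )


@dataclass
class Volume3D:
    """A 3-D scalar or integer grid with a voxel->world (mm) affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    kind: VolumeKind = "intensity"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got ndim={self.data.ndim}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.kind == "binary_mask":
            vals = np.unique(self.data)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("binary_mask volume must contain only {0, 1}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points to continuous voxel coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, vox: np.ndarray) -> np.ndarray:
        vox = np.atleast_2d(np.asarray(vox, dtype=np.float64))
        return vox @ self.affine[:3, :3].T + self.affine[:3, 3]

    def voxel_indices(self, points: np.ndarray) -> np.ndarray:
        """Integer voxel containing each world point (centre convention)."""
        return np.floor(self.world_to_voxel(points) + 0.5).astype(np.int64)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean: does each world point fall inside the grid?"""
        idx = self.voxel_indices(points)
        shp = np.array(self.shape)
        return np.all((idx >= 0) & (idx < shp), axis=1)

    def values_at(self, points: np.ndarray, outside=0) -> np.ndarray:
        """Nearest-voxel lookup of the volume at world points.

        Points outside the grid return ``outside``.
        """
        idx = self.voxel_indices(points)
        inside = np.all((idx >= 0) & (idx < np.array(self.shape)), axis=1)
        out = np.full(len(idx), outside, dtype=self.data.dtype)
        ii = idx[inside]
        out[inside] = self.data[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out

    def same_grid(self, other: "Volume3D", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))


# ---------------------------------------------------------------------------
# Resampling


def resample_streamline(points: np.ndarray, k: int) -> np.ndarray:
    """Resample a polyline to ``k`` points equidistant in arc length.

    Endpoints are preserved exactly.  Raises
    :class:`DegenerateStreamlineError` if the polyline has zero total length.
    """
    pts = as_streamline(points)
    if k < 2:
        raise ValueError("k must be >= 2")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0.0:
        raise DegenerateStreamlineError("zero-length polyline cannot be resampled")
    targets = np.linspace(0.0, total, k)
    out = np.empty((k, 3))
    for d in range(3):
        out[:, d] = np.interp(targets, cum, pts[:, d])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


# ---------------------------------------------------------------------------
# Tractogram I/O (TRK / TCK via nibabel)


def _format_for(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("trk", "tck"):
            raise ValueError(f"unknown tractogram format {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".trk", ".tck"):
        return suffix[1:]
    raise ValueError(f"cannot infer tractogram format from {path}")


def write_tractogram(
    sset: StreamlineSet, path: str | Path, fmt: str | None = None
) -> None:
    """Write a bundle to TRK or TCK.  Coordinates are stored in world mm."""
    fmt = _format_for(path, fmt)
    tg = Tractogram(list(sset.streamlines), affine_to_rasmm=np.eye(4))
    if fmt == "trk":
        header = {}
        header["voxel_to_rasmm"] = sset.reference_affine.astype(np.float32)
        zooms = np.sqrt((sset.reference_affine[:3, :3] ** 2).sum(axis=0))
        header["voxel_sizes"] = zooms.astype(np.float32)
        if sset.reference_shape is not None:
            header["dimensions"] = np.asarray(sset.reference_shape, dtype=np.int16)
        trk = TrkFile(tg, header=header)
        trk.save(str(path))
    else:
        TckFile(tg).save(str(path))


def read_tractogram(path: str | Path, fmt: str | None = None) -> StreamlineSet:
    """Read a TRK or TCK file; returns coordinates in world mm."""
    fmt = _format_for(path, fmt)
    cls = TrkFile if fmt == "trk" else TckFile
    try:
        tfile = cls.load(str(path), lazy_load=False)
    except Exception as exc:  # nibabel raises assorted header errors
        raise TractogramFormatError(f"cannot parse {path}: {exc}") from exc
    affine = np.eye(4)
    shape = None
    if fmt == "trk":
        affine = np.asarray(tfile.header.get("voxel_to_rasmm", np.eye(4)), dtype=np.float64)
        dims = tfile.header.get("dimensions")
        if dims is not None:
            shape = tuple(int(d) for d in dims)
    streamlines = [np.asarray(s, dtype=np.float64) for s in tfile.tractogram.streamlines]
    return StreamlineSet(streamlines, reference_affine=affine, reference_shape=shape)


def write_volume(vol: Volume3D, path: str | Path) -> None:
    data = vol.data
    if vol.kind in ("binary_mask", "occupancy", "label_map"):
        data = data.astype(np.int16)
    else:
        data = data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, vol.affine), str(path))


def read_volume(path: str | Path, kind: VolumeKind = "intensity") -> Volume3D:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if kind in ("binary_mask", "occupancy", "label_map"):
        data = np.rint(data).astype(np.int64)
    else:
        data = data.astype(np.float64)
    return Volume3D(data, affine=np.asarray(img.affine, dtype=np.float64), kind=kind)


# ---------------------------------------------------------------------------
# Occupancy rasterization (segment-voxel traversal)


def _traverse_segment(p0: np.ndarray, p1: np.ndarray, shape: tuple[int, int, int]):
    """Yield (i, j, k, length) for voxels crossed by one segment.

    ``p0``/``p1`` are continuous voxel coordinates shifted so voxel ``i``
    spans [i, i+1) (i.e. raw voxel coord + 0.5).  Amanatides-Woo 3-D DDA.
    Lengths are in the same units as the input coordinates.
    """
    d = p1 - p0
    seg_len = float(np.linalg.norm(d))
    shp = np.asarray(shape)
    # clip the segment to the grid box [0, shape)
    t0, t1 = 0.0, 1.0
    for ax in range(3):
        if d[ax] == 0.0:
            if p0[ax] < 0.0 or p0[ax] >= shp[ax]:
                return
            continue
        ta = (0.0 - p0[ax]) / d[ax]
        tb = (shp[ax] - 1e-12 - p0[ax]) / d[ax]
        lo, hi = (ta, tb) if ta < tb else (tb, ta)
        t0 = max(t0, lo)
        t1 = min(t1, hi)
    if t0 > t1:
        return
    a = p0 + t0 * d
    b = p0 + t1 * d
    cell = np.floor(a).astype(np.int64)
    end_cell = np.floor(b).astype(np.int64)
    cell = np.clip(cell, 0, shp - 1)
    end_cell = np.clip(end_cell, 0, shp - 1)
    if np.array_equal(cell, end_cell):
        yield int(cell[0]), int(cell[1]), int(cell[2]), seg_len * (t1 - t0)
        return
    step = np.sign(d).astype(np.int64)
    t = t0
    t_max = np.full(3, np.inf)
    t_delta = np.full(3, np.inf)
    for ax in range(3):
        if d[ax] != 0.0:
            nxt = cell[ax] + (1 if step[ax] > 0 else 0)
            t_max[ax] = (nxt - p0[ax]) / d[ax]
            t_delta[ax] = abs(1.0 / d[ax])
    for _ in range(int(np.abs(end_cell - cell).sum()) + 4):
        ax = int(np.argmin(t_max))
        t_next = min(t_max[ax], t1)
        if t_next - t > 1e-12:  # skip zero-length corner grazes
            yield int(cell[0]), int(cell[1]), int(cell[2]), seg_len * (t_next - t)
        if np.array_equal(cell, end_cell) or t_next >= t1:
            return
        t = t_max[ax]
        t_max[ax] += t_delta[ax]
        cell[ax] += step[ax]
        if cell[ax] < 0 or cell[ax] >= shp[ax]:
            return


def iter_segment_voxels(
    sset: StreamlineSet | Iterable[np.ndarray], grid: Volume3D
):
    """Yield (streamline_index, voxel ijk tuple, length_mm, unit direction).

    Segments (or parts of segments) outside the grid are skipped.
    """
    inv = np.linalg.inv(grid.affine)
    for si, pts in enumerate(sset):
        pts = np.asarray(pts, dtype=np.float64)
        vox = pts @ inv[:3, :3].T + inv[:3, 3] + 0.5
        for j in range(len(vox) - 1):
            p0, p1 = vox[j], vox[j + 1]
            d_world = pts[j + 1] - pts[j]
            norm = float(np.linalg.norm(d_world))
            if norm == 0.0:
                continue
            u = d_world / norm
            vlen = float(np.linalg.norm(p1 - p0))
            mm_per_vox = norm / vlen if vlen > 0 else 0.0
            for i, jj, kk, ln in _traverse_segment(p0, p1, grid.shape):
                yield si, (i, jj, kk), ln * mm_per_vox, u


def streamlines_to_occupancy(
    sset: StreamlineSet | Iterable[np.ndarray], grid: Volume3D
) -> Volume3D:
    """Binary occupancy map: voxel = 1 iff some streamline segment crosses it.

    Uses segment-voxel traversal (3-D DDA), not point membership, so long
    segments cannot skip voxels.  Segments outside the grid are ignored with
    a logged warning.
    """
    occ = np.zeros(grid.shape, dtype=np.int64)
    inv = np.linalg.inv(grid.affine)
    shp = np.asarray(grid.shape)
    warned = False
    for pts in sset:
        pts = np.asarray(pts, dtype=np.float64)
        vox = pts @ inv[:3, :3].T + inv[:3, 3] + 0.5
        outside = np.any((vox < 0) | (vox >= shp), axis=1)
        if np.any(outside) and not warned:
            logger.warning("streamline points outside grid ignored in occupancy")
            warned = True
        cells = np.floor(vox).astype(np.int64)
        same = np.all(cells[:-1] == cells[1:], axis=1)
        inside = ~outside
        # fast path: both endpoints in the same in-grid voxel
        fast = same & inside[:-1]
        cf = cells[:-1][fast]
        occ[cf[:, 0], cf[:, 1], cf[:, 2]] = 1
        for j in np.nonzero(~fast)[0]:
            for i, jj, kk, _ in _traverse_segment(vox[j], vox[j + 1], grid.shape):
                occ[i, jj, kk] = 1
    return Volume3D(occ, affine=grid.affine.copy(), kind="occupancy")
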