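"""Volumetric density maps: I/O, resampling, normalization, chunking, masking.

Conventions
-----------
* ``DensityMap.grid`` is stored ``[z, y, x]`` (section, row, column — the
  common single-particle convention), so ``grid[iz, iy, ix]`` sits at physical
  position ``origin + voxel_size * (ix, iy, iz)`` where ``origin`` is the
  ``(x, y, z)`` coordinate (Å) of the center of voxel ``(0, 0, 0)``.
* Files are MRC2014 / CCP4 volumes read and written through gemmi.  The
  MAPC/MAPR/MAPS axis permutation is honored on read; files are always written
  in canonical X-fastest order.
* The physical origin is taken from the ORIGIN header words when any is
  nonzero, otherwise from NSTART × voxel size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy import ndimage

from .errors import DegenerateMapError, MapFormatError, ParameterError

CHUNK_SIZE = 64
CHUNK_STRIDE = 32

__all__ = [
    "DensityMap",
    "MapChunk",
    "read_mrc",
    "write_mrc",
    "resample",
    "normalize",
    "chunk_map",
    "mask_region",
    "CHUNK_SIZE",
    "CHUNK_STRIDE",
]


@dataclass
class DensityMap:
    """A 3-D scalar density grid with physical metadata.

    Parameters
    ----------
    grid : ndarray, shape (nz, ny, nx)
        Density values, ``[z, y, x]`` storage order.
    voxel_size : float
        Edge length of a voxel in Å (isotropic; anisotropic input maps carry
        a per-axis ``spacing`` until resampled).
    origin : ndarray, shape (3,)
        Physical ``(x, y, z)`` position (Å) of the center of voxel (0, 0, 0).
    resolution : float
        Nominal resolution of the map in Å.
    contour_level : float
        Density threshold below which values are treated as background noise.
    spacing : tuple of float, optional
        Per-axis ``(sx, sy, sz)`` voxel size for anisotropic input; ``None``
        once the map is isotropic.
    """

    grid: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    resolution: float = 5.0
    contour_level: float = 0.0
    spacing: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3:
            raise ParameterError("density grid must be 3-D")
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if self.voxel_size <= 0:
            raise ParameterError("voxel_size must be positive")
        if self.resolution <= 0:
            raise ParameterError("resolution must be positive")

    # -- geometry helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # (nz, ny, nx)

    @property
    def is_anisotropic(self) -> bool:
        return self.spacing is not None

    def axis_spacing(self) -> np.ndarray:
        """Per-axis voxel size as ``(sx, sy, sz)``."""
        if self.spacing is not None:
            return np.asarray(self.spacing, dtype=np.float64)
        return np.full(3, float(self.voxel_size))

    def voxel_centers(self) -> np.ndarray:
        """Physical ``(x, y, z)`` coordinates of all voxel centers.

        Returns an array of shape ``grid.shape + (3,)``.
        """
        nz, ny, nx = self.grid.shape
        sx, sy, sz = self.axis_spacing()
        zz, yy, xx = np.meshgrid(
            self.origin[2] + sz * np.arange(nz),
            self.origin[1] + sy * np.arange(ny),
            self.origin[0] + sx * np.arange(nx),
            indexing="ij",
        )
        return np.stack([xx, yy, zz], axis=-1)

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map ``(iz, iy, ix)`` indices to physical ``(x, y, z)`` Å."""
        idx = np.atleast_2d(np.asarray(idx, dtype=np.float64))
        s = self.axis_spacing()
        xyz = np.empty_like(idx)
        xyz[:, 0] = self.origin[0] + s[0] * idx[:, 2]
        xyz[:, 1] = self.origin[1] + s[1] * idx[:, 1]
        xyz[:, 2] = self.origin[2] + s[2] * idx[:, 0]
        return xyz

    def physical_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Map physical ``(x, y, z)`` Å to fractional ``(iz, iy, ix)`` indices."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=np.float64))
        s = self.axis_spacing()
        idx = np.empty_like(xyz)
        idx[:, 0] = (xyz[:, 2] - self.origin[2]) / s[2]
        idx[:, 1] = (xyz[:, 1] - self.origin[1]) / s[1]
        idx[:, 2] = (xyz[:, 0] - self.origin[0]) / s[0]
        return idx

    def copy(self) -> "DensityMap":
        return replace(self, grid=self.grid.copy(), origin=self.origin.copy())


@dataclass
class MapChunk:
    """A 64³ sub-volume cut from a parent map on the stride-32 lattice."""

    data: np.ndarray  # (64, 64, 64), [z, y, x]
    corner_index: tuple[int, int, int]  # (iz, iy, ix) offset in the parent grid

    def __post_init__(self) -> None:
        if self.data.shape != (CHUNK_SIZE,) * 3:
            raise ParameterError(
                f"chunk data must be {CHUNK_SIZE}^3, got {self.data.shape}"
            )


# ---------------------------------------------------------------------------
# I/O


def read_mrc(path, resolution: float = 5.0, contour_level: float = 0.0) -> DensityMap:
    """Read an MRC2014/CCP4 volume (optionally gzip-compressed).

    The MAPC/MAPR/MAPS permutation in the header is applied so the returned
    grid is always ``[z, y, x]``.  Anisotropic voxels are accepted; the map is
    flagged (``spacing`` set) for later resampling.
    """
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise MapFormatError(f"cannot read MRC volume {path}: {exc}") from exc

    # normalize axis order in place (honors MAPC/MAPR/MAPS)
    ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    arr = np.array(ccp4.grid, copy=True)  # indexed [ix, iy, iz] after reorder
    if arr.ndim != 3 or arr.size == 0:
        raise MapFormatError(f"{path}: empty or non-volumetric data block")
    if np.isnan(arr).any():
        raise MapFormatError(f"{path}: data block shorter than NX*NY*NZ (truncated file)")

    cell = ccp4.grid.unit_cell
    if not (
        abs(cell.alpha - 90) < 1e-3
        and abs(cell.beta - 90) < 1e-3
        and abs(cell.gamma - 90) < 1e-3
    ):
        raise MapFormatError(
            f"{path}: non-orthogonal cell angles "
            f"({cell.alpha}, {cell.beta}, {cell.gamma}) in CELLB"
        )
    nx, ny, nz = arr.shape
    spacing = np.array([cell.a / nx, cell.b / ny, cell.c / nz])
    if np.any(spacing <= 0):
        raise MapFormatError(f"{path}: non-positive voxel size from CELLA/MX,MY,MZ")

    origin = np.array([ccp4.header_float(i) for i in (50, 51, 52)], dtype=np.float64)
    if not np.any(origin != 0):
        nstart = np.array([ccp4.header_i32(i) for i in (5, 6, 7)], dtype=np.float64)
        origin = nstart * spacing

    iso = np.allclose(spacing, spacing[0], rtol=1e-4)
    if not iso:
        warnings.warn(
            f"{path}: anisotropic voxels {tuple(np.round(spacing, 4))} Å; "
            "resample to an isotropic lattice before fitting",
            stacklevel=2,
        )
    return DensityMap(
        grid=arr.transpose(2, 1, 0),  # -> [z, y, x]
        voxel_size=float(spacing.mean()),
        origin=origin,
        resolution=resolution,
        contour_level=contour_level,
        spacing=None if iso else tuple(spacing),
    )


def write_mrc(dmap: DensityMap, path) -> None:
    """Write a map as an MRC2014 volume in canonical X-fastest axis order."""
    sx, sy, sz = dmap.axis_spacing()
    nz, ny, nx = dmap.grid.shape
    grid = gemmi.FloatGrid(nx, ny, nz)
    np.asarray(grid)[:] = dmap.grid.transpose(2, 1, 0).astype(np.float32)
    grid.set_unit_cell(gemmi.UnitCell(nx * sx, ny * sy, nz * sz, 90.0, 90.0, 90.0))
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for word, value in zip((50, 51, 52), dmap.origin):
        ccp4.set_header_float(word, float(value))
    ccp4.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# Resampling and normalization


def resample(dmap: DensityMap, target_voxel: float) -> DensityMap:
    """Trilinearly resample a map onto an isotropic ``target_voxel`` lattice.

    The new lattice starts at the same physical origin and covers (at least)
    the same physical extent.  Resampling a map to its own voxel size is the
    identity.
    """
    if target_voxel <= 0:
        raise ParameterError("target_voxel must be positive")
    spacing = dmap.axis_spacing()  # (sx, sy, sz)
    if dmap.spacing is None and abs(target_voxel - dmap.voxel_size) < 1e-12:
        return dmap.copy()

    nz, ny, nx = dmap.grid.shape
    old_n = np.array([nz, ny, nx], dtype=float)
    spacing_zyx = spacing[::-1]
    new_n = np.maximum(np.ceil(old_n * spacing_zyx / target_voxel - 1e-9), 1).astype(int)
    if np.any(new_n < 8):
        raise ParameterError(
            f"target voxel {target_voxel} Å would shrink the grid below 8 voxels "
            f"per axis (new shape {tuple(new_n)})"
        )
    # fractional old-grid indices of the new voxel centers
    axes = [np.arange(n) * target_voxel / s for n, s in zip(new_n, spacing_zyx)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    new_grid = ndimage.map_coordinates(
        dmap.grid.astype(np.float64),
        np.stack([zz, yy, xx]),
        order=1,
        mode="nearest",
    )
    return DensityMap(
        grid=new_grid.astype(np.float32),
        voxel_size=float(target_voxel),
        origin=dmap.origin.copy(),
        resolution=dmap.resolution,
        contour_level=dmap.contour_level,
    )


def normalize(dmap: DensityMap, contour_level: float | None = None) -> DensityMap:
    """Threshold at the contour level and rescale to [0, 1].

    Values below ``contour_level`` (default: the map's own, default 0) are set
    exactly to 0.  The remaining values are divided by their 98th-percentile
    value and clipped to 1, so the top ~2% of the signal saturates.  The
    percentile is computed over voxels at/above the contour only, and with the
    'higher' order statistic so the operation is exactly idempotent.
    """
    level = float(dmap.contour_level if contour_level is None else contour_level)
    if not np.isfinite(level):
        raise ParameterError("contour_level must be finite")
    grid = dmap.grid.astype(np.float64)
    # the percentile runs over the surviving signal only: values below the
    # contour become exact zeros (as does empty padding), and including that
    # background would make the scale depend on the box size
    signal = grid[(grid >= level) & (grid > 0)]
    if signal.size == 0:
        raise DegenerateMapError("all voxels below the contour level; nothing to fit")
    p98 = float(np.percentile(signal, 98, method="higher"))
    if p98 <= 0:
        raise DegenerateMapError("98th-percentile density is not positive; empty map")
    out = np.where(grid < level, 0.0, np.clip(grid / p98, 0.0, 1.0))
    if not np.any(out > 0):
        raise DegenerateMapError("map is identically zero after thresholding")
    return DensityMap(
        grid=out.astype(np.float32),
        voxel_size=dmap.voxel_size,
        origin=dmap.origin.copy(),
        resolution=dmap.resolution,
        contour_level=0.0,
        spacing=dmap.spacing,
    )


# ---------------------------------------------------------------------------
# Chunking and masking


def chunk_corners(shape: tuple[int, int, int]) -> list[tuple[int, int, int]]:
    """Corner offsets of the stride-32 chunk lattice covering ``shape``."""
    axes = [list(range(0, n, CHUNK_STRIDE)) for n in shape]
    return [(z, y, x) for z in axes[0] for y in axes[1] for x in axes[2]]


def chunk_map(dmap: DensityMap) -> list[MapChunk]:
    """Cut a map into overlapping 64³ chunks on a stride-32 voxel lattice.

    Every voxel of the parent map is covered by at least one chunk; chunks
    extending past the map boundary are zero-padded.  Chunking is defined on
    the 1 Å lattice used for segmentation (stride 32 voxels = 32 Å there).
    """
    grid = dmap.grid
    chunks = []
    for corner in chunk_corners(grid.shape):
        data = np.zeros((CHUNK_SIZE,) * 3, dtype=np.float32)
        sl_src = tuple(
            slice(c, min(c + CHUNK_SIZE, n)) for c, n in zip(corner, grid.shape)
        )
        sl_dst = tuple(slice(0, s.stop - s.start) for s in sl_src)
        data[sl_dst] = grid[sl_src]
        chunks.append(MapChunk(data=data, corner_index=corner))
    return chunks


def _sphere_offsets(radius: float, spacing: np.ndarray) -> np.ndarray:
    """Integer (dz, dy, dx) offsets whose physical length is <= radius."""
    nmax = np.floor(radius / spacing[::-1]).astype(int)  # (z, y, x)
    ranges = [np.arange(-n, n + 1) for n in nmax]
    dz, dy, dx = np.meshgrid(*ranges, indexing="ij")
    d2 = (
        (dx * spacing[0]) ** 2
        + (dy * spacing[1]) ** 2
        + (dz * spacing[2]) ** 2
    )
    keep = d2 <= radius**2 + 1e-9
    return np.stack([dz[keep], dy[keep], dx[keep]], axis=1)


def mask_region(dmap: DensityMap, coords: np.ndarray, radius: float = 3.0) -> DensityMap:
    """Zero all voxels whose center lies within ``radius`` Å of any coordinate.

    ``coords`` is an (N, 3) array of physical ``(x, y, z)`` positions —
    typically all heavy atoms of a fitted chain.  The operation is idempotent
    and never touches voxels outside the stated radius.
    """
    if radius <= 0:
        raise ParameterError("mask radius must be positive")
    coords = np.atleast_2d(np.asarray(coords, dtype=np.float64))
    out = dmap.copy()
    if coords.size == 0:
        warnings.warn("mask_region called with no coordinates; map unchanged",
                      stacklevel=2)
        return out
    spacing = dmap.axis_spacing()
    # stencil padded by half a voxel diagonal: atoms sit off voxel centers, so
    # the exact distance test below does the final trimming
    pad = 0.5 * float(np.linalg.norm(spacing))
    offsets = _sphere_offsets(radius + pad, spacing)  # (M, 3) in (dz, dy, dx)
    centers = np.round(dmap.physical_to_index(coords)).astype(int)  # (N, 3) zyx
    # candidate voxels = nearest voxel to each atom + sphere stencil, then an
    # exact physical-distance check against the generating atom
    vox = (centers[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    atom_xyz = np.repeat(coords, len(offsets), axis=0)
    shape = np.array(dmap.grid.shape)
    inb = np.all((vox >= 0) & (vox < shape), axis=1)
    vox, atom_xyz = vox[inb], atom_xyz[inb]
    ctr = dmap.index_to_physical(vox)
    d2 = np.sum((ctr - atom_xyz) ** 2, axis=1)
    hit = vox[d2 <= radius**2 + 1e-9]
    out.grid[hit[:, 0], hit[:, 1], hit[:, 2]] = 0.0
    return out
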