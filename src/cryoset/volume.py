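"""Density-map handling: MRC2014 I/O, resampling, adaptive normalization.

A cryoEM reconstruction arrives as a 3-D grid of real density values
with a voxel size in angstroms and a world-space origin.  Before a map
can feed a voxel-wise learner it is (1) resampled to a uniform target
voxel size and (2) denoised and rescaled by *adaptive contour-anchored
normalization*: instead of clipping at the fixed value 0, a per-map
threshold ``t`` is chosen so that the deposition's recommended contour
level ``c`` sits at a fixed percentile (default the 85th) of the values
that survive the clip.  Values below ``t`` are zeroed; values above are
mapped linearly onto [0, 1].

The closed form: with ``N_above`` voxels strictly above the contour and
anchor fraction ``p``, the retained-set size is ``k = round(N_above /
(1 - p))`` and ``t`` is the k-th largest voxel value; then the
nearest-rank p-percentile of the retained values equals the contour to
within one rank.  Two failure modes abort normalization for an entry:
a contour at/above the map maximum (``N_above == 0``) and a contour
below the map's own p-percentile (``k`` exceeds the voxel count).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
from scipy import ndimage

from .errors import DegenerateOutputError, MapFormatError, NormalizationError, UsageError

__all__ = [
    "DensityMap",
    "NormalizationParams",
    "read_density_map",
    "write_density_map",
    "resample",
    "derive_denoise_threshold",
    "normalize",
]


@dataclass
class DensityMap:
    """A 3-D density grid with voxel size and origin in angstroms.

    ``grid[i, j, k]`` is the density at world position
    ``origin + (i, j, k) * voxel_size`` (node convention).
    """

    grid: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3:
            raise UsageError("density grid must be 3-dimensional")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.origin = tuple(float(o) for o in self.origin)
        if any(v <= 0 for v in self.voxel_size):
            raise UsageError("voxel_size components must be positive")
        if not np.isfinite(self.grid).all():
            raise UsageError("density grid contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def world_to_index(self, pos: np.ndarray) -> np.ndarray:
        """Continuous grid index of world position(s) ``pos`` (angstrom)."""
        return (np.asarray(pos, dtype=float) - self.origin) / self.voxel_size


@dataclass(frozen=True)
class NormalizationParams:
    """Adaptive-normalization parameters for one map."""

    contour_level: float
    anchor_percentile: float  # fraction, e.g. 0.85
    threshold: float  # derived denoise threshold t
    v_max: float

    def __post_init__(self) -> None:
        if not 0.0 < self.anchor_percentile < 1.0:
            raise UsageError("anchor_percentile must lie in (0, 1)")
        if not self.threshold <= self.contour_level <= self.v_max:
            raise UsageError("invariant t <= contour <= v_max violated")


# ---------------------------------------------------------------------------
# MRC2014 I/O (gemmi handles .mrc/.map and transparent gzip)

_ORIGIN_WORDS = (50, 51, 52)
_START_WORDS = (5, 6, 7)


def read_density_map(path: str | Path) -> DensityMap:
    """Read an MRC2014 map (optionally gzipped)."""
    path = Path(path)
    if not path.exists():
        raise MapFormatError(f"no such file: {path}")
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
        ccp4.setup(float("nan"))
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"{path}: {exc}") from exc
    grid = np.array(ccp4.grid, copy=True)
    if grid.size == 0:
        raise MapFormatError(f"{path}: empty grid")
    cell = ccp4.grid.unit_cell
    nu, nv, nw = ccp4.grid.nu, ccp4.grid.nv, ccp4.grid.nw
    voxel = (cell.a / nu, cell.b / nv, cell.c / nw)
    origin = tuple(ccp4.header_float(w) for w in _ORIGIN_WORDS)
    if all(o == 0.0 for o in origin):
        # MRC fallback: nxstart/nystart/nzstart in voxel units
        origin = tuple(
            ccp4.header_i32(w) * v for w, v in zip(_START_WORDS, voxel)
        )
    if not np.isfinite(grid).all():
        raise MapFormatError(f"{path}: non-finite density values")
    return DensityMap(grid, voxel, origin)


def write_density_map(dmap: DensityMap, path: str | Path) -> None:
    """Write a map as MRC2014 with voxel size and origin in the header."""
    nx, ny, nz = dmap.shape
    grid = gemmi.FloatGrid(nx, ny, nz)
    grid.set_unit_cell(
        gemmi.UnitCell(
            nx * dmap.voxel_size[0],
            ny * dmap.voxel_size[1],
            nz * dmap.voxel_size[2],
            90.0,
            90.0,
            90.0,
        )
    )
    np.asarray(grid)[...] = dmap.grid.astype(np.float32)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for w, o in zip(_ORIGIN_WORDS, dmap.origin):
        ccp4.set_header_float(w, float(o))
    try:
        ccp4.write_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# resampling


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def resample(dmap: DensityMap, target_voxel: float, order: int = 3) -> DensityMap:
    """Resample to an isotropic *target_voxel* size (angstrom).

    Per-axis zoom factor = original voxel size / target; the output has
    ``round(dim * factor)`` nodes per axis, placed at
    ``origin + j * target`` in world space, and values interpolated with
    an order-*order* spline (edge-clamped).  The origin is preserved.
    """
    if not target_voxel > 0:
        raise UsageError("target_voxel must be positive")
    factors = [v / target_voxel for v in dmap.voxel_size]
    out_shape = tuple(_round_half_up(d * f) for d, f in zip(dmap.shape, factors))
    if any(n < 1 for n in out_shape):
        raise DegenerateOutputError(
            f"resampling {dmap.shape} by factors {factors} yields {out_shape}"
        )
    if out_shape == dmap.shape and all(abs(f - 1.0) < 1e-12 for f in factors):
        return DensityMap(dmap.grid.copy(), (target_voxel,) * 3, dmap.origin)
    # output node j sits at input index j * target / voxel
    axes = [
        np.arange(n) * target_voxel / v for n, v in zip(out_shape, dmap.voxel_size)
    ]
    coords = np.meshgrid(*axes, indexing="ij")
    out = ndimage.map_coordinates(
        dmap.grid.astype(np.float64), coords, order=order, mode="nearest"
    )
    return DensityMap(out, (target_voxel,) * 3, dmap.origin)


# ---------------------------------------------------------------------------
# adaptive contour-anchored normalization


def derive_denoise_threshold(
    dmap: DensityMap, contour: float, p: float = 0.85
) -> NormalizationParams:
    """Choose the denoise threshold anchoring *contour* at percentile *p*.

    Raises :class:`NormalizationError` when the contour leaves nothing
    above it, or when anchoring would require retaining more voxels than
    the map has (contour below the map's own p-percentile).
    """
    if not np.isfinite(contour):
        raise UsageError("contour must be finite")
    if not 0.0 < p < 1.0:
        raise UsageError("anchor percentile must lie in (0, 1)")
    values = dmap.grid.ravel()
    n_above = int((values > contour).sum())
    if n_above == 0:
        raise NormalizationError(
            f"contour {contour:g} at or above map maximum {values.max():g}"
        )
    k = _round_half_up(n_above / (1.0 - p))
    if k > values.size:
        raise NormalizationError(
            f"contour {contour:g} below the map's own {p:.0%} percentile "
            f"(would retain {k} of {values.size} voxels)"
        )
    # t = k-th largest value
    t = float(np.partition(values, values.size - k)[values.size - k])
    return NormalizationParams(
        contour_level=float(contour),
        anchor_percentile=float(p),
        threshold=t,
        v_max=float(values.max()),
    )


def normalize(dmap: DensityMap, params: NormalizationParams) -> DensityMap:
    """Zero values below the threshold, map [t, v_max] linearly to [0, 1]."""
    t, vmax = params.threshold, params.v_max
    if vmax <= t:
        raise NormalizationError("flat retained set: v_max <= threshold")
    grid = dmap.grid.astype(np.float64)
    out = np.where(grid >= t, (grid - t) / (vmax - t), 0.0)
    return DensityMap(out, dmap.voxel_size, dmap.origin)
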