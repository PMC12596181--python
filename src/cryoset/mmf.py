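"""Map-model fitness: Volume Overlap Fraction (VOF) and Dice-like scores.

Q-scores judge local resolvability but miss *global* inconsistencies -
a model covering only part of the map, or density with no model.  The
VOF score catches these cheaply: the normalized map and the voxelized
model are each projected to 2-D along six directions (the three
principal axes plus three diagonal-like orientations), every projection
is binarized at >= 1, and the per-direction intersection-over-union is
computed.  The VOF is the mean IoU over the six directions *excluding
the highest-scoring one* (dropping the most flattering view mitigates
directional bias).  A Dice-like coefficient - overlap divided by the
sum of both mask sizes, i.e. Dice without the factor of 2 - is reported
alongside, averaged over the same five directions.

Diagonal projections are exact discrete line sums: a "projection along
(1,1,0)" accumulates voxels over lines of constant ``(x - y, z)``, and
analogously for the other two diagonals, with the difference index
offset so it is non-negative.  No interpolation is involved, so an
independent brute-force loop reproduces every pixel exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import UsageError
from .metadata import CurationReport, Entry, StageRecord
from .model import AtomicModel, Atom
from .volume import DensityMap

__all__ = [
    "DIRECTIONS",
    "BinaryVolume",
    "FitnessScores",
    "voxelize_model",
    "project_volume",
    "binary_iou",
    "vof_score",
    "validate_pairs",
]

#: Fixed direction order; ties for the dropped direction resolve to the
#: first of these.
DIRECTIONS = ("X", "Y", "Z", "D_xy", "D_yz", "D_xz")

DEFAULT_RADIUS = 1.5  # angstrom, matches the default labeling radius


@dataclass
class BinaryVolume:
    """A {0,1} occupancy grid aligned to a density map's frame."""

    grid: np.ndarray
    skipped_atoms: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if not np.isin(self.grid, (0, 1)).all():
            raise UsageError("BinaryVolume values must be 0 or 1")
        self.grid = self.grid.astype(np.uint8)


@dataclass(frozen=True)
class FitnessScores:
    """Per-direction IoUs plus the derived VOF and Dice-like scores."""

    iou: dict[str, float]
    dice: dict[str, float]
    dropped_direction: str
    vof: float
    dice_like: float


def voxelize_model(
    model: AtomicModel | Sequence[Atom],
    frame: DensityMap,
    radius: float = DEFAULT_RADIUS,
    heavy_only: bool = True,
) -> BinaryVolume:
    """Occupancy volume: voxel = 1 iff its center is within *radius* of an atom.

    Voxel centers follow the frame's node convention
    (``origin + index * voxel_size``).  Atoms whose influence sphere
    misses the grid entirely are skipped and counted.
    """
    if not radius > 0:
        raise UsageError("radius must be positive")
    atoms = list(model)
    if heavy_only:
        atoms = [a for a in atoms if not a.is_hydrogen]
    grid = np.zeros(frame.shape, dtype=np.uint8)
    skipped = 0
    for atom in atoms:
        if not _stamp_sphere(grid, frame, np.asarray(atom.position), radius):
            skipped += 1
    return BinaryVolume(grid, skipped_atoms=skipped)


def _sphere_box(frame: DensityMap, center: np.ndarray, radius: float):
    """Index ranges and squared distances of voxel centers near *center*.

    Returns ``None`` when the bounding box misses the grid.
    """
    idx = frame.world_to_index(center)
    los, his, axes = [], [], []
    for d in range(3):
        r_vox = radius / frame.voxel_size[d]
        lo = int(np.ceil(idx[d] - r_vox))
        hi = int(np.floor(idx[d] + r_vox))
        lo, hi = max(lo, 0), min(hi, frame.shape[d] - 1)
        if lo > hi:
            return None
        los.append(lo)
        his.append(hi)
        axes.append(((np.arange(lo, hi + 1) - idx[d]) * frame.voxel_size[d]) ** 2)
    d2 = axes[0][:, None, None] + axes[1][None, :, None] + axes[2][None, None, :]
    return los, his, d2


def _stamp_sphere(grid, frame, center, radius) -> bool:
    box = _sphere_box(frame, center, radius)
    if box is None:
        return False
    los, his, d2 = box
    region = grid[los[0] : his[0] + 1, los[1] : his[1] + 1, los[2] : his[2] + 1]
    inside = d2 <= radius * radius
    if not inside.any():
        return False
    region[inside] = 1
    return True


def project_volume(vol: np.ndarray, direction: str) -> np.ndarray:
    """Sum a 3-D volume to 2-D along one of the six directions."""
    vol = np.asarray(vol)
    if vol.ndim != 3 or vol.size == 0:
        raise UsageError("volume must be a non-empty 3-D array")
    nx, ny, nz = vol.shape
    if direction == "X":
        return vol.sum(axis=0)
    if direction == "Y":
        return vol.sum(axis=1)
    if direction == "Z":
        return vol.sum(axis=2)
    if direction == "D_xy":
        # lines of constant (x - y, z); difference offset by ny - 1
        out = np.zeros((nx + ny - 1, nz), dtype=vol.dtype)
        for y in range(ny):
            out[ny - 1 - y : ny - 1 - y + nx, :] += vol[:, y, :]
        return out
    if direction == "D_yz":
        # lines of constant (x, y - z); difference offset by nz - 1
        out = np.zeros((nx, ny + nz - 1), dtype=vol.dtype)
        for z in range(nz):
            out[:, nz - 1 - z : nz - 1 - z + ny] += vol[:, :, z]
        return out
    if direction == "D_xz":
        # lines of constant (x - z, y); difference offset by nz - 1
        out = np.zeros((nx + nz - 1, ny), dtype=vol.dtype)
        for z in range(nz):
            out[nz - 1 - z : nz - 1 - z + nx, :] += vol[:, :, z]
        return out
    raise UsageError(f"unknown projection direction {direction!r}")


def binary_iou(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """IoU and Dice-like coefficient of two binary masks.

    Convention: two empty masks agree perfectly (both scores 1); exactly
    one empty mask scores 0 on both.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise UsageError(f"shape mismatch {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0, 1.0
    if na == 0 or nb == 0:
        return 0.0, 0.0
    inter = int((a & b).sum())
    union = na + nb - inter
    return inter / union, inter / (na + nb)


def vof_score(
    norm_map: DensityMap,
    model: AtomicModel | BinaryVolume,
    radius: float = DEFAULT_RADIUS,
) -> FitnessScores:
    """VOF and Dice-like fitness of a normalized map / model pair.

    Both the map (already normalized to [0, 1]) and the voxelized model
    are projected along all six directions; each projection is binarized
    at >= 1.  The direction with the highest IoU is dropped (first in
    the fixed order on ties); VOF is the mean of the remaining five
    IoUs and the Dice-like score the mean of the same five Dice values.
    """
    if isinstance(model, BinaryVolume):
        occ = model
    else:
        occ = voxelize_model(model, norm_map, radius=radius)
    if occ.grid.shape != norm_map.shape:
        raise UsageError("model volume shape does not match the map frame")
    ious, dices = {}, {}
    for d in DIRECTIONS:
        map_mask = project_volume(norm_map.grid.astype(np.float64), d) >= 1.0
        mod_mask = project_volume(occ.grid.astype(np.int64), d) >= 1
        ious[d], dices[d] = binary_iou(map_mask, mod_mask)
    dropped = max(DIRECTIONS, key=lambda d: ious[d])  # first wins ties
    keep = [d for d in DIRECTIONS if d != dropped]
    return FitnessScores(
        iou=ious,
        dice=dices,
        dropped_direction=dropped,
        vof=float(np.mean([ious[d] for d in keep])),
        dice_like=float(np.mean([dices[d] for d in keep])),
    )


def validate_pairs(
    pairs: Sequence[tuple[DensityMap, AtomicModel, Entry]],
    threshold: float = 0.82,
    radius: float = DEFAULT_RADIUS,
) -> tuple[list[tuple[DensityMap, AtomicModel, Entry]], CurationReport, dict[str, FitnessScores]]:
    """Keep pairs whose VOF is at least *threshold*; record all scores."""
    if not 0.0 <= threshold <= 1.0:
        raise UsageError("threshold must lie in [0, 1]")
    kept, discarded, scores = [], {}, {}
    for dmap, model, entry in pairs:
        fs = vof_score(dmap, model, radius=radius)
        scores[entry.emdb_id] = fs
        if fs.vof < threshold:
            discarded[entry.emdb_id] = f"VOF {fs.vof:.3f} < {threshold:g}"
        else:
            kept.append((dmap, model, entry))
    report = CurationReport(
        [StageRecord("mmf", len(pairs), [e.emdb_id for _, _, e in kept], discarded)]
    )
    return kept, report, scores
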