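"""Subvolume partitioning, train/val/test splitting, and dataset output.

Map and label volumes are cut into cubic patches (default 64 voxels per
side) at stride multiples, zero-padding the last patch on each axis, so
the per-axis patch count is ``ceil(dim / stride)``.  Patches are then
split into train/validation/test sets either per *entry* (no leakage of
one deposition across splits; the default) or per *subvolume*, and
serialized as one ``.npy`` file per array with a CSV manifest.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .errors import UsageError
from .labeling import LabelVolume
from .volume import DensityMap

__all__ = [
    "PartitionConfig",
    "SubvolumeRecord",
    "partition",
    "split_dataset",
    "write_dataset",
    "read_manifest",
    "stitch",
]

Split = Literal["train", "val", "test"]
_SPLITS: tuple[Split, ...] = ("train", "val", "test")


@dataclass(frozen=True)
class PartitionConfig:
    patch: int = 64  # voxels per axis
    stride: int | None = None  # defaults to patch (non-overlapping)

    def __post_init__(self) -> None:
        stride = self.patch if self.stride is None else self.stride
        if not 0 < stride <= self.patch:
            raise UsageError("require 0 < stride <= patch")
        object.__setattr__(self, "stride", stride)


@dataclass
class SubvolumeRecord:
    entry_id: str
    corner: tuple[int, int, int]
    patch: int
    split: Split | None = None
    map_patch: np.ndarray | None = None
    label_patch: np.ndarray | None = None
    map_path: str | None = None
    label_path: str | None = None


def partition(
    dmap: DensityMap,
    labels: LabelVolume,
    cfg: PartitionConfig = PartitionConfig(),
    entry_id: str = "",
) -> list[SubvolumeRecord]:
    """Cut map and label volumes into identically-placed cubic patches."""
    if dmap.shape != labels.grid.shape:
        raise UsageError("map and label shapes differ")
    stride = cfg.stride
    counts = [math.ceil(d / stride) for d in dmap.shape]
    records = []
    for ix in range(counts[0]):
        for iy in range(counts[1]):
            for iz in range(counts[2]):
                corner = (ix * stride, iy * stride, iz * stride)
                records.append(
                    SubvolumeRecord(
                        entry_id=entry_id,
                        corner=corner,
                        patch=cfg.patch,
                        map_patch=_cut(dmap.grid, corner, cfg.patch),
                        label_patch=_cut(labels.grid, corner, cfg.patch),
                    )
                )
    return records


def _cut(grid: np.ndarray, corner: tuple[int, int, int], patch: int) -> np.ndarray:
    out = np.zeros((patch,) * 3, dtype=grid.dtype)
    src = tuple(
        slice(c, min(c + patch, d)) for c, d in zip(corner, grid.shape)
    )
    block = grid[src]
    out[tuple(slice(0, s) for s in block.shape)] = block
    return out


def split_dataset(
    records: Sequence[SubvolumeRecord],
    ratios: tuple[float, float, float] = (0.8, 0.2, 0.0),
    granularity: Literal["entry", "subvolume"] = "entry",
    seed: int = 0,
) -> list[SubvolumeRecord]:
    """Assign every record to exactly one split by a seeded shuffle.

    ``entry`` granularity assigns whole depositions to one split (no
    leakage); ``subvolume`` granularity assigns patches independently.
    Realized counts follow cumulative rounding of the targets, so each
    split is within one unit of its target fraction.
    """
    if any(r < 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise UsageError("ratios must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    if granularity == "entry":
        units: list = list(dict.fromkeys(r.entry_id for r in records))
    elif granularity == "subvolume":
        units = list(range(len(records)))
    else:
        raise UsageError(f"unknown granularity {granularity!r}")
    order = list(rng.permutation(len(units)))
    assignment: dict = {}
    bounds = _cumulative_counts(len(units), ratios)
    for rank, pos in enumerate(order):
        split = _SPLITS[np.searchsorted(bounds, rank, side="right")]
        assignment[units[pos]] = split
    for i, rec in enumerate(records):
        key = rec.entry_id if granularity == "entry" else i
        rec.split = assignment[key]
    return list(records)


def _cumulative_counts(n: int, ratios: tuple[float, float, float]) -> list[int]:
    # boundaries after cumulative rounding: rank < bounds[0] -> train, etc.
    cum = np.cumsum(ratios)
    return [int(round(c * n)) for c in cum[:2]]


def write_dataset(records: Sequence[SubvolumeRecord], out_dir: str | Path) -> Path:
    """Serialize patches (one ``.npy`` per array) plus a CSV manifest."""
    out_dir = Path(out_dir)
    for split in _SPLITS:
        (out_dir / split).mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["entry_id", "cx", "cy", "cz", "patch", "split", "map_path", "label_path"])
        for rec in records:
            if rec.split is None:
                raise UsageError("records must be split before writing")
            if rec.map_patch is None or rec.label_patch is None:
                raise UsageError("records must carry arrays")
            stem = f"{rec.entry_id}_{rec.corner[0]}_{rec.corner[1]}_{rec.corner[2]}"
            map_path = out_dir / rec.split / f"{stem}_map.npy"
            label_path = out_dir / rec.split / f"{stem}_label.npy"
            np.save(map_path, np.ascontiguousarray(rec.map_patch))
            np.save(label_path, np.ascontiguousarray(rec.label_patch))
            rec.map_path = str(map_path)
            rec.label_path = str(label_path)
            w.writerow(
                [rec.entry_id, *rec.corner, rec.patch, rec.split, map_path, label_path]
            )
    return manifest


def read_manifest(manifest: str | Path, load_arrays: bool = True) -> list[SubvolumeRecord]:
    """Re-read a manifest (and optionally the arrays) written by write_dataset."""
    records = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            rec = SubvolumeRecord(
                entry_id=row["entry_id"],
                corner=(int(row["cx"]), int(row["cy"]), int(row["cz"])),
                patch=int(row["patch"]),
                split=row["split"],  # type: ignore[arg-type]
                map_path=row["map_path"],
                label_path=row["label_path"],
            )
            if load_arrays:
                rec.map_patch = np.load(rec.map_path)
                rec.label_patch = np.load(rec.label_path)
                if rec.map_patch.shape != (rec.patch,) * 3:
                    raise UsageError(f"{rec.map_path}: wrong patch shape")
            records.append(rec)
    return records


def stitch(records: Sequence[SubvolumeRecord], shape: tuple[int, int, int],
           which: Literal["map", "label"] = "map") -> np.ndarray:
    """Reassemble stride==patch records into the zero-padded original."""
    if not records:
        raise UsageError("no records to stitch")
    patch = records[0].patch
    padded = tuple(math.ceil(d / patch) * patch for d in shape)
    first = records[0].map_patch if which == "map" else records[0].label_patch
    out = np.zeros(padded, dtype=first.dtype)
    for rec in records:
        arr = rec.map_patch if which == "map" else rec.label_patch
        sl = tuple(slice(c, c + patch) for c in rec.corner)
        out[sl] = arr
    return out
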