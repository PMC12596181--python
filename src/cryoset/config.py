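"""Pipeline configuration with the pipeline's default thresholds.

Defaults mirror the curation settings the pipeline is calibrated
around: Q-score minimum 0.4, cross-reference similarity maximum 0.70,
VOF minimum 0.82, 1.0 angstrom target voxel size, 85th-percentile
contour anchoring, 1.5 angstrom labeling radius, 64-voxel patches, and
an 80:20 train/validation split.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import UsageError
from .model import SelectionRule

__all__ = ["LabelRule", "PipelineConfig"]


@dataclass(frozen=True)
class LabelRule:
    label: int
    ss: tuple[str, ...] | None = None
    residues: tuple[str, ...] | None = None
    atom_names: tuple[str, ...] | None = None

    def to_selection(self) -> SelectionRule:
        return SelectionRule.make(
            ss=list(self.ss) if self.ss else None,
            residues=self.residues,
            atom_names=self.atom_names,
        )


#: default labeling scheme: the four secondary-structure classes
DEFAULT_LABEL_RULES = (
    LabelRule(label=1, ss=("helix",)),
    LabelRule(label=2, ss=("sheet",)),
    LabelRule(label=3, ss=("coil",)),
    LabelRule(label=4, ss=("rna",)),
)


@dataclass
class PipelineConfig:
    query: str = ""
    q_score_min: float = 0.4
    similarity_max: float = 0.70
    similarity_method: str = "containment"
    vof_min: float = 0.82
    voxel_size: float = 1.0  # angstrom
    anchor_percentile: float = 0.85
    label_rules: tuple[LabelRule, ...] = DEFAULT_LABEL_RULES
    label_radius: float = 1.5  # angstrom
    patch: int = 64
    stride: int | None = None
    split_ratios: tuple[float, float, float] = (0.8, 0.2, 0.0)
    split_granularity: str = "entry"
    seed: int = 0
    workdir: str = "cryoset_work"
    data_dir: str | None = None  # local maps/models (offline) or download cache
    cache_dir: str | None = None  # metadata query cache
    offline: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.similarity_max <= 1.0:
            raise UsageError("similarity_max must lie in [0, 1]")
        if not 0.0 <= self.vof_min <= 1.0:
            raise UsageError("vof_min must lie in [0, 1]")
        if not 0.0 < self.anchor_percentile < 1.0:
            raise UsageError("anchor_percentile must lie in (0, 1)")
        if self.voxel_size <= 0 or self.label_radius <= 0 or self.patch < 1:
            raise UsageError("voxel_size, label_radius and patch must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "label_rules" in data:
            data["label_rules"] = tuple(
                LabelRule(
                    label=int(r["label"]),
                    ss=tuple(r["ss"]) if r.get("ss") else None,
                    residues=tuple(r["residues"]) if r.get("residues") else None,
                    atom_names=tuple(r["atom_names"]) if r.get("atom_names") else None,
                )
                for r in data["label_rules"]
            )
        if "split_ratios" in data:
            data["split_ratios"] = tuple(float(x) for x in data["split_ratios"])
        data.update(overrides)
        return cls(**data)
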