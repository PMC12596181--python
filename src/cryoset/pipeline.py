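"""Three-stage pipeline orchestration: fetch, curate, build.

Stage boundaries are on-disk artifacts so stages can be rerun
independently:

* ``fetch``  -> ``metadata_raw.csv``
* ``curate`` -> ``metadata_curated.csv`` + ``conditioned/<id>.mrc`` +
  curation report CSV (cleaning, Q-score, redundancy tiers,
  normalization failures, VOF validation all accounted per entry)
* ``build``  -> ``dataset/{train,val,test}`` with ``manifest.csv``

Per-entry failures (missing files, unsuccessful normalization) are
logged and tallied, never fatal to the batch.
"""

from __future__ import annotations

import logging
import shutil
import urllib.request
from pathlib import Path

from .config import PipelineConfig
from .dataset import PartitionConfig, partition, split_dataset, write_dataset
from .errors import CryosetError, StageOrderingError, UsageError
from .labeling import LabelSpec, build_label_volume
from .metadata import (
    CurationReport,
    MetadataTable,
    StageRecord,
    clean_entries,
    fetch_entries,
    filter_qscore,
    similarity_filter,
    uniqueness_filter,
)
from .mmf import DIRECTIONS, validate_pairs
from .model import parse_model
from .volume import (
    derive_denoise_threshold,
    normalize,
    read_density_map,
    resample,
    write_density_map,
)

__all__ = ["run_stage"]

log = logging.getLogger("cryoset.pipeline")

EMDB_MAP_URL = "https://ftp.ebi.ac.uk/pub/databases/emdb/structures/{emdb}/map/{emdb_lower}.map.gz"
RCSB_MODEL_URL = "https://files.rcsb.org/download/{pdb}.pdb"


def run_stage(stage: str, config: PipelineConfig) -> CurationReport:
    """Run one pipeline stage; returns the stage's curation report."""
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    if stage == "fetch":
        return _stage_fetch(config, workdir)
    if stage == "curate":
        return _stage_curate(config, workdir)
    if stage == "build":
        return _stage_build(config, workdir)
    raise UsageError(f"unknown stage {stage!r}")


def _stage_fetch(config: PipelineConfig, workdir: Path) -> CurationReport:
    table = fetch_entries(
        config.query,
        mode="offline" if config.offline else "online",
        cache_dir=config.cache_dir,
    )
    table.to_csv(workdir / "metadata_raw.csv")
    log.info("fetch: %d entries -> %s", len(table), workdir / "metadata_raw.csv")
    report = CurationReport([StageRecord("fetch", len(table), table.ids())])
    return report


def _stage_curate(config: PipelineConfig, workdir: Path) -> CurationReport:
    raw_csv = workdir / "metadata_raw.csv"
    if not raw_csv.exists():
        raise StageOrderingError("curate requires metadata_raw.csv (run fetch first)")
    table = MetadataTable.from_csv(raw_csv)
    report = CurationReport()

    table, rep = clean_entries(table)
    report.extend(rep)
    table, rep = filter_qscore(table, config.q_score_min)
    report.extend(rep)
    table, rep = uniqueness_filter(table)
    report.extend(rep)
    table, rep = similarity_filter(table, config.similarity_max, config.similarity_method)  # type: ignore[arg-type]
    report.extend(rep)

    # structural data conditioning: resample -> adaptive normalization
    cond_dir = workdir / "conditioned"
    cond_dir.mkdir(exist_ok=True)
    pairs = []
    retained, discarded = [], {}
    for entry in table:
        try:
            map_path = _locate_map(entry.emdb_id, config)
            model_path = _locate_model(entry.pdb_id, config)
            dmap = read_density_map(map_path)
            dmap = resample(dmap, config.voxel_size)
            params = derive_denoise_threshold(
                dmap, entry.contour_level, config.anchor_percentile
            )
            dmap = normalize(dmap, params)
        except CryosetError as exc:
            log.warning("curate: %s dropped: %s", entry.emdb_id, exc)
            discarded[entry.emdb_id] = f"unsuccessful normalization: {exc}"
            continue
        except FileNotFoundError as exc:
            log.warning("curate: %s dropped: %s", entry.emdb_id, exc)
            discarded[entry.emdb_id] = str(exc)
            continue
        write_density_map(dmap, cond_dir / f"{entry.emdb_id}.mrc")
        shutil.copy(model_path, cond_dir / f"{entry.emdb_id}_model{model_path.suffix}")
        pairs.append((dmap, parse_model(model_path), entry))
        retained.append(entry.emdb_id)
    report.add(
        StageRecord("conditioning", len(table), retained, discarded)
    )

    kept, rep, scores = validate_pairs(pairs, config.vof_min, config.label_radius)
    report.extend(rep)

    kept_ids = {e.emdb_id for _, _, e in kept}
    curated = MetadataTable([e for e in table if e.emdb_id in kept_ids], table.provenance)
    curated.to_csv(workdir / "metadata_curated.csv")
    with open(workdir / "vof_scores.csv", "w") as fh:
        fh.write("emdb_id," + ",".join(f"iou_{d}" for d in DIRECTIONS) + ",vof,dice_like,passed\n")
        for eid, fs in scores.items():
            ious = ",".join(f"{fs.iou[d]:.4f}" for d in DIRECTIONS)
            fh.write(f"{eid},{ious},{fs.vof:.4f},{fs.dice_like:.4f},{eid in kept_ids}\n")
    report.to_csv(workdir / "curation_report.csv")
    log.info("curate summary:\n%s", report.summary())
    return report


def _stage_build(config: PipelineConfig, workdir: Path) -> CurationReport:
    curated_csv = workdir / "metadata_curated.csv"
    cond_dir = workdir / "conditioned"
    if not curated_csv.exists() or not cond_dir.exists():
        raise StageOrderingError("build requires curate outputs (run curate first)")
    table = MetadataTable.from_csv(curated_csv)
    spec = LabelSpec(
        rules=[(r.to_selection(), r.label) for r in config.label_rules],
        radius=config.label_radius,
    )
    cfg = PartitionConfig(patch=config.patch, stride=config.stride)
    records = []
    retained, discarded = [], {}
    for entry in table:
        try:
            dmap = read_density_map(cond_dir / f"{entry.emdb_id}.mrc")
            model_path = next(cond_dir.glob(f"{entry.emdb_id}_model.*"))
            model = parse_model(model_path)
            labels = build_label_volume(model, dmap, spec)
            records.extend(partition(dmap, labels, cfg, entry_id=entry.emdb_id))
            retained.append(entry.emdb_id)
        except (CryosetError, StopIteration, FileNotFoundError) as exc:
            log.warning("build: %s dropped: %s", entry.emdb_id, exc)
            discarded[entry.emdb_id] = str(exc)
    split_dataset(
        records,
        ratios=config.split_ratios,
        granularity=config.split_granularity,  # type: ignore[arg-type]
        seed=config.seed,
    )
    write_dataset(records, workdir / "dataset")
    report = CurationReport([StageRecord("build", len(table), retained, discarded)])
    report.to_csv(workdir / "build_report.csv")
    return report


def _locate_map(emdb_id: str, config: PipelineConfig) -> Path:
    data_dir = Path(config.data_dir or config.workdir)
    for suffix in (".mrc", ".map", ".mrc.gz", ".map.gz"):
        p = data_dir / f"{emdb_id}{suffix}"
        if p.exists():
            return p
    if config.offline:
        raise FileNotFoundError(f"no local map for {emdb_id} in {data_dir}")
    num = emdb_id.split("-")[-1]
    url = EMDB_MAP_URL.format(emdb=f"EMD-{num}", emdb_lower=f"emd_{num}")
    dest = data_dir / f"{emdb_id}.map.gz"
    _download(url, dest)
    return dest


def _locate_model(pdb_id: str | None, config: PipelineConfig) -> Path:
    if not pdb_id:
        raise FileNotFoundError("entry has no fitted model")
    data_dir = Path(config.data_dir or config.workdir)
    for suffix in (".pdb", ".cif", ".ent"):
        p = data_dir / f"{pdb_id}{suffix}"
        if p.exists():
            return p
    if config.offline:
        raise FileNotFoundError(f"no local model for {pdb_id} in {data_dir}")
    dest = data_dir / f"{pdb_id}.pdb"
    _download(RCSB_MODEL_URL.format(pdb=pdb_id), dest)
    return dest


def _download(url: str, dest: Path) -> None:
    dest.parent.mkdir(parents=True, exist_ok=True)
    if dest.exists():  # resumability: completed downloads are skipped
        return
    tmp = dest.with_suffix(dest.suffix + ".part")
    with urllib.request.urlopen(url, timeout=300) as resp, open(tmp, "wb") as out:
        shutil.copyfileobj(resp, out)
    tmp.rename(dest)
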