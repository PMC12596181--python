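"""EMDB entry metadata: retrieval, cleaning, and redundancy filtering.

An :class:`Entry` is one EMDB deposition's curated metadata: accession,
title, reported resolution, the first fitted PDB model, the deposited
Q-score and recommended contour level, and the UniProtKB/AlphaFold
cross-references that serve as redundancy proxies.  A
:class:`MetadataTable` is an ordered, duplicate-free collection of
entries plus provenance; every filtering operation returns a new table
together with a :class:`CurationReport` stage whose accounting always
satisfies ``retained + discarded + flagged == input``.

Redundancy filtering is two-tier:

* :func:`uniqueness_filter` collapses groups with *identical*
  cross-reference sets to the best-resolution member and flags entries
  with no cross-references at all (kept aside for manual review);
* :func:`similarity_filter` then greedily sweeps entries in
  best-resolution-first order and discards any entry whose
  cross-reference overlap with an already-retained entry exceeds a
  threshold, so every retained pair ends up with similarity <= threshold.

"Best resolution" always means the numerically smallest value in
angstroms, with ties broken by lexicographically smallest EMDB ID.
"""

from __future__ import annotations

import csv
import json
import time
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import MetadataParseError, RetrievalError, SimilarityUndefinedError, UsageError

__all__ = [
    "Entry",
    "MetadataTable",
    "CurationReport",
    "StageRecord",
    "fetch_entries",
    "clean_entries",
    "filter_qscore",
    "xref_similarity",
    "uniqueness_filter",
    "similarity_filter",
    "pairwise_similarity_matrix",
]

SimilarityMethod = Literal["containment", "jaccard"]

EMDB_SEARCH_URL = "https://www.ebi.ac.uk/emdb/api/search/"


@dataclass(frozen=True)
class Entry:
    """Curated metadata for one EMDB deposition."""

    emdb_id: str
    title: str = ""
    resolution: float | None = None  # angstrom
    pdb_id: str | None = None
    q_score: float | None = None
    atom_inclusion: float | None = None  # percent
    contour_level: float | None = None  # map density units
    xrefs_uniprot: frozenset[str] = frozenset()
    xrefs_alphafold: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.emdb_id:
            raise UsageError("Entry requires a non-empty emdb_id")
        if self.resolution is not None and not self.resolution > 0:
            raise UsageError(f"{self.emdb_id}: resolution must be positive")

    @property
    def xrefs(self) -> frozenset[str]:
        """Merged, deduplicated UniProtKB + AlphaFold accession set."""
        return self.xrefs_uniprot | self.xrefs_alphafold


@dataclass
class MetadataTable:
    """Ordered entries with unique EMDB IDs plus retrieval provenance."""

    entries: list[Entry]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [e.emdb_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise UsageError("MetadataTable entries must have unique emdb_id")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def ids(self) -> list[str]:
        return [e.emdb_id for e in self.entries]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(_CSV_COLUMNS)
            for e in self.entries:
                w.writerow(
                    [
                        e.emdb_id,
                        e.title,
                        _fmt(e.resolution),
                        e.pdb_id or "",
                        _fmt(e.q_score),
                        _fmt(e.atom_inclusion),
                        _fmt(e.contour_level),
                        ";".join(sorted(e.xrefs_uniprot)),
                        ";".join(sorted(e.xrefs_alphafold)),
                    ]
                )

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str | None = None) -> "MetadataTable":
        entries = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            missing = set(_CSV_COLUMNS) - set(reader.fieldnames or ())
            if missing:
                raise MetadataParseError(f"{path}: missing columns {sorted(missing)}")
            for row in reader:
                entries.append(
                    Entry(
                        emdb_id=row["emdb_id"],
                        title=row["title"],
                        resolution=_parse_float(row["resolution"]),
                        pdb_id=row["pdb_id"] or None,
                        q_score=_parse_float(row["q_score"]),
                        atom_inclusion=_parse_float(row["atom_inclusion"]),
                        contour_level=_parse_float(row["contour_level"]),
                        xrefs_uniprot=_parse_set(row["xrefs_uniprot"]),
                        xrefs_alphafold=_parse_set(row["xrefs_alphafold"]),
                    )
                )
        return cls(entries, provenance or f"csv:{path}")


_CSV_COLUMNS = [
    "emdb_id",
    "title",
    "resolution",
    "pdb_id",
    "q_score",
    "atom_inclusion",
    "contour_level",
    "xrefs_uniprot",
    "xrefs_alphafold",
]


def _fmt(x: float | None) -> str:
    return "" if x is None else repr(x)


def _parse_float(s: str) -> float | None:
    s = (s or "").strip()
    if not s:
        return None
    try:
        return float(s)
    except ValueError as exc:
        raise MetadataParseError(f"bad numeric field: {s!r}") from exc


def _parse_set(s: str) -> frozenset[str]:
    return frozenset(tok for tok in (s or "").split(";") if tok)


@dataclass
class StageRecord:
    """Accounting for one filter stage."""

    name: str
    n_input: int
    retained: list[str]
    discarded: dict[str, str] = field(default_factory=dict)  # id -> reason
    flagged: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = len(self.retained) + len(self.discarded) + len(self.flagged)
        if total != self.n_input:
            raise UsageError(
                f"stage {self.name}: retained({len(self.retained)}) + "
                f"discarded({len(self.discarded)}) + flagged({len(self.flagged)}) "
                f"!= input({self.n_input})"
            )

    @property
    def n_retained(self) -> int:
        return len(self.retained)


@dataclass
class CurationReport:
    """Ordered per-stage accounting of retained / discarded / flagged entries."""

    stages: list[StageRecord] = field(default_factory=list)

    def add(self, stage: StageRecord) -> None:
        self.stages.append(stage)

    def extend(self, other: "CurationReport") -> None:
        self.stages.extend(other.stages)

    def stage(self, name: str) -> StageRecord:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(name)

    def summary(self) -> str:
        lines = [f"{'stage':<22}{'input':>8}{'kept':>8}{'discarded':>11}{'flagged':>9}"]
        for s in self.stages:
            lines.append(
                f"{s.name:<22}{s.n_input:>8}{s.n_retained:>8}"
                f"{len(s.discarded):>11}{len(s.flagged):>9}"
            )
        return "\n".join(lines)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["stage", "emdb_id", "status", "reason"])
            for s in self.stages:
                for eid in s.retained:
                    w.writerow([s.name, eid, "retained", ""])
                for eid, reason in s.discarded.items():
                    w.writerow([s.name, eid, "discarded", reason])
                for eid, reason in s.flagged.items():
                    w.writerow([s.name, eid, "flagged", reason])


# ---------------------------------------------------------------------------
# retrieval


def fetch_entries(
    query: str,
    mode: Literal["online", "offline"] = "offline",
    cache_dir: str | Path | None = None,
    max_retries: int = 3,
) -> MetadataTable:
    """Fetch EMDB entries matching *query*.

    In ``offline`` mode previously serialized JSON responses are read from
    *cache_dir*; in ``online`` mode the EMDB search API is queried over
    HTTPS (with bounded retries) and the response is cached.  When a
    record lists several fitted PDB models only the first is retained.
    """
    if not query:
        raise UsageError("query must be non-empty")
    if cache_dir is None:
        raise UsageError("cache_dir is required")
    cache_dir = Path(cache_dir)
    cache_file = cache_dir / (_slug(query) + ".json")

    if mode == "offline":
        if not cache_file.exists():
            raise RetrievalError(f"offline mode: no cached response for query {query!r}")
        raw = cache_file.read_text()
    elif mode == "online":
        raw = _http_get_with_retries(
            EMDB_SEARCH_URL + urllib.parse.quote(query) + "?rows=1000000&format=json",
            max_retries,
        )
        cache_dir.mkdir(parents=True, exist_ok=True)
        cache_file.write_text(raw)
    else:  # pragma: no cover - guarded by Literal type
        raise UsageError(f"unknown mode {mode!r}")

    try:
        records = json.loads(raw)
    except json.JSONDecodeError as exc:
        raise MetadataParseError(f"{cache_file}: malformed JSON response: {exc}") from exc
    if isinstance(records, dict):  # some API variants wrap the hit list
        records = records.get("results", records.get("entries", []))
    if not isinstance(records, list):
        raise MetadataParseError(f"{cache_file}: expected a list of records")

    entries = [_record_to_entry(rec, i) for i, rec in enumerate(records)]
    stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
    return MetadataTable(entries, provenance=f"query={query!r} mode={mode} at={stamp}")


def _slug(query: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in query)[:120]


def _http_get_with_retries(url: str, max_retries: int) -> str:
    last: Exception | None = None
    for attempt in range(max_retries):
        try:
            with urllib.request.urlopen(url, timeout=60) as resp:
                return resp.read().decode("utf-8")
        except Exception as exc:  # noqa: BLE001 - network errors are diverse
            last = exc
            time.sleep(min(2.0 * (attempt + 1), 10.0))
    raise RetrievalError(f"GET {url} failed after {max_retries} attempts: {last}")


def _record_to_entry(rec: dict, index: int) -> Entry:
    if not isinstance(rec, dict):
        raise MetadataParseError(f"record #{index}: not an object")
    try:
        emdb_id = rec["emdb_id"]
        fitted = rec.get("fitted_pdbs") or []
        if isinstance(fitted, str):
            fitted = [fitted]
        return Entry(
            emdb_id=emdb_id,
            title=rec.get("title", ""),
            resolution=_opt_float(rec.get("resolution")),
            pdb_id=fitted[0] if fitted else None,  # only the first fitted model
            q_score=_opt_float(rec.get("qscore", rec.get("q_score"))),
            atom_inclusion=_opt_float(rec.get("atom_inclusion")),
            contour_level=_opt_float(rec.get("contour_level", rec.get("recommended_contour_level"))),
            xrefs_uniprot=frozenset(rec.get("uniprot_refs", rec.get("xrefs_uniprot", []))),
            xrefs_alphafold=frozenset(rec.get("alphafold_refs", rec.get("xrefs_alphafold", []))),
        )
    except (KeyError, TypeError, ValueError, UsageError) as exc:
        raise MetadataParseError(f"record #{index}: {exc}") from exc


def _opt_float(v) -> float | None:
    return None if v is None or v == "" else float(v)


# ---------------------------------------------------------------------------
# cleaning and filtering


def _resolution_key(e: Entry) -> tuple[float, str]:
    # smallest angstrom value wins; lexicographic EMDB ID breaks ties
    res = e.resolution if e.resolution is not None else float("inf")
    return (res, e.emdb_id)


def _keep_best(group: Sequence[Entry]) -> Entry:
    return min(group, key=_resolution_key)


def clean_entries(table: MetadataTable) -> tuple[MetadataTable, CurationReport]:
    """Drop entries missing critical fields or duplicating an ID/title.

    Critical fields are the fitted PDB ID, the resolution, and the
    recommended contour level.  Among duplicate-ID or duplicate-title
    groups the best-resolution entry survives.
    """
    report = CurationReport()

    entries = list(table.entries)
    kept, discarded = [], {}
    for e in entries:
        missing = [
            name
            for name, value in (
                ("pdb_id", e.pdb_id),
                ("resolution", e.resolution),
                ("contour_level", e.contour_level),
            )
            if value is None
        ]
        if missing:
            discarded[e.emdb_id] = "missing " + ", ".join(missing)
        else:
            kept.append(e)
    report.add(StageRecord("missing-fields", len(entries), [e.emdb_id for e in kept], discarded))

    # MetadataTable construction already guarantees unique emdb_id, but a
    # table assembled from merged sources may not have passed through it.
    kept = _dedupe(kept, key=lambda e: e.emdb_id, stage="duplicate-id", report=report)
    kept = _dedupe(kept, key=lambda e: e.title, stage="duplicate-title", report=report)

    return MetadataTable(kept, table.provenance), report


def _dedupe(entries, key, stage, report) -> list[Entry]:
    groups: dict[str, list[Entry]] = {}
    for e in entries:
        groups.setdefault(key(e), []).append(e)
    winners = {id(_keep_best(g)) for g in groups.values()}
    kept, discarded = [], {}
    for e in entries:
        if id(e) in winners:
            kept.append(e)
        else:
            best = _keep_best(groups[key(e)])
            discarded[e.emdb_id] = f"{stage} (kept {best.emdb_id})"
    report.add(StageRecord(stage, len(entries), [e.emdb_id for e in kept], discarded))
    return kept


def filter_qscore(
    table: MetadataTable, threshold: float = 0.4
) -> tuple[MetadataTable, CurationReport]:
    """Discard entries with Q-score strictly below *threshold* or absent."""
    if not np.isfinite(threshold):
        raise UsageError("threshold must be finite")
    kept, discarded = [], {}
    for e in table:
        if e.q_score is None:
            discarded[e.emdb_id] = "missing Q-score"
        elif e.q_score < threshold:
            discarded[e.emdb_id] = f"Q-score {e.q_score:g} < {threshold:g}"
        else:
            kept.append(e)
    report = CurationReport(
        [StageRecord("qscore", len(table), [e.emdb_id for e in kept], discarded)]
    )
    return MetadataTable(kept, table.provenance), report


def xref_similarity(a: Entry, b: Entry, method: SimilarityMethod = "containment") -> float:
    """Proportion of shared cross-references between two entries.

    ``containment`` = |A∩B| / min(|A|,|B|); ``jaccard`` = |A∩B| / |A∪B|.
    Both are symmetric and lie in [0, 1].
    """
    return _set_similarity(a.xrefs, b.xrefs, method)


def _set_similarity(sa: frozenset, sb: frozenset, method: SimilarityMethod) -> float:
    if not sa or not sb:
        raise SimilarityUndefinedError("similarity undefined for an empty cross-reference set")
    inter = len(sa & sb)
    if method == "containment":
        return inter / min(len(sa), len(sb))
    if method == "jaccard":
        return inter / len(sa | sb)
    raise UsageError(f"unknown similarity method {method!r}")


def uniqueness_filter(table: MetadataTable) -> tuple[MetadataTable, CurationReport]:
    """First-tier redundancy filter.

    Entries without any UniProtKB/AlphaFold cross-reference are flagged
    (set aside for optional manual review).  Among entries whose merged
    cross-reference sets are identical, only the best-resolution member
    is retained.
    """
    flagged = {e.emdb_id: "no cross-references" for e in table if not e.xrefs}
    candidates = [e for e in table if e.xrefs]

    groups: dict[frozenset, list[Entry]] = {}
    for e in candidates:
        groups.setdefault(e.xrefs, []).append(e)
    winners = {id(_keep_best(g)) for g in groups.values()}

    kept, discarded = [], {}
    for e in candidates:
        if id(e) in winners:
            kept.append(e)
        else:
            best = _keep_best(groups[e.xrefs])
            discarded[e.emdb_id] = f"identical cross-references (kept {best.emdb_id})"
    report = CurationReport(
        [StageRecord("uniqueness", len(table), [e.emdb_id for e in kept], discarded, flagged)]
    )
    return MetadataTable(kept, table.provenance), report


def similarity_filter(
    table: MetadataTable,
    threshold: float = 0.70,
    method: SimilarityMethod = "containment",
) -> tuple[MetadataTable, CurationReport]:
    """Second-tier redundancy filter: greedy best-resolution-first sweep.

    Entries are visited in ascending-angstrom order; an entry is retained
    iff its cross-reference similarity to every already-retained entry is
    <= *threshold*, otherwise it is discarded in favour of the
    better-resolution representative it resembles.  Consequently every
    retained pair has similarity <= threshold.
    """
    if not 0.0 <= threshold <= 1.0:
        raise UsageError("threshold must lie in [0, 1]")
    order = sorted(table.entries, key=_resolution_key)
    retained: list[Entry] = []
    discarded: dict[str, str] = {}
    for e in order:
        clash = next(
            (r for r in retained if xref_similarity(e, r, method) > threshold), None
        )
        if clash is None:
            retained.append(e)
        else:
            sim = xref_similarity(e, clash, method)
            discarded[e.emdb_id] = f"similarity {sim:.3f} > {threshold:g} vs {clash.emdb_id}"
    retained_ids = {e.emdb_id for e in retained}
    kept = [e for e in table if e.emdb_id in retained_ids]  # original order
    report = CurationReport(
        [StageRecord("similarity", len(table), [e.emdb_id for e in kept], discarded)]
    )
    return MetadataTable(kept, table.provenance), report


def pairwise_similarity_matrix(
    sets: Iterable[Iterable[str]], method: SimilarityMethod = "containment"
) -> np.ndarray:
    """Symmetric matrix of pairwise identifier-set similarities.

    Used for dataset-redundancy assessment over e.g. InterPro domain
    identifier sets; the diagonal is 1 by definition.
    """
    frozen = [frozenset(s) for s in sets]
    n = len(frozen)
    mat = np.ones((n, n))
    for i in range(n):
        if not frozen[i]:
            raise SimilarityUndefinedError(f"set #{i} is empty")
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = _set_similarity(frozen[i], frozen[j], method)
    return mat
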