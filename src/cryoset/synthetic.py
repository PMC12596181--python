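"""Synthetic maps, models, and metadata for offline testing.

Density maps are sums of isotropic Gaussians placed on pseudo-atoms
(an ideal alpha-helix trace, a nucleic-acid ladder, or random coil)
plus optional Gaussian noise; the recommended contour level is chosen
so a known fraction of voxels exceed it.  This deliberately simplifies
cryoEM image formation (no CTF, no realistic noise spectrum), which is
adequate here because no in-scope computation depends on those
features.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import gemmi
import numpy as np

from .errors import UsageError
from .metadata import Entry, MetadataTable
from .model import AtomicModel, _from_gemmi
from .volume import DensityMap, write_density_map

__all__ = [
    "FixtureParams",
    "OverlapSpec",
    "synth_map_model",
    "synth_metadata",
    "write_fixture_set",
]

# ideal alpha-helix Calpha trace geometry
_HELIX_RADIUS = 2.3  # angstrom
_HELIX_RISE = 1.5  # angstrom per residue
_HELIX_TWIST = np.deg2rad(100.0)


@dataclass(frozen=True)
class FixtureParams:
    shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: float = 1.0  # angstrom
    layout: Literal["helix", "nucleic", "random"] = "helix"
    n_residues: int = 10
    gaussian_width: float = 1.0  # sigma, angstrom
    noise_sd: float = 0.02  # relative to unit peak amplitude
    contour_fraction: float = 0.03  # fraction of voxels above the contour
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 4 or self.voxel_size <= 0 or self.n_residues < 1:
            raise UsageError("degenerate fixture parameters")
        if not 0 < self.contour_fraction < 0.14:
            # must stay below 1 - anchor_percentile so the adaptive
            # threshold is derivable by construction
            raise UsageError("contour_fraction must lie in (0, 0.14)")


def _helix_atoms(params: FixtureParams, center: np.ndarray) -> list[tuple[str, str, np.ndarray]]:
    n = params.n_residues
    out = []
    for i in range(n):
        pos = center + np.array(
            [
                _HELIX_RADIUS * np.cos(i * _HELIX_TWIST),
                _HELIX_RADIUS * np.sin(i * _HELIX_TWIST),
                (i - (n - 1) / 2) * _HELIX_RISE,
            ]
        )
        out.append(("ALA", "CA", pos))
    return out


def _nucleic_atoms(params: FixtureParams, center: np.ndarray) -> list[tuple[str, str, np.ndarray]]:
    bases = ["A", "U", "G", "C"]
    n = params.n_residues
    out = []
    for i in range(n):
        z = (i - (n - 1) / 2) * 3.0
        res = bases[i % 4]
        out.append((res, "P", center + np.array([-2.0, 0.0, z])))
        out.append((res, "C4'", center + np.array([2.0, 0.0, z])))
    return out


def _random_atoms(params: FixtureParams, center: np.ndarray, rng) -> list[tuple[str, str, np.ndarray]]:
    extent = (np.array(params.shape) - 1) * params.voxel_size
    margin = 4.0
    lo, hi = margin, extent - margin
    if (hi <= lo).any():
        raise UsageError("box too small for the random layout margin")
    out = []
    for _ in range(params.n_residues):
        pos = rng.uniform(lo, hi)
        out.append(("ALA", "CA", pos))
    return out


def synth_map_model(params: FixtureParams) -> tuple[DensityMap, AtomicModel, float]:
    """Build a (density map, atomic model, contour level) fixture triple.

    The model's annotations are consistent with its layout: the helix
    trace carries a HELIX record spanning all residues, so the parsed
    secondary-structure classes are helix; the nucleic ladder yields
    rna; random coil yields coil.
    """
    dmap, st, contour = _synth(params)
    model = _from_gemmi(st, source=f"synthetic:{params.layout}")
    return dmap, model, contour


def _synth(params: FixtureParams) -> tuple[DensityMap, gemmi.Structure, float]:
    rng = np.random.default_rng(params.seed)
    extent = (np.array(params.shape) - 1) * params.voxel_size
    center = extent / 2.0

    if params.layout == "helix":
        atom_list = _helix_atoms(params, center)
    elif params.layout == "nucleic":
        atom_list = _nucleic_atoms(params, center)
    elif params.layout == "random":
        atom_list = _random_atoms(params, center, rng)
    else:
        raise UsageError(f"unknown layout {params.layout!r}")
    if not atom_list:
        raise UsageError("layout produced zero atoms")

    grid = _gaussian_density(params, atom_list)
    if params.noise_sd > 0:
        grid = grid + rng.normal(0.0, params.noise_sd, size=grid.shape)
    contour = float(np.quantile(grid, 1.0 - params.contour_fraction))

    st = _build_structure(params, atom_list)
    return DensityMap(grid, (params.voxel_size,) * 3), st, contour


def _gaussian_density(params: FixtureParams, atom_list) -> np.ndarray:
    grid = np.zeros(params.shape, dtype=np.float64)
    sigma = params.gaussian_width
    cutoff = 4.0 * sigma
    axes_idx = [np.arange(n) * params.voxel_size for n in params.shape]
    for _, _, pos in atom_list:
        ranges, sq = [], []
        for d in range(3):
            ax = axes_idx[d]
            lo = int(np.searchsorted(ax, pos[d] - cutoff))
            hi = int(np.searchsorted(ax, pos[d] + cutoff))
            lo, hi = max(lo, 0), min(hi, params.shape[d])
            if lo >= hi:
                break
            ranges.append(slice(lo, hi))
            sq.append((ax[lo:hi] - pos[d]) ** 2)
        else:
            d2 = sq[0][:, None, None] + sq[1][None, :, None] + sq[2][None, None, :]
            grid[tuple(ranges)] += np.exp(-d2 / (2.0 * sigma**2))
    return grid


def _build_structure(params: FixtureParams, atom_list) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "synthetic"
    st.cell = gemmi.UnitCell(*((np.array(params.shape)) * params.voxel_size), 90, 90, 90)
    mdl = gemmi.Model("1")
    chain = gemmi.Chain("A")
    resnum = 0
    last_res = None
    for resname, atom_name, pos in atom_list:
        if last_res is None or atom_name in ("CA", "P"):
            resnum += 1
            last_res = gemmi.Residue()
            last_res.name = resname
            last_res.seqid = gemmi.SeqId(resnum, " ")
            chain.add_residue(last_res)
            last_res = chain[-1]
        at = gemmi.Atom()
        at.name = atom_name
        at.element = gemmi.Element(atom_name[0])
        at.pos = gemmi.Position(*pos)
        last_res.add_atom(at)
    mdl.add_chain(chain)
    st.add_model(mdl)
    if params.layout == "helix":
        h = gemmi.Helix()
        h.start = _addr("A", 1, "ALA")
        h.end = _addr("A", resnum, "ALA")
        h.length = resnum
        st.helices.append(h)
    st.setup_entities()
    return st


def _addr(chain: str, seqnum: int, name: str) -> gemmi.AtomAddress:
    a = gemmi.AtomAddress()
    a.chain_name = chain
    a.res_id = gemmi.ResidueId()
    a.res_id.name = name
    a.res_id.seqid = gemmi.SeqId(seqnum, " ")
    return a


# ---------------------------------------------------------------------------
# metadata fixtures


@dataclass(frozen=True)
class OverlapSpec:
    """Controlled cross-reference overlap structure for synthetic tables.

    ``duplicate_groups`` are groups of entries sharing one identical
    accession set; ``subset_chains`` are nested-set chains (each next
    entry's set strictly contains the previous); ``n_disjoint`` entries
    get pairwise-disjoint singletons; ``n_empty`` entries have no
    cross-references at all.
    """

    duplicate_groups: tuple[int, ...] = ()  # sizes of identical-set groups
    subset_chains: tuple[int, ...] = ()  # lengths of nested-set chains
    n_disjoint: int = 0
    n_empty: int = 0


def synth_metadata(
    n: int | None = None,
    overlap: OverlapSpec | None = None,
    qscore_range: tuple[float, float] = (0.2, 0.6),
    seed: int = 0,
) -> MetadataTable:
    """Synthetic metadata table with controlled redundancy structure.

    When *overlap* is omitted, *n* pairwise-disjoint entries are
    generated.  Q-scores are drawn uniformly from *qscore_range*;
    resolutions uniformly from 2.5-4.0 angstrom.  Deterministic in the
    seed.
    """
    if overlap is None:
        if not n or n < 1:
            raise UsageError("n must be positive when no overlap spec is given")
        overlap = OverlapSpec(n_disjoint=n)
    rng = np.random.default_rng(seed)
    entries: list[Entry] = []
    acc = _accession_counter()

    def add(xrefs: frozenset[str]) -> None:
        i = len(entries)
        entries.append(
            Entry(
                emdb_id=f"EMD-{10000 + i}",
                title=f"synthetic particle {i}",
                resolution=float(np.round(rng.uniform(2.5, 4.0), 2)),
                pdb_id=f"{9000 + i}",
                q_score=float(np.round(rng.uniform(*qscore_range), 3)),
                contour_level=0.5,
                xrefs_uniprot=xrefs,
            )
        )

    for size in overlap.duplicate_groups:
        shared = frozenset(next(acc) for _ in range(3))
        for _ in range(size):
            add(shared)
    for length in overlap.subset_chains:
        pool = [next(acc) for _ in range(length + 1)]
        for k in range(length):
            add(frozenset(pool[: k + 2]))
    for _ in range(overlap.n_disjoint):
        add(frozenset([next(acc)]))
    for _ in range(overlap.n_empty):
        add(frozenset())
    return MetadataTable(entries, provenance=f"synthetic seed={seed}")


def _accession_counter():
    i = 0
    while True:
        yield f"U{i:05d}"
        i += 1


def write_fixture_set(
    out_dir: str | Path,
    n_entries: int = 4,
    params: FixtureParams = FixtureParams(),
    seed: int = 0,
) -> MetadataTable:
    """Write a small on-disk fixture set (MRC maps, PDB models, CSV, cache).

    Produces the inputs a full offline pipeline run needs: one map and
    model file per entry plus a metadata CSV and a JSON query cache.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    layouts = ["helix", "nucleic", "random"]
    entries = []
    records = []
    for i in range(n_entries):
        p = FixtureParams(
            shape=params.shape,
            voxel_size=params.voxel_size,
            layout=layouts[i % len(layouts)],
            n_residues=params.n_residues,
            gaussian_width=params.gaussian_width,
            noise_sd=params.noise_sd,
            contour_fraction=params.contour_fraction,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        dmap, model, contour = synth_map_model(p)
        emdb_id = f"EMD-{20000 + i}"
        pdb_id = f"{8000 + i}"
        write_density_map(dmap, out_dir / f"{emdb_id}.mrc")
        _write_pdb(p, out_dir / f"{pdb_id}.pdb")
        entry = Entry(
            emdb_id=emdb_id,
            title=f"fixture {p.layout} particle {i}",
            resolution=float(np.round(rng.uniform(2.8, 3.8), 2)),
            pdb_id=pdb_id,
            q_score=float(np.round(rng.uniform(0.3, 0.7), 3)),
            contour_level=contour,
            xrefs_uniprot=frozenset([f"U9{i:04d}"]),
        )
        entries.append(entry)
        records.append(
            {
                "emdb_id": entry.emdb_id,
                "title": entry.title,
                "resolution": entry.resolution,
                "fitted_pdbs": [entry.pdb_id],
                "qscore": entry.q_score,
                "contour_level": entry.contour_level,
                "uniprot_refs": sorted(entry.xrefs_uniprot),
            }
        )
    table = MetadataTable(entries, provenance=f"fixture_set seed={seed}")
    table.to_csv(out_dir / "metadata.csv")
    (out_dir / "fixture_query.json").write_text(json.dumps(records, indent=1))
    return table


def _write_pdb(params: FixtureParams, path: Path) -> None:
    _, st, _ = _synth(params)  # deterministic rebuild
    st.write_pdb(str(path))
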