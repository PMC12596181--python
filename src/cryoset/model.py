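"""Atomic-model parsing and three-tier atom annotation.

Each atom carries the three-tier identity used throughout labeling and
fitness scoring: a secondary-structure class (helix / sheet / coil for
protein, rna / dna for nucleic acids, other for ligands, ions and
waters), a residue name, and a PDB atom name.  Secondary structure
comes from the deposited annotations (HELIX/SHEET records in PDB,
struct_conf / struct_sheet_range in mmCIF) rather than being
recomputed; when a file carries no annotations all protein residues
default to coil.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import EmptyModelError, ModelFormatError, UsageError

__all__ = [
    "SSClass",
    "Atom",
    "AtomicModel",
    "SelectionRule",
    "parse_model",
    "assign_ss",
    "select_atoms",
]


class SSClass(str, enum.Enum):
    HELIX = "helix"
    SHEET = "sheet"
    COIL = "coil"
    RNA = "rna"
    DNA = "dna"
    OTHER = "other"


_RNA_RESIDUES = {"A", "U", "G", "C"}
_DNA_RESIDUES = {"DA", "DT", "DG", "DC"}


def _is_amino_acid(resname: str) -> bool:
    info = gemmi.find_tabulated_residue(resname)
    return bool(info and info.is_amino_acid())


@dataclass(frozen=True)
class Atom:
    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: tuple[float, float, float]
    ss_class: SSClass = SSClass.OTHER
    file_order: int = 0

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class AtomicModel:
    """Ordered atom records; order equals file order (tie-break contract)."""

    atoms: list[Atom]
    chains: list[str] = field(default_factory=list)
    source: str = ""
    _helix_ranges: list[tuple[str, int, int]] = field(default_factory=list, repr=False)
    _sheet_ranges: list[tuple[str, int, int]] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        orders = [a.file_order for a in self.atoms]
        if any(b <= a for a, b in zip(orders, orders[1:])):
            raise UsageError("atoms must be in strictly increasing file order")
        if not self.chains:
            seen: list[str] = []
            for a in self.atoms:
                if a.chain_id not in seen:
                    seen.append(a.chain_id)
            self.chains = seen

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def positions(self, atoms: Sequence[Atom] | None = None) -> np.ndarray:
        src = self.atoms if atoms is None else atoms
        return np.array([a.position for a in src], dtype=float).reshape(-1, 3)


def parse_model(path: str | Path) -> AtomicModel:
    """Parse a PDB or mmCIF file into an :class:`AtomicModel`.

    Only the first model of multi-model files and the first alternate
    location of each atom are kept; hydrogens are retained (selection
    rules can drop them later).
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ModelFormatError(f"{path}: {exc}") from exc
    st.setup_entities()
    return _from_gemmi(st, source=str(path))


def _from_gemmi(st: gemmi.Structure, source: str = "") -> AtomicModel:
    if len(st) == 0:
        raise EmptyModelError(f"{source or st.name}: no models")
    model = st[0]
    atoms: list[Atom] = []
    order = 0
    for chain in model:
        for res in chain:
            for atom in res:
                if atom.altloc not in ("", "\0", "A"):
                    continue  # first altloc only
                atoms.append(
                    Atom(
                        chain_id=chain.name,
                        residue_number=res.seqid.num,
                        residue_name=res.name,
                        atom_name=atom.name,
                        element=atom.element.name,
                        position=(atom.pos.x, atom.pos.y, atom.pos.z),
                        file_order=order,
                    )
                )
                order += 1
    if not atoms:
        raise EmptyModelError(f"{source or st.name}: zero atoms")
    helices = [
        (h.start.chain_name, h.start.res_id.seqid.num, h.end.res_id.seqid.num)
        for h in st.helices
    ]
    sheets = [
        (s.start.chain_name, s.start.res_id.seqid.num, s.end.res_id.seqid.num)
        for sheet in st.sheets
        for s in sheet.strands
    ]
    return assign_ss(
        AtomicModel(atoms, source=source, _helix_ranges=helices, _sheet_ranges=sheets)
    )


def assign_ss(model: AtomicModel) -> AtomicModel:
    """Assign every atom exactly one secondary-structure class.

    Protein residues inside deposited helix/sheet ranges become helix or
    sheet, remaining amino acids coil; A/U/G/C residues are rna and
    DA/DT/DG/DC dna; everything else (ligands, ions, waters) is other.
    """

    def in_ranges(a: Atom, ranges: Iterable[tuple[str, int, int]]) -> bool:
        return any(
            a.chain_id == ch and lo <= a.residue_number <= hi for ch, lo, hi in ranges
        )

    annotated = []
    for a in model.atoms:
        if a.residue_name in _RNA_RESIDUES:
            ss = SSClass.RNA
        elif a.residue_name in _DNA_RESIDUES:
            ss = SSClass.DNA
        elif _is_amino_acid(a.residue_name):
            if in_ranges(a, model._helix_ranges):
                ss = SSClass.HELIX
            elif in_ranges(a, model._sheet_ranges):
                ss = SSClass.SHEET
            else:
                ss = SSClass.COIL
        else:
            ss = SSClass.OTHER
        annotated.append(replace(a, ss_class=ss))
    return AtomicModel(
        annotated,
        chains=list(model.chains),
        source=model.source,
        _helix_ranges=model._helix_ranges,
        _sheet_ranges=model._sheet_ranges,
    )


@dataclass(frozen=True)
class SelectionRule:
    """Three-tier atom selection: secondary structure, residue, atom name.

    Each tier is either ``None`` (unconstrained) or a set of accepted
    values; an atom matches iff it satisfies every specified tier.  The
    special ss value ``"none"`` selects only atoms outside the
    polymer classes (``ss_class == other``) — the ligand path.
    """

    ss: frozenset[SSClass] | None = None
    residues: frozenset[str] | None = None
    atom_names: frozenset[str] | None = None
    include_hydrogens: bool = True

    @classmethod
    def make(
        cls,
        ss: Iterable[str] | str | None = None,
        residues: Iterable[str] | None = None,
        atom_names: Iterable[str] | None = None,
        include_hydrogens: bool = True,
    ) -> "SelectionRule":
        if isinstance(ss, str):
            ss = [ss]
        if ss is not None:
            classes = frozenset(
                SSClass.OTHER if s == "none" else SSClass(s) for s in ss
            )
        else:
            classes = None
        return cls(
            ss=classes,
            residues=None if residues is None else frozenset(residues),
            atom_names=None if atom_names is None else frozenset(atom_names),
            include_hydrogens=include_hydrogens,
        )

    def matches(self, atom: Atom) -> bool:
        if not self.include_hydrogens and atom.is_hydrogen:
            return False
        if self.ss is not None and atom.ss_class not in self.ss:
            return False
        if self.residues is not None and atom.residue_name not in self.residues:
            return False
        if self.atom_names is not None and atom.atom_name not in self.atom_names:
            return False
        return True


def select_atoms(model: AtomicModel, rule: SelectionRule) -> list[Atom]:
    """Atoms matching every specified tier of *rule*, in file order."""
    return [a for a in model.atoms if rule.matches(a)]
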