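"""Macromolecular structure model and mmCIF/PDB input/output.

The in-memory model is a small chain -> residue -> atom hierarchy that keeps
*author* residue numbering throughout, because that is the numbering used in
the structural literature this package serves (domain boundaries such as
"NBD, residues 102-262", mutations such as M96C).  Parsing and serialization
are delegated to :mod:`gemmi`; this module owns altloc resolution, water and
hydrogen filtering, van der Waals radius assignment and the selection algebra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence

import gemmi
import numpy as np
import yaml

__all__ = [
    "Atom",
    "Residue",
    "Cell",
    "Structure",
    "AtomSelection",
    "SelectedAtom",
    "DomainEntry",
    "DomainMap",
    "StructureError",
    "FormatError",
    "SelectionError",
    "VDW_RADII",
    "DEFAULT_VDW_RADIUS",
    "read_structure",
    "write_structure",
    "select_atoms",
    "get_cell",
]


class StructureError(Exception):
    """Base class for structural model errors."""


class FormatError(StructureError):
    """File could not be parsed or serialized under the requested dialect."""


class SelectionError(StructureError):
    """An atom selection could not be resolved against a structure."""


#: Bondi-style van der Waals radii (Angstrom) used for SASA and contacts.
#: Fixed here so that area calculations are reproducible across installs.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
}
DEFAULT_VDW_RADIUS: float = 1.70

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


def vdw_radius(element: str) -> float:
    """Van der Waals radius for an element symbol; warns and falls back for
    unknown elements."""
    el = element.strip().upper()
    if el in VDW_RADII:
        return VDW_RADII[el]
    warnings.warn(
        f"unknown element {element!r}: using default vdW radius "
        f"{DEFAULT_VDW_RADIUS} A",
        stacklevel=2,
    )
    return DEFAULT_VDW_RADIUS


@dataclass
class Atom:
    """A single atom with coordinates in Angstrom."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False
    vdw_radius: float = DEFAULT_VDW_RADIUS

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(
                f"atom {self.name}: coordinates must be a finite 3-vector"
            )
        if self.vdw_radius <= 0:
            raise StructureError(f"atom {self.name}: vdw_radius must be > 0")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"atom {self.name}: occupancy outside [0, 1]")


@dataclass
class Residue:
    """A residue identified by its author number (+ insertion code)."""

    auth_number: int
    name: str
    atoms: list[Atom]
    insertion_code: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError(
                f"residue {self.name} {self.auth_number}: needs at least one atom"
            )
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise StructureError(
                f"residue {self.name} {self.auth_number}: duplicate atom names "
                "after altloc resolution"
            )

    @property
    def label(self) -> str:
        return f"{self.name} {self.auth_number}{self.insertion_code}"

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_water(self) -> bool:
        return self.name in _WATER_NAMES


@dataclass
class Cell:
    """Crystallographic unit cell (lengths in Angstrom, angles in degrees)."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    space_group: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise StructureError("cell lengths must be positive")


@dataclass
class Structure:
    """Chain-ordered hierarchy of residues and atoms.

    ``chains`` maps chain id to the residue list in file order.  Hetero
    residues (ligands) stay in their chain but are tagged; waters are dropped
    on load unless requested.
    """

    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    cell: Optional[Cell] = None

    def __post_init__(self) -> None:
        if len(self.chains) != len(set(self.chains)):
            raise StructureError("chain ids must be unique")

    # -- census ------------------------------------------------------------

    def polymer_chain_ids(self) -> list[str]:
        """Chains containing at least one non-hetero residue."""
        return [
            cid
            for cid, residues in self.chains.items()
            if any(not r.is_hetero for r in residues)
        ]

    @property
    def ligands(self) -> list[tuple[str, Residue]]:
        """Hetero, non-water residues with their chain id."""
        out = []
        for cid, residues in self.chains.items():
            for res in residues:
                if res.is_hetero and not res.is_water:
                    out.append((cid, res))
        return out

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for rs in self.chains.values() for r in rs)

    def n_residues(self, polymer_only: bool = True) -> int:
        return sum(
            1
            for rs in self.chains.values()
            for r in rs
            if not (polymer_only and r.is_hetero)
        )

    # -- access ------------------------------------------------------------

    def get_residue(
        self, chain_id: str, auth_number: int, insertion_code: str = ""
    ) -> Residue:
        if chain_id not in self.chains:
            raise SelectionError(f"no such chain {chain_id!r}")
        for res in self.chains[chain_id]:
            if res.auth_number == auth_number and res.insertion_code == insertion_code:
                return res
        raise SelectionError(
            f"residue {auth_number}{insertion_code} not found in chain {chain_id}"
        )

    def iter_atoms(self) -> Iterator[tuple[str, Residue, Atom]]:
        for cid, residues in self.chains.items():
            for res in residues:
                for atom in res.atoms:
                    yield cid, res, atom


class SelectedAtom(NamedTuple):
    """An atom together with its chain and residue context."""

    chain_id: str
    residue: Residue
    atom: Atom


@dataclass
class AtomSelection:
    """Declarative atom subset: chain, author-numbered range and atom names.

    ``residue_range`` is inclusive on both ends (author numbering); an
    explicit ``residues`` list may be given instead.  ``atom_names`` of None
    means all atoms.  Hetero residues are excluded unless ``include_hetero``.
    """

    chain_id: Optional[str] = None
    residue_range: Optional[tuple[int, int]] = None
    residues: Optional[Sequence[int]] = None
    atom_names: Optional[Sequence[str]] = None
    include_hetero: bool = False

    def __post_init__(self) -> None:
        if self.residue_range is not None:
            start, end = self.residue_range
            if start > end:
                raise SelectionError(
                    f"residue range start {start} exceeds end {end}"
                )
        if self.residue_range is not None and self.residues is not None:
            raise SelectionError("give residue_range or residues, not both")

    def matches_residue(self, res: Residue) -> bool:
        if res.is_hetero and not self.include_hetero:
            return False
        if self.residue_range is not None:
            start, end = self.residue_range
            if not start <= res.auth_number <= end:
                return False
        if self.residues is not None and res.auth_number not in self.residues:
            return False
        return True

    def matches_atom(self, atom: Atom) -> bool:
        return self.atom_names is None or atom.name in set(self.atom_names)


def select_atoms(structure: Structure, selection: AtomSelection) -> list[SelectedAtom]:
    """Resolve a selection to an ordered atom list.

    Order is deterministic: chain order, then residue file order, then atom
    record order.  An empty result is valid; a missing chain is an error so
    that "no such chain" is never silently confused with "empty range".
    """
    if selection.chain_id is not None and selection.chain_id not in structure.chains:
        raise SelectionError(
            f"no such chain {selection.chain_id!r} "
            f"(present: {sorted(structure.chains)})"
        )
    out: list[SelectedAtom] = []
    for cid, residues in structure.chains.items():
        if selection.chain_id is not None and cid != selection.chain_id:
            continue
        for res in residues:
            if not selection.matches_residue(res):
                continue
            for atom in res.atoms:
                if selection.matches_atom(atom):
                    out.append(SelectedAtom(cid, res, atom))
    return out


def selection_coords(atoms: Iterable[SelectedAtom]) -> np.ndarray:
    """Coordinates of selected atoms as an (N, 3) array."""
    return np.array([sa.atom.coords for sa in atoms], dtype=float).reshape(-1, 3)


# ---------------------------------------------------------------------------
# Domain maps


@dataclass
class DomainEntry:
    name: str
    chain_id: str
    start: int
    end: int
    atoms: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise SelectionError(
                f"domain {self.name}: start {self.start} exceeds end {self.end}"
            )

    def selection(self, atom_names: Optional[Sequence[str]] = None) -> AtomSelection:
        return AtomSelection(
            chain_id=self.chain_id,
            residue_range=(self.start, self.end),
            atom_names=atom_names if atom_names is not None else self.atoms,
        )


@dataclass
class DomainMap:
    """Named residue ranges per chain, e.g. the NOD subdomain boundaries."""

    entries: list[DomainEntry]

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            key = (e.chain_id, e.name)
            if key in seen:
                raise StructureError(
                    f"duplicate domain name {e.name!r} on chain {e.chain_id}"
                )
            seen.add(key)

    def get(self, name: str, chain_id: Optional[str] = None) -> DomainEntry:
        for e in self.entries:
            if e.name == name and (chain_id is None or e.chain_id == chain_id):
                return e
        raise SelectionError(f"no domain named {name!r}")

    def overlapping_pairs(self) -> list[tuple[str, str]]:
        """Pairs of same-chain domains with overlapping ranges (flagged,
        not forbidden: some annotations legitimately overlap)."""
        out = []
        for i, a in enumerate(self.entries):
            for b in self.entries[i + 1 :]:
                if a.chain_id == b.chain_id and a.start <= b.end and b.start <= a.end:
                    out.append((a.name, b.name))
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DomainMap":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dicts(raw["domains"] if isinstance(raw, dict) else raw)

    @classmethod
    def from_dicts(cls, dicts: Sequence[dict]) -> "DomainMap":
        return cls(
            [
                DomainEntry(
                    name=d["name"],
                    chain_id=d["chain"],
                    start=int(d["start"]),
                    end=int(d["end"]),
                    atoms=d.get("atoms"),
                )
                for d in dicts
            ]
        )


# ---------------------------------------------------------------------------
# Reading


def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """One atom per name: highest occupancy wins, ties break alphabetically
    by altloc id."""
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
            continue
        if atom.occ > prev.occ or (atom.occ == prev.occ and atom.altloc < prev.altloc):
            best[atom.name] = atom
    # preserve record order of the winners
    winners = set(map(id, best.values()))
    return [a for a in res if id(a) in winners]


def _coor_format(path: Path, format: str) -> gemmi.CoorFormat:
    if format == "auto":
        suffix = path.suffix.lower()
        if suffix in {".cif", ".mmcif"}:
            return gemmi.CoorFormat.Mmcif
        if suffix in {".pdb", ".ent"}:
            return gemmi.CoorFormat.Pdb
        return gemmi.CoorFormat.Detect
    if format.lower() in {"mmcif", "cif"}:
        return gemmi.CoorFormat.Mmcif
    if format.lower() == "pdb":
        return gemmi.CoorFormat.Pdb
    raise FormatError(f"unknown structure format {format!r}")


def read_structure(
    path: str | Path,
    format: str = "auto",
    keep_waters: bool = False,
) -> Structure:
    """Read an mmCIF or PDB file into a :class:`Structure`.

    Only the first model of multi-model files is kept.  Hydrogens are
    discarded (every analysis in this package is heavy-atom based), waters are
    discarded unless ``keep_waters``, and alternate locations are resolved to
    a single conformer (highest occupancy, alphabetical tie-break).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        gst = gemmi.read_structure(str(path), format=_coor_format(path, format))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    gst.setup_entities()

    if len(gst) == 0:
        raise FormatError(f"{path}: no models found")
    model = gst[0]

    chains: dict[str, list[Residue]] = {}
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            if gres.is_water() and not keep_waters:
                continue
            is_het = gres.het_flag == "H"
            atoms = []
            for gatom in _resolve_altlocs(gres):
                element = gatom.element.name if gatom.element else ""
                if element.upper() in {"H", "D"}:
                    continue
                atoms.append(
                    Atom(
                        name=gatom.name,
                        element=element,
                        coords=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                        occupancy=float(min(max(gatom.occ, 0.0), 1.0)),
                        b_factor=float(gatom.b_iso),
                        is_hetero=is_het,
                        vdw_radius=vdw_radius(element),
                    )
                )
            if atoms:
                residues.append(
                    Residue(
                        auth_number=gres.seqid.num,
                        name=gres.name,
                        atoms=atoms,
                        insertion_code=(gres.seqid.icode or "").strip(),
                        is_hetero=is_het,
                    )
                )
        if residues:
            chains.setdefault(gchain.name, []).extend(residues)

    cell = None
    gcell = gst.cell
    if gcell and not _is_placeholder_cell(gcell):
        cell = Cell(
            a=gcell.a,
            b=gcell.b,
            c=gcell.c,
            alpha=gcell.alpha,
            beta=gcell.beta,
            gamma=gcell.gamma,
            space_group=gst.spacegroup_hm or "",
        )

    return Structure(id=gst.name or path.stem, chains=chains, cell=cell)


def _is_placeholder_cell(cell: gemmi.UnitCell) -> bool:
    # gemmi reports 1,1,1,90,90,90 when the file carries no cell
    return (
        abs(cell.a - 1.0) < 1e-6
        and abs(cell.b - 1.0) < 1e-6
        and abs(cell.c - 1.0) < 1e-6
    )


def get_cell(structure: Structure) -> Optional[Cell]:
    """Unit cell and space group, or None when not crystallographic."""
    return structure.cell


# ---------------------------------------------------------------------------
# Writing

_PDB_MAX_SERIAL = 99999
_PDB_MAX_RESSEQ = 9999


def write_structure(structure: Structure, path: str | Path, format: str = "auto") -> Path:
    """Serialize a structure to PDB or mmCIF (coordinates at 3 decimals).

    Structures exceeding the fixed-column capacity of the PDB format (100k
    atoms, residue numbers above 9999) are refused with advice to use mmCIF.
    """
    path = Path(path)
    fmt = _coor_format(path, format)
    if fmt == gemmi.CoorFormat.Detect:
        raise FormatError(f"cannot infer format from suffix of {path}")
    if structure.n_atoms() == 0:
        raise StructureError("refusing to write a structure with no atoms")

    if fmt == gemmi.CoorFormat.Pdb:
        if structure.n_atoms() > _PDB_MAX_SERIAL:
            raise FormatError(
                f"{structure.n_atoms()} atoms exceed the PDB serial-number "
                "columns; write mmCIF instead"
            )
        max_num = max(
            r.auth_number for rs in structure.chains.values() for r in rs
        )
        if max_num > _PDB_MAX_RESSEQ:
            raise FormatError(
                f"residue number {max_num} exceeds PDB columns; write mmCIF instead"
            )

    gst = _to_gemmi(structure)
    if fmt == gemmi.CoorFormat.Pdb:
        gst.write_pdb(str(path))
    else:
        gst.make_mmcif_document().write_file(str(path))
    return path


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    gst = gemmi.Structure()
    gst.name = structure.id
    if structure.cell is not None:
        c = structure.cell
        gst.cell = gemmi.UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
        gst.spacegroup_hm = c.space_group
    model = gemmi.Model("1")
    for cid, residues in structure.chains.items():
        gchain = gemmi.Chain(cid)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.auth_number, res.insertion_code or " ")
            gres.het_flag = "H" if res.is_hetero else "A"
            for atom in res.atoms:
                gatom = gemmi.Atom()
                gatom.name = atom.name
                gatom.element = gemmi.Element(atom.element or "C")
                gatom.pos = gemmi.Position(*np.round(atom.coords, 3))
                gatom.occ = atom.occupancy
                gatom.b_iso = atom.b_factor
                gres.add_atom(gatom)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    gst.add_model(model)
    gst.setup_entities()
    return gst
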