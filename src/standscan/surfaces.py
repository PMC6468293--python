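"""Solvent-accessible surface areas, buried interfaces and residue contacts.

SASA follows the Shrake-Rupley construction: each atom is inflated by the
probe radius and sampled with a deterministic Fibonacci sphere lattice; the
accessible area is the fraction of sample points not occluded by any
neighbouring inflated sphere, times the sphere area.  The buried interface
area between two atom sets A and B is the standard half-sum convention

    buried(A, B) = (SASA(A alone) + SASA(B alone) - SASA(A+B)) / 2

computed by default on the isolated pair (the two sets extracted from the
rest of the structure), which matches per-domain-pair interface accounting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import (
    Atom,
    AtomSelection,
    SelectedAtom,
    SelectionError,
    Structure,
    StructureError,
    select_atoms,
)

__all__ = [
    "SASAResult",
    "Contact",
    "InterfaceReport",
    "shrake_rupley",
    "buried_interface_area",
    "find_contacts",
    "DEFAULT_PROBE_RADIUS",
    "DEFAULT_N_POINTS",
    "HBOND_CUTOFF",
]

#: water-probe radius (Angstrom) and sphere sample count defaults
DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_POINTS = 960
#: any N/O-N/O pair at or below this distance is classed as hydrogen-bonding
HBOND_CUTOFF = 3.5


@dataclass
class SASAResult:
    """Per-atom and total solvent-accessible areas (Angstrom^2)."""

    per_atom: np.ndarray  # area per input atom, same order
    total: float
    probe_radius: float
    n_points: int


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere lattice (golden-angle spiral).

    No randomized offset: the lattice is fixed so areas are bit-reproducible.
    """
    i = np.arange(n, dtype=float)
    # offset by 0.5 keeps points away from the poles
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = np.pi * (1.0 + 5.0**0.5) * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _atom_arrays(atoms: Sequence) -> tuple[np.ndarray, np.ndarray]:
    coords = []
    radii = []
    for a in atoms:
        atom = a.atom if isinstance(a, SelectedAtom) else a
        coords.append(atom.coords)
        radii.append(atom.vdw_radius)
    return np.asarray(coords, dtype=float), np.asarray(radii, dtype=float)


def shrake_rupley(
    atoms: Sequence[Atom | SelectedAtom],
    probe: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> SASAResult:
    """Shrake-Rupley SASA of an atom list.

    ``atoms`` may be bare :class:`Atom` objects or :class:`SelectedAtom`
    tuples; van der Waals radii are taken from the atoms themselves.
    """
    if len(atoms) == 0:
        raise StructureError("SASA of an empty atom list is undefined")
    if probe < 0:
        raise StructureError("probe radius must be >= 0")
    if n_points < 16:
        raise StructureError("need at least 16 sphere sample points")

    coords, radii = _atom_arrays(atoms)
    if not np.all(np.isfinite(coords)):
        raise StructureError("non-finite coordinates in SASA input")
    inflated = radii + probe

    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    r_max = inflated.max()
    per_atom = np.empty(len(atoms), dtype=float)

    for i in range(len(atoms)):
        ri = inflated[i]
        pts = coords[i] + ri * sphere
        neighbors = [
            j
            for j in tree.query_ball_point(coords[i], ri + r_max)
            if j != i
            and np.linalg.norm(coords[j] - coords[i]) < ri + inflated[j]
        ]
        if neighbors:
            accessible = np.ones(n_points, dtype=bool)
            for j in neighbors:
                d2 = ((pts - coords[j]) ** 2).sum(axis=1)
                accessible &= d2 > inflated[j] ** 2
            frac = accessible.mean()
        else:
            frac = 1.0
        per_atom[i] = frac * 4.0 * np.pi * ri * ri

    return SASAResult(
        per_atom=per_atom,
        # exactly rounded sum: the total is then independent of atom order,
        # which makes buried(A, B) == buried(B, A) bit-exact
        total=math.fsum(per_atom),
        probe_radius=probe,
        n_points=n_points,
    )


def buried_interface_area(
    structure: Structure,
    sel_a: AtomSelection,
    sel_b: AtomSelection,
    probe: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    context: str = "isolated-pair",
) -> float:
    """Buried surface area between two disjoint selections (Angstrom^2).

    ``context='isolated-pair'`` (default) extracts the two selections from
    the structure and evaluates the pair in isolation.  In
    ``context='full-structure'`` the monomer terms are computed with each
    partner's atoms removed from the full structure instead (a delta-SASA
    convention); the pairwise default matches per-domain-pair bookkeeping.
    """
    atoms_a = select_atoms(structure, sel_a)
    atoms_b = select_atoms(structure, sel_b)
    if not atoms_a or not atoms_b:
        raise SelectionError("interface selections must each resolve to >= 1 atom")
    ids_a = {id(sa.atom) for sa in atoms_a}
    if any(id(sa.atom) in ids_a for sa in atoms_b):
        raise SelectionError("interface selections overlap at the atom level")
    if context not in ("isolated-pair", "full-structure"):
        raise ValueError(f"unknown interface context {context!r}")

    if context == "isolated-pair":
        sasa_a = shrake_rupley(atoms_a, probe, n_points).total
        sasa_b = shrake_rupley(atoms_b, probe, n_points).total
        sasa_ab = shrake_rupley(list(atoms_a) + list(atoms_b), probe, n_points).total
    else:
        everything = [sa for sa in structure.iter_atoms()]
        all_atoms = [SelectedAtom(c, r, a) for c, r, a in everything]
        ids_b = {id(sa.atom) for sa in atoms_b}
        without_b = [sa for sa in all_atoms if id(sa.atom) not in ids_b]
        without_a = [sa for sa in all_atoms if id(sa.atom) not in ids_a]
        res_no_b = shrake_rupley(without_b, probe, n_points)
        res_no_a = shrake_rupley(without_a, probe, n_points)
        res_full = shrake_rupley(all_atoms, probe, n_points)
        idx_a = [k for k, sa in enumerate(without_b) if id(sa.atom) in ids_a]
        idx_b = [k for k, sa in enumerate(without_a) if id(sa.atom) in ids_b]
        idx_full_a = [k for k, sa in enumerate(all_atoms) if id(sa.atom) in ids_a]
        idx_full_b = [k for k, sa in enumerate(all_atoms) if id(sa.atom) in ids_b]
        sasa_a = float(res_no_b.per_atom[idx_a].sum())
        sasa_b = float(res_no_a.per_atom[idx_b].sum())
        sasa_ab = float(
            res_full.per_atom[idx_full_a].sum() + res_full.per_atom[idx_full_b].sum()
        )

    return max(0.0, (sasa_a + sasa_b - sasa_ab) / 2.0)


@dataclass
class Contact:
    """Closest-approach record between two residues."""

    chain_a: str
    residue_a: int
    resname_a: str
    chain_b: str
    residue_b: int
    resname_b: str
    min_distance: float
    contact_class: str  # "hbond" | "vdw"


@dataclass
class InterfaceReport:
    """Buried area plus classified residue contacts for a domain pair."""

    name: str
    buried_area: float
    contacts: list[Contact]
    probe_radius: float
    cutoff: float
    context: str = "isolated-pair"
    area_convention: str = "(SASA_A + SASA_B - SASA_AB) / 2"

    def contact_residues_b(self) -> list[int]:
        return sorted({c.residue_b for c in self.contacts})

    def contact_residues_a(self) -> list[int]:
        return sorted({c.residue_a for c in self.contacts})


_POLAR_ELEMENTS = {"N", "O"}


def find_contacts(
    structure: Structure,
    sel_a: AtomSelection,
    sel_b: AtomSelection,
    cutoff: float = 4.0,
) -> list[Contact]:
    """Residue pairs across two selections within a heavy-atom cutoff.

    A pair is classed ``hbond`` when its closest N/O-N/O atom pair is within
    :data:`HBOND_CUTOFF` (donor/acceptor chemistry is deliberately not
    inferred: at moderate resolution with no hydrogens, N/O proximity is the
    operative criterion), else ``vdw``.  Sorted by (chain, residue) of both
    partners.  The KD-tree pruning is exact: output equals the all-pairs scan.
    """
    atoms_a = select_atoms(structure, sel_a)
    atoms_b = select_atoms(structure, sel_b)
    if not atoms_a or not atoms_b:
        raise SelectionError("contact selections must each resolve to >= 1 atom")

    coords_a, _ = _atom_arrays(atoms_a)
    coords_b, _ = _atom_arrays(atoms_b)
    tree_a = cKDTree(coords_a)
    tree_b = cKDTree(coords_b)
    pairs = tree_a.query_ball_tree(tree_b, r=cutoff)

    best: dict[tuple, dict] = {}
    for ia, js in enumerate(pairs):
        sa = atoms_a[ia]
        for jb in js:
            sb = atoms_b[jb]
            dist = float(np.linalg.norm(sa.atom.coords - sb.atom.coords))
            key = (
                sa.chain_id,
                sa.residue.auth_number,
                sa.residue.insertion_code,
                sb.chain_id,
                sb.residue.auth_number,
                sb.residue.insertion_code,
            )
            rec = best.setdefault(
                key,
                {
                    "min": np.inf,
                    "polar_min": np.inf,
                    "resname_a": sa.residue.name,
                    "resname_b": sb.residue.name,
                },
            )
            rec["min"] = min(rec["min"], dist)
            if (
                sa.atom.element.upper() in _POLAR_ELEMENTS
                and sb.atom.element.upper() in _POLAR_ELEMENTS
            ):
                rec["polar_min"] = min(rec["polar_min"], dist)

    contacts = [
        Contact(
            chain_a=key[0],
            residue_a=key[1],
            resname_a=rec["resname_a"],
            chain_b=key[3],
            residue_b=key[4],
            resname_b=rec["resname_b"],
            min_distance=rec["min"],
            contact_class="hbond" if rec["polar_min"] <= HBOND_CUTOFF else "vdw",
        )
        for key, rec in best.items()
    ]
    contacts.sort(
        key=lambda c: (c.chain_a, c.residue_a, c.chain_b, c.residue_b)
    )
    return contacts
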