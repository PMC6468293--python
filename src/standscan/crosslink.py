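"""Residue-pair distances, disulfide feasibility and patch spans.

These are the geometric readouts behind cysteine-pair cross-linking
experiments: an engineered Cys pair can form a disulfide only when the two
C-beta atoms lie within a few Angstrom, and two surface patches on partner
proteins can engage a pair of determinants only if the inter-determinant
distance fits inside the patch-to-patch span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .structure_io import (
    AtomSelection,
    SelectionError,
    Structure,
    select_atoms,
)

__all__ = [
    "ResiduePair",
    "PairDistance",
    "DistanceReport",
    "pair_distances",
    "disulfide_feasibility",
    "patch_span",
    "DEFAULT_DISULFIDE_THRESHOLD",
]

#: default CB-CB feasibility threshold (Angstrom) for an engineered cysteine
#: pair: generous enough to admit side-chain rotamer freedom, strict enough
#: to exclude non-touching patches.
DEFAULT_DISULFIDE_THRESHOLD = 7.0


@dataclass(frozen=True)
class ResiduePair:
    """Two residues and the atom rule used to measure their separation."""

    chain_a: str
    number_a: int
    chain_b: str
    number_b: int
    atom_choice: str = "CB"  # "CA" | "CB" | "closest-heavy"

    def __post_init__(self) -> None:
        if self.atom_choice not in ("CA", "CB", "closest-heavy"):
            raise ValueError(f"unknown atom_choice {self.atom_choice!r}")


@dataclass
class PairDistance:
    pair: ResiduePair
    distance: float
    atoms_used: tuple[str, str]
    feasible: Optional[bool] = None
    threshold: Optional[float] = None
    notes: list[str] = field(default_factory=list)


@dataclass
class DistanceReport:
    pairs: list[PairDistance]
    span: Optional[tuple[float, float]] = None  # (min, max) in patch mode

    def __post_init__(self) -> None:
        if self.span is not None and self.span[0] > self.span[1]:
            raise ValueError("span min exceeds max")


def _measure_atom(structure: Structure, chain: str, number: int, choice: str):
    """Pick the measuring atom; CB falls back to CA for glycine (noted)."""
    res = structure.get_residue(chain, number)
    note = None
    if choice == "CB":
        atom = res.atom("CB")
        if atom is None:
            atom = res.atom("CA")
            if atom is None:
                raise SelectionError(
                    f"residue {chain}:{number} ({res.name}) has neither CB nor CA"
                )
            note = f"{chain}:{number} ({res.name}): CB absent, fell back to CA"
        return [atom], note
    if choice == "CA":
        atom = res.atom("CA")
        if atom is None:
            raise SelectionError(f"residue {chain}:{number} ({res.name}) has no CA")
        return [atom], note
    # closest-heavy: all atoms participate (hydrogens never loaded)
    return list(res.atoms), note


def pair_distances(
    structure: Structure, pairs: Sequence[ResiduePair]
) -> DistanceReport:
    """Euclidean distances for each residue pair under its atom rule.

    ``closest-heavy`` reports the minimum over all heavy-atom pairs of the
    two residues; CA/CB use the single named atom (glycine CB requests fall
    back to CA with an explicit per-pair note).
    """
    out: list[PairDistance] = []
    for pair in pairs:
        atoms_a, note_a = _measure_atom(
            structure, pair.chain_a, pair.number_a, pair.atom_choice
        )
        atoms_b, note_b = _measure_atom(
            structure, pair.chain_b, pair.number_b, pair.atom_choice
        )
        best = (np.inf, "", "")
        for aa in atoms_a:
            for ab in atoms_b:
                d = float(np.linalg.norm(aa.coords - ab.coords))
                if d < best[0]:
                    best = (d, aa.name, ab.name)
        out.append(
            PairDistance(
                pair=pair,
                distance=best[0],
                atoms_used=(best[1], best[2]),
                notes=[n for n in (note_a, note_b) if n],
            )
        )
    return DistanceReport(pairs=out)


def disulfide_feasibility(
    report: DistanceReport, threshold: float = DEFAULT_DISULFIDE_THRESHOLD
) -> DistanceReport:
    """Flag each pair as disulfide-feasible when distance <= threshold.

    Flags in place and returns the report; monotone by construction (raising
    the threshold never unflags a pair).
    """
    for pd in report.pairs:
        pd.threshold = threshold
        pd.feasible = pd.distance <= threshold
    return report


def patch_span(
    structure: Structure, patch_a: AtomSelection, patch_b: AtomSelection
) -> tuple[float, float]:
    """(min, max) over all inter-patch atom-pair distances, exactly.

    Patch membership is caller-supplied; nothing is inferred beyond the
    listed residues/atoms.
    """
    atoms_a = select_atoms(structure, patch_a)
    atoms_b = select_atoms(structure, patch_b)
    if not atoms_a or not atoms_b:
        raise SelectionError("each patch must resolve to at least one atom")
    coords_a = np.array([sa.atom.coords for sa in atoms_a])
    coords_b = np.array([sa.atom.coords for sa in atoms_b])
    d = np.linalg.norm(coords_a[:, None, :] - coords_b[None, :, :], axis=2)
    return float(d.min()), float(d.max())
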