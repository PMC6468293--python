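"""Shared fixtures: handcrafted coordinate files and generated structures."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from standscan.synthetic import (
    HelixSpec,
    SolenoidSpec,
    make_ideal_helix,
    make_solenoid,
)

REPO_ROOT = Path(__file__).resolve().parents[1]


def pdb_atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    x: float,
    y: float,
    z: float,
    occ: float = 1.0,
    b: float = 10.0,
    element: str = "C",
    altloc: str = " ",
    het: bool = False,
) -> str:
    """One fixed-column PDB coordinate record."""
    record = "HETATM" if het else "ATOM  "
    name_field = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"{record}{serial:5d} {name_field}{altloc:1s}{resname:>3s} "
        f"{chain:1s}{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture
def mixed_pdb(tmp_path) -> Path:
    """A tiny PDB with altlocs, a glycine, an ADP hetero residue and a water.

    Altloc expectations: residue 1 CA keeps conformer B (higher occupancy);
    residue 1 CB is an occupancy tie, so conformer A wins alphabetically.
    """
    lines = [
        "CRYST1   50.000   60.000   70.000  90.00  90.00 120.00 P 65",
        pdb_atom_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, element="N"),
        pdb_atom_line(2, "CA", "ALA", "A", 1, 1.0, 0.0, 0.0, occ=0.40, altloc="A"),
        pdb_atom_line(3, "CA", "ALA", "A", 1, 1.2, 0.0, 0.0, occ=0.60, altloc="B"),
        pdb_atom_line(4, "CB", "ALA", "A", 1, 2.0, 1.0, 0.0, occ=0.50, altloc="A"),
        pdb_atom_line(5, "CB", "ALA", "A", 1, 2.2, 1.0, 0.0, occ=0.50, altloc="B"),
        pdb_atom_line(6, "N", "GLY", "A", 2, 3.0, 0.0, 0.0, element="N"),
        pdb_atom_line(7, "CA", "GLY", "A", 2, 4.0, 0.0, 0.0),
        pdb_atom_line(8, "N", "ALA", "B", 1, 0.0, 5.0, 0.0, element="N"),
        pdb_atom_line(9, "CA", "ALA", "B", 1, 1.0, 5.0, 0.0),
        pdb_atom_line(10, "PA", "ADP", "A", 801, 10.0, 0.0, 0.0, element="P", het=True),
        pdb_atom_line(11, "O1A", "ADP", "A", 801, 11.0, 0.0, 0.0, element="O", het=True),
        pdb_atom_line(12, "O", "HOH", "A", 901, 20.0, 0.0, 0.0, element="O", het=True),
        "END",
    ]
    path = tmp_path / "mixed.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def helix20():
    return make_ideal_helix(HelixSpec(n_residues=20))


@pytest.fixture
def ladder_solenoid():
    """Translation-only solenoid: ABA and BAB angles are equal by symmetry."""
    return make_solenoid(SolenoidSpec(n_repeats=4, curl_deg=0.0))


@pytest.fixture
def curled_solenoid():
    """Solenoid curving toward the A face (BAB > ABA by 5 degrees)."""
    return make_solenoid(SolenoidSpec(n_repeats=5, curl_deg=5.0))


def all_coords(structure) -> np.ndarray:
    return np.array([a.coords for _, _, a in structure.iter_atoms()])


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random proper rotation via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
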