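"""Download-free synthetic structure generators.

Everything the analysis modules consume can be generated here with known
ground truth: ideal alpha-helical C-alpha traces (parameterized rise, twist
and radius), antiparallel helical hairpins stacked into solenoids with a
prescribed per-repeat curvature (so the ABA/BAB packing-angle difference is
known analytically before any fitting), seeded Gaussian coordinate noise,
and random sphere clusters for surface-area oracles.

Generators build C-alpha-only traces: that is exactly what the superposition
and packing-angle analyses consume, and surface tests use sphere clusters,
so no physically realistic backbone is pretended.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geometry import HelixSegment, SolenoidAnnotation
from .structure_io import Atom, Residue, Structure, StructureError, vdw_radius

__all__ = [
    "RigidTransform",
    "HelixSpec",
    "SolenoidSpec",
    "make_ideal_helix",
    "make_solenoid",
    "perturb",
    "make_sphere_cluster",
    "cluster_to_structure",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)
        if r.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if abs(np.linalg.det(r) - 1.0) > 1e-6:
            raise ValueError("transform must be proper (det(R) = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def translate(cls, t: Sequence[float]) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(t, dtype=float))

    @classmethod
    def about_axis(
        cls,
        axis_direction: Sequence[float],
        angle_deg: float,
        axis_point: Sequence[float] = (0.0, 0.0, 0.0),
        translation: Sequence[float] = (0.0, 0.0, 0.0),
    ) -> "RigidTransform":
        """Rotation about a line in space followed by a translation."""
        k = np.asarray(axis_direction, dtype=float)
        k = k / np.linalg.norm(k)
        a = np.radians(angle_deg)
        kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        r = np.eye(3) + np.sin(a) * kx + (1 - np.cos(a)) * (kx @ kx)
        p = np.asarray(axis_point, dtype=float)
        t = p - r @ p + np.asarray(translation, dtype=float)
        return cls(r, t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def power(self, n: int) -> "RigidTransform":
        out = RigidTransform.identity()
        for _ in range(n):
            out = self.compose(out)
        return out


@dataclass
class HelixSpec:
    """Ideal alpha-helix C-alpha trace parameters."""

    n_residues: int = 12
    rise: float = 1.5  # Angstrom per residue
    twist: float = 100.0  # degrees per residue
    radius: float = 2.3  # Angstrom
    placement: RigidTransform = field(default_factory=RigidTransform.identity)

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise StructureError("a helix needs at least 4 residues")
        if self.rise <= 0 or self.radius <= 0:
            raise StructureError("rise and radius must be positive")

    def local_coords(self) -> np.ndarray:
        i = np.arange(self.n_residues, dtype=float)
        phi = np.radians(self.twist) * i
        return np.column_stack(
            [self.radius * np.cos(phi), self.radius * np.sin(phi), self.rise * i]
        )

    def coords(self) -> np.ndarray:
        return self.placement.apply(self.local_coords())


def _ca_structure(
    coords: np.ndarray, structure_id: str, chain_id: str = "A", first_number: int = 1
) -> Structure:
    residues = [
        Residue(
            auth_number=first_number + i,
            name="ALA",
            atoms=[
                Atom(
                    name="CA",
                    element="C",
                    coords=c,
                    vdw_radius=vdw_radius("C"),
                )
            ],
        )
        for i, c in enumerate(np.asarray(coords, dtype=float))
    ]
    return Structure(id=structure_id, chains={chain_id: residues})


def make_ideal_helix(spec: HelixSpec) -> Structure:
    """A single ideal helix as a C-alpha-only structure (residues from 1)."""
    return _ca_structure(spec.coords(), "ideal-helix")


# ---------------------------------------------------------------------------
# Solenoids


@dataclass
class SolenoidSpec:
    """Helical-hairpin solenoid with a prescribed per-repeat curvature.

    Each repeat is one hairpin: an A-face helix rising along +z, a turn, and
    an antiparallel B-face helix descending at an x-offset of
    ``hairpin_spacing``; repeats are propagated by ``repeat_transform``
    (default: a ``stack_rise`` translation along +y composed with a
    ``curl_deg`` rotation about a z-parallel axis placed on the A side, which
    opens the turn fan on the A face).  Positive ``curl_deg`` therefore
    yields mean BAB > mean ABA, the canonical TPR situation.
    """

    n_repeats: int = 4
    helix_a: HelixSpec = field(default_factory=lambda: HelixSpec(n_residues=12))
    helix_b: HelixSpec = field(default_factory=lambda: HelixSpec(n_residues=12))
    turn_length: int = 3  # interpolated residues per turn
    hairpin_spacing: float = 10.0  # A-to-B axis offset, Angstrom
    stack_rise: float = 11.0  # repeat-to-repeat stacking translation, Angstrom
    curl_deg: float = 0.0  # per-repeat rotation; 0 = straight ladder
    repeat_transform: Optional[RigidTransform] = None  # overrides the above
    invert_repeat: Optional[int] = None  # locally counter-rotate one repeat
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 2:
            raise StructureError("a solenoid needs at least 2 repeats")
        if self.turn_length < 1:
            raise StructureError("turn_length must be >= 1")

    def transform(self) -> RigidTransform:
        if self.repeat_transform is not None:
            return self.repeat_transform
        if self.curl_deg == 0.0:
            return RigidTransform.translate((0.0, self.stack_rise, 0.0))
        # rotation axis parallel to the helix axes, displaced onto the A side
        return RigidTransform.about_axis(
            axis_direction=(0.0, 0.0, 1.0),
            angle_deg=-self.curl_deg,
            axis_point=(-4.0 * self.hairpin_spacing, 0.0, 0.0),
            translation=(0.0, self.stack_rise, 0.0),
        )


def _interpolate_turn(start: np.ndarray, end: np.ndarray, n: int) -> np.ndarray:
    """n evenly spaced points strictly between two C-alpha positions."""
    f = np.linspace(0.0, 1.0, n + 2)[1:-1]
    return start[None, :] + f[:, None] * (end - start)[None, :]


def make_solenoid(
    spec: SolenoidSpec,
) -> tuple[Structure, SolenoidAnnotation, dict]:
    """Build a solenoid with analytically known packing angles.

    Returns ``(structure, annotation, ground_truth)`` where ``ground_truth``
    holds per-interior-helix angles computed from the exact construction
    (exact turn endpoints, exact propagated axis directions — no fitting),
    evaluated before noise is applied.  ``ground_truth`` keys: ``records``
    (list of (helix_index, label, angle_deg)), ``mean_aba``, ``mean_bab``,
    ``delta`` (mean_bab - mean_aba).
    """
    t_repeat = spec.transform()

    # local hairpin geometry
    a_local = spec.helix_a.local_coords()
    height = (spec.helix_a.n_residues - 1) * spec.helix_a.rise
    b_raw = spec.helix_b.local_coords()
    # antiparallel: descend from the top, offset along +x
    b_local = np.column_stack(
        [
            spec.hairpin_spacing + b_raw[:, 0],
            b_raw[:, 1],
            height - b_raw[:, 2],
        ]
    )

    helix_coords: list[np.ndarray] = []  # exact per-helix C-alpha blocks
    axis_dirs: list[np.ndarray] = []  # exact axis directions, N->C
    for r in range(spec.n_repeats):
        t = t_repeat.power(r)
        if spec.invert_repeat is not None and r == spec.invert_repeat:
            # counter-rotate this one repeat in place, emulating a solenoid
            # whose local packing bucks the global trend at a single hairpin
            kink = RigidTransform.about_axis(
                axis_direction=t.rotation @ np.array([0.0, 0.0, 1.0]),
                angle_deg=2.0 * spec.curl_deg,
                axis_point=t.apply(
                    np.array([[-spec.hairpin_spacing, 0.0, 0.0]])
                )[0],
            )
            t = kink.compose(t)
        helix_coords.append(t.apply(a_local))
        axis_dirs.append(t.rotation @ np.array([0.0, 0.0, 1.0]))
        helix_coords.append(t.apply(b_local))
        axis_dirs.append(t.rotation @ np.array([0.0, 0.0, -1.0]))

    # assemble residues: helix, turn, helix, turn, ...
    all_coords: list[np.ndarray] = []
    helix_ranges: list[tuple[int, int]] = []
    num = 1
    for k, block in enumerate(helix_coords):
        start = num
        all_coords.append(block)
        num += len(block)
        helix_ranges.append((start, num - 1))
        if k + 1 < len(helix_coords):
            turn = _interpolate_turn(block[-1], helix_coords[k + 1][0], spec.turn_length)
            all_coords.append(turn)
            num += len(turn)

    coords = np.vstack(all_coords)
    _check_steric(helix_coords)

    structure = _ca_structure(coords, "synthetic-solenoid")
    annotation = SolenoidAnnotation(
        helices=[
            HelixSegment(
                chain_id="A",
                start=rng[0],
                end=rng[1],
                face_label="A" if k % 2 == 0 else "B",
            )
            for k, rng in enumerate(helix_ranges)
        ]
    )

    ground_truth = _exact_angles(helix_coords, axis_dirs)

    if spec.noise_sigma > 0:
        structure = perturb(structure, spec.noise_sigma, spec.seed)

    return structure, annotation, ground_truth


def _check_steric(helix_coords: list[np.ndarray]) -> None:
    """Reject transforms that collapse repeats onto each other."""
    n_per_repeat = 2
    for i in range(0, len(helix_coords), n_per_repeat):
        for j in range(i + n_per_repeat, len(helix_coords), n_per_repeat):
            block_i = np.vstack(helix_coords[i : i + n_per_repeat])
            block_j = np.vstack(helix_coords[j : j + n_per_repeat])
            d, _ = cKDTree(block_j).query(block_i, k=1)
            if d.min() < 1.0:
                raise StructureError(
                    "repeat transform causes steric collapse "
                    f"(C-alpha distance {d.min():.2f} A between repeats "
                    f"{i // 2} and {j // 2})"
                )


def _exact_angles(
    helix_coords: list[np.ndarray], axis_dirs: list[np.ndarray]
) -> dict:
    """Packing angles from the exact construction frame (no fitting)."""
    records = []
    aba, bab = [], []
    for i in range(1, len(helix_coords) - 1):
        t_in = helix_coords[i][0] - helix_coords[i - 1][-1]
        t_out = helix_coords[i + 1][0] - helix_coords[i][-1]
        axis = axis_dirs[i]
        p_in = t_in - np.dot(t_in, axis) * axis
        p_out = t_out - np.dot(t_out, axis) * axis
        cosang = np.dot(p_in, p_out) / (np.linalg.norm(p_in) * np.linalg.norm(p_out))
        angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        label = "BAB" if i % 2 == 0 else "ABA"
        (bab if label == "BAB" else aba).append(angle)
        records.append((i, label, angle))
    mean_aba = float(np.mean(aba)) if aba else None
    mean_bab = float(np.mean(bab)) if bab else None
    delta = (
        mean_bab - mean_aba if mean_aba is not None and mean_bab is not None else None
    )
    return {
        "records": records,
        "mean_aba": mean_aba,
        "mean_bab": mean_bab,
        "delta": delta,
    }


# ---------------------------------------------------------------------------
# Noise and clusters


def perturb(structure: Structure, sigma: float, seed: int) -> Structure:
    """I.i.d. Gaussian displacement of every atom; seeded; sigma=0 is identity."""
    if sigma < 0:
        raise StructureError("sigma must be >= 0")
    out = copy.deepcopy(structure)
    if sigma == 0:
        return out
    rng = np.random.default_rng(seed)
    for _, _, atom in out.iter_atoms():
        atom.coords = atom.coords + rng.normal(0.0, sigma, size=3)
    return out


def make_sphere_cluster(
    n: int,
    radii: Sequence[float] = (1.70,),
    box: float = 10.0,
    seed: int = 0,
) -> list[Atom]:
    """n atoms placed uniformly in a cube of side ``box`` (Angstrom).

    Radii are cycled from ``radii``; the placement is reproducible for a
    given seed.  Intended as SASA-oracle input.
    """
    if n < 1:
        raise StructureError("need at least one atom")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, box, size=(n, 3))
    return [
        Atom(
            name="C",
            element="C",
            coords=coords[i],
            is_hetero=True,
            vdw_radius=float(radii[i % len(radii)]),
        )
        for i in range(n)
    ]


def cluster_to_structure(atoms: Sequence[Atom], structure_id: str = "cluster") -> Structure:
    """Wrap a bare atom list as a one-atom-per-residue structure."""
    residues = [
        Residue(
            auth_number=i + 1,
            name="SPH",
            atoms=[copy.deepcopy(atom)],
            is_hetero=True,
        )
        for i, atom in enumerate(atoms)
    ]
    return Structure(id=structure_id, chains={"A": residues})
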