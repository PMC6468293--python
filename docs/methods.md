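# Methods

This note records how each analysis is defined, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
design decisions taken where more than one reasonable convention exists.

## Structure model and I/O

Structures are parsed with gemmi (mmCIF and PDB) into a chain → residue →
atom hierarchy that preserves **author residue numbering**, because domain
boundaries and mutations in the structural literature are cited in author
numbers.  On load:

- alternate locations are resolved to a single conformer — highest
  occupancy wins, ties break alphabetically by altloc id — so every
  downstream analysis sees one position per atom, deterministically;
- hydrogens and deuteriums are dropped: all analyses here are heavy-atom
  based, and moderate-resolution crystal structures deposit no hydrogens;
- waters are dropped unless explicitly retained; other hetero residues
  (nucleotides and similar ligands) stay in their chain, tagged;
- van der Waals radii are assigned from a fixed Bondi-style table
  (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20 Å; default 1.70 Å with a
  warning for unknown elements).  Freezing the table inside the package
  makes surface areas reproducible across installs.

A residue counts as modeled if it has at least one deposited atom.  A unit
cell of 1×1×1 Å (gemmi's placeholder) is reported as "no cell"; absence is
a value, not an error.

## Superposition

`kabsch_superpose` is the standard SVD solution of the orthogonal Procrustes
problem with the reflection corrected by sign-flipping the smallest singular
direction, so the returned matrix is always a proper rotation.  Inputs with
fewer than three atoms, or rank-deficient (collinear) coordinate sets, are
rejected rather than silently returning one of the infinitely many optima.
Chains are paired by author residue number + insertion code + atom name
(`map_common_atoms`); residues absent from either partner are dropped, which
is what "RMSD over the common Cα set" means in practice.

## Surface areas and interfaces

`shrake_rupley` samples each atom's probe-inflated sphere with a
deterministic golden-angle Fibonacci lattice (no random offset, so areas are
bit-reproducible) and counts points not occluded by any neighbouring
inflated sphere.  Defaults: probe 1.4 Å (a water molecule), 960 points.
At 960 points the total area of 50-atom clusters is within 1% of a
4000-point evaluation and within 2% of an independent 10⁵-point
re-implementation; single spheres are exact by construction.  Totals are
computed with exactly rounded summation (`math.fsum`) so they do not depend
on atom order; this makes `buried(A,B) == buried(B,A)` bit-exact.

Buried interface area uses the half-sum convention
`(SASA_A + SASA_B − SASA_AB)/2`, clamped at zero.  The default context is
**isolated-pair**: the two selections are extracted from the rest of the
structure and evaluated alone.  This matches per-domain-pair bookkeeping
(each pair accounted independently); a full-structure ΔSASA mode is
available behind a flag for users who want occlusion by the remainder of
the chain included.  Published interface areas rarely state their software,
radii set or probe, so agreement at the ±20% level is the appropriate
expectation when comparing across programs.

Contacts are residue pairs whose minimum heavy-atom distance is within the
cutoff (default 4.0 Å).  A pair is classed `hbond` when its closest
N/O–N/O atom distance is ≤ 3.5 Å, else `vdw`.  Donor/acceptor chemistry is
deliberately not inferred: without hydrogens, N/O proximity is the
operative criterion.  The KD-tree acceleration is exact — output equals the
all-pairs scan, which the tests verify by enumeration.

## Solenoid packing angles and curvature

A TPR-like solenoid is an ordered list of helices with strictly alternating
face labels A, B, A, B, … (A first).  For each interior helix:

1. its axis is fitted from the Cα trace: the trace is smoothed with
   sliding 4-residue midpoints (4 ≈ the helical period, cancelling the
   helical wobble; the window shrinks to 3 for the minimal 4-residue helix
   so that two midpoints exist), and the axis is the principal direction of
   the centered midpoints, oriented N→C;
2. the two bracketing turn vectors are formed — Cα(last residue of the
   preceding helix) → Cα(first residue of the following helix), the plainest
   reading of "the direction of the turn";
3. both turn vectors are projected onto the plane perpendicular to the
   helix axis, and the unsigned angle between the projections (degrees,
   [0, 180]) is recorded: **BAB** when the bracketed helix is on the A face,
   **ABA** for the B face.  A projected vector shorter than 10⁻³ of its 3D
   length means the turn runs along the helix axis; that angle is reported
   as undefined and excluded from the means.

Curvature is called from the means: `toward-A` when
mean BAB − mean ABA > 2°, `toward-B` below −2°, `flat` in between.  The 2°
flat band sits above the angle noise measured on σ = 0.2 Å-perturbed
synthetic solenoids (where recovered deltas stay within ~1° of truth) —
differences inside the band are not evidence of curvature.

**Anomalies** are defined against the *dominant local trend*, not the
mean-based call: each valid angle is compared with the mean of the valid
flanking angles of the opposite label, giving a local toward-A/toward-B
sign; the majority sign is the dominant trend and helices carrying the
minority sign are flagged.  The reason for this choice is the situation the
statistic exists to describe: a solenoid in which every hairpin but one
follows the BAB > ABA rule, while the single inverted hairpin drags the
mean the other way.  Defining anomalies against the mean-based call would
make the inverted hairpin *consistent* and flag everything else, which
inverts the intended reading.  Ties fall back to the sign of the global
mean difference.

Angles are reported unsigned.  A signed convention would need a reference
normal for the slab, which is itself ill-defined for curved solenoids; the
BAB-vs-ABA comparison carries the curvature information without it.

Helix segment boundaries for real structures are configuration data (the
bundled `ph0952.yaml` marks its arm/sensor helix tables as approximate,
to be corrected against the deposited coordinates); a geometric fallback is
not attempted on real structures.  Secondary-structure assignment in
general (DSSP-style) is out of scope.

## Cross-link geometry

Disulfide feasibility for an engineered cysteine pair uses the Cβ–Cβ
distance with a default threshold of 7.0 Å — generous enough to admit
side-chain rotamer freedom under oxidative cross-linking, strict enough to
exclude patches that do not touch.  Glycine has no Cβ; a Cβ request falls
back to Cα with an explicit per-pair note.  Feasibility is monotone in the
threshold by construction.  Patch spans are exact min/max over all
inter-patch atom pairs; patch membership must be supplied by the user — the
package never infers which residues "belong" to a functional patch.
No rotamer modeling or disulfide geometry scoring (χ angles, energies) is
attempted: the readout is proximity, matching what a cross-linking gel
demonstrates.

## Synthetic generator

The generator emulates exactly what the analyses consume and no more:

- **ideal helices** are Cα-only traces with parameterized rise (1.5
  Å/residue), twist (100°/residue) and radius (2.3 Å) — the canonical
  α-helix values;
- **solenoids** are hairpins (A helix up, interpolated turn, antiparallel
  B helix down at a 10 Å offset) propagated by a per-repeat rigid transform:
  an 11 Å stacking translation (typical TPR packing) composed with a
  prescribed rotation about an A-side axis.  The prescribed per-repeat
  rotation equals the resulting mean BAB − ABA difference, and ground-truth
  angles are computed from the exact construction frame (exact turn
  endpoints, exact propagated axis directions — no fitting), before any
  noise.  A single repeat can be locally counter-rotated to produce a
  ground-truth anomaly.  Transforms that bring repeats within 1 Å Cα–Cα
  are rejected as steric collapse;
- **noise** is i.i.d. Gaussian displacement per atom, seeded, with
  σ = 0.2 Å as the reference "coordinate uncertainty" level (RMS
  displacement σ√3 ≈ 0.35 Å, checked against the χ-distribution
  expectation);
- **sphere clusters** are uniform placements in a cube with assigned radii,
  for surface-area oracles.

What passing these tests shows: the estimators recover known geometry from
coordinates alone, at stated noise levels, and the numerical machinery
(projection, fitting, sampling, neighbor search) is correct.  What it does
not show: robustness to the ways real structures deviate from the generator
— missing residues inside helices, bent or frayed helix ends, non-ideal
turn conformations, sequence-dependent packing, crystal contacts, or
coordinate error that is correlated rather than i.i.d.  Real-structure
conclusions additionally depend on the helix tables supplied in the
configuration.

## Determinism and problem sizes

Every random draw is owned by an explicit seed argument; there is no hidden
global RNG state.  Reports round floats to three decimals and serialize
with sorted keys and no timestamps, so identical inputs give byte-identical
JSON.  The test suite and `scripts/acceptance.py` use small problem sizes —
solenoids of 4–5 repeats (8–10 helices, ~100–160 residues), 20-residue
helices, sphere clusters of 50–200 atoms, 10⁴ atoms for noise statistics —
chosen so each recovery check is statistically meaningful for its stated
tolerance while the whole suite runs in well under a minute.

## Known limitations

- The turn-vector construction (helix-end Cα to helix-start Cα) is one of
  several defensible definitions; alternatives (axis-termini based) shift
  absolute angles but not the BAB-vs-ABA comparison on which calls rest.
- Interface areas depend on radii/probe conventions; cross-program
  comparisons are meaningful at the ±20% level, not the Å² level.
- No symmetry-mate generation: analyses see the deposited asymmetric unit
  only.
- The PDB writer enforces the format's fixed-column limits (100 000 atoms,
  residue numbers ≤ 9999) and directs larger structures to mmCIF.
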