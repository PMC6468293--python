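# standscan

Structural analysis of STAND-ATPase resting forms.

STAND proteins (signal transduction ATPases with numerous domains — APAF1,
NLR immune receptors, the bacterial transcription activator MalT, archaeal
homologs such as *Pyrococcus horikoshii* PH0952) rest as autoinhibited
monomers in which a nucleotide-binding oligomerization domain (NOD =
NBD + HD + WHD) clamps an ADP molecule, while an arm domain and a repeat
sensor domain (TPR, WD40 or LRR) pin the NOD shut.  Characterizing a resting
form means answering a small set of geometric questions about a crystal
structure, and `standscan` packages exactly those analyses:

- **Superposition** — Kabsch least-squares superposition and Cα RMSD between
  the copies in an asymmetric unit (`geometry.kabsch_superpose`,
  `geometry.map_common_atoms`).
- **Buried interfaces** — Shrake–Rupley solvent-accessible surface areas and
  domain-pair buried areas, `buried(A,B) = (SASA_A + SASA_B − SASA_AB)/2`,
  with residue-level contact maps (`surfaces`).
- **Ligand pocket** — residues contacting a bound nucleotide at a heavy-atom
  cutoff, classed `hbond` (N/O–N/O ≤ 3.5 Å) or `vdw` (`surfaces.find_contacts`).
- **Solenoid curvature** — the ABA/BAB packing-angle statistic for TPR-like
  helical-hairpin slabs: for each interior helix, the two bracketing turn
  vectors are projected onto the plane perpendicular to that helix's axis and
  the unsigned angle between the projections is recorded (BAB when the
  bracketed helix lies on the A face, ABA for the B face).  Canonical TPR
  solenoids have mean BAB > mean ABA and curve toward the A face; the
  comparison of means classifies curvature, and single hairpins that buck the
  dominant local trend are flagged as anomalies (`geometry.packing_angles`).
- **Cross-link geometry** — Cβ–Cβ disulfide feasibility for engineered
  cysteine pairs and exact min/max spans between user-defined surface patches
  (`crosslink`).
- **Synthetic structures** — ideal helices, hairpin solenoids with
  analytically known packing angles, seeded Gaussian noise and sphere
  clusters, so every analysis is testable without downloading coordinates
  (`synthetic`).

## Worked example

Generate a six-hairpin solenoid whose repeats are rotated 5° per repeat
about an A-side axis (so the true mean BAB − ABA difference is exactly 5°),
then recover the curvature from the coordinates alone:

```python
from standscan import SolenoidSpec, make_solenoid, packing_angles

st, ann, gt = make_solenoid(SolenoidSpec(n_repeats=5, curl_deg=5.0))
rep = packing_angles(ann, st)
for r in rep.records:
    print(f"helix {r.helix_index:2d}  {r.label}  {r.angle_deg:7.2f} deg")
print(f"mean ABA = {rep.mean_aba:.2f} deg, mean BAB = {rep.mean_bab:.2f} deg")
print(f"curvature: {rep.curvature_call} (ground truth delta = {gt['delta']:.1f} deg)")
```

prints

```
helix  1  ABA   151.36 deg
helix  2  BAB   156.36 deg
helix  3  ABA   151.36 deg
helix  4  BAB   156.36 deg
helix  5  ABA   151.36 deg
helix  6  BAB   156.36 deg
helix  7  ABA   151.36 deg
helix  8  BAB   156.36 deg
mean ABA = 151.36 deg, mean BAB = 156.36 deg
curvature: toward-A (ground truth delta = 5.0 deg)
```

Every interior helix sees the same pair of turn directions in this ideal
slab, so the eight angles fall into two values whose difference is the
prescribed 5°; the call `toward-A` is the canonical TPR geometry.

For a real structure, the bundled `src/standscan/data/ph0952.yaml` encodes
the PH0952 domain boundaries (NBD 102–262, HD 263–316, WHD 317–393, arm
394–496, sensor 497–748), the NBD:WHD / NBD:arm / NBD:sensor interface
pairs, the ADP ligand selector and the arm/sensor helix tables, so the whole
analysis is one command:

```
standscan analyze --config src/standscan/data/ph0952.yaml \
    --structure data/6MFV.cif -o report.json --tsv-dir report_tsv
```

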