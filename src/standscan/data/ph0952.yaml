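# Analysis configuration for the Pyrococcus horikoshii PH0952 resting-form
# structure (PDB entry 6MFV; obtain a local copy, e.g.
#   standscan fetch 6MFV -o data/6MFV.cif
# and pass it with --structure).
#
# Domain boundaries are author residue numbers on chain A.  The same
# boundaries apply to chains B, C and D of the asymmetric unit.
#
# NOTE on the solenoid helix tables: exact helix endpoints for the arm
# (alpha15-alpha20) and sensor (alpha21-alpha33) are config data transcribed
# from the structure, not code.  The endpoints below are evenly spaced
# APPROXIMATE placeholders within the published domain ranges; verify and
# correct them against the deposited coordinates before relying on
# per-helix angles.

domains:
  - {name: NBD,    chain: A, start: 102, end: 262}
  - {name: HD,     chain: A, start: 263, end: 316}
  - {name: WHD,    chain: A, start: 317, end: 393}
  - {name: arm,    chain: A, start: 394, end: 496}
  - {name: sensor, chain: A, start: 497, end: 748}

interface_pairs:
  - [NBD, WHD]
  - [NBD, arm]
  - [NBD, sensor]

ligand: ADP
contact_cutoff: 4.0
probe: 1.4

solenoids:
  arm:  # three helical hairpins, alpha15-alpha20 -- endpoints approximate
    - {chain: A, start: 396, end: 407, face: A}
    - {chain: A, start: 412, end: 423, face: B}
    - {chain: A, start: 428, end: 439, face: A}
    - {chain: A, start: 444, end: 455, face: B}
    - {chain: A, start: 460, end: 471, face: A}
    - {chain: A, start: 476, end: 487, face: B}
  sensor:  # six TPR repeats, alpha21-alpha32 -- endpoints approximate
    - {chain: A, start: 500, end: 511, face: A}
    - {chain: A, start: 517, end: 528, face: B}
    - {chain: A, start: 534, end: 545, face: A}
    - {chain: A, start: 551, end: 562, face: B}
    - {chain: A, start: 568, end: 579, face: A}
    - {chain: A, start: 585, end: 596, face: B}
    - {chain: A, start: 602, end: 613, face: A}
    - {chain: A, start: 619, end: 630, face: B}
    - {chain: A, start: 636, end: 647, face: A}
    - {chain: A, start: 653, end: 664, face: B}
    - {chain: A, start: 670, end: 681, face: A}
    - {chain: A, start: 687, end: 698, face: B}
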