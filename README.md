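# ansamer

Stereodescriptor assignment and conformational analysis for **bridged
macrocyclic peptides** (amatoxin-type bicycles and relatives).

A head-to-tail cyclic peptide (macrolactam) carrying a single side-chain
cross-link can exist as two configurational isomers — *ansamers* — that
differ only in which face of the main ring carries the bridge ("handle").
They are not interconverted by bond rotation and can have drastically
different conformations, H-bond networks and physicochemical behavior.
This package assigns the planar-chirality-style descriptor of such a
structure and provides the ensemble analyses used to characterize the two
isomers. It is aimed at people doing structural work on bicyclic peptides:
natural-product chemists checking which isomer a synthesis produced,
and modellers analysing MD ensembles of bridged macrocycles.

## The assignment rule

For a bridged macrolactam with main cycle **M** and bridge **B**:

1. identify **M** (the largest all-backbone simple cycle) and orient it
   N→C (each amide N precedes its Cα, which precedes the carbonyl C′);
2. identify the bridge, its first bridgehead α (the bridgehead reached
   first walking N→C from the lowest-index residue) and the leading atom
   **L** (the bridge atom bonded to α);
3. determine the sense in which the N→C traversal appears when the ring is
   viewed from L. Numerically: fit the least-squares plane of **M**, orient
   its normal **n** by the right-hand rule on the N→C circulation, and take
   s = sign((**r**<sub>L</sub> − centroid) · **n**);
4. s = −1 (traversal clockwise from L) ⇒ ***P*<sub>ansa</sub>**;
   s = +1 (counter-clockwise) ⇒ ***M*<sub>ansa</sub>**
   (P = plus = right-handed, as in helicity nomenclature).

The clockwise⇒P calibration is a single module constant
(`ansamer.descriptor.DESCRIPTOR_FOR_POSITIVE_SIDE`), so recalibrating
against a reference crystal structure is a one-sign change.

Around the descriptor, the package provides the three-plane angle model
(planes fitted to the two ring arcs A/B and the bridge C, with oriented
normals and angles θ<sub>A,C</sub>, θ<sub>C,B</sub>, θ<sub>A,B</sub> in
[0°, 180°]), geometric H-bond populations with a strict >10% filter and
pairwise co-occurrence (Pearson φ), Shrake–Rupley SASA with amide exposure
classes (< 0.02 nm² shielded, > 0.04 nm² exposed), VT-NMR amide slope
classes (> −3.0 ppb K⁻¹ H-bonded, < −4.6 ppb K⁻¹ exposed), backbone φ/ψ/ω
dihedrals with cis/trans calls (|ω| ≤ 90° cis), Kabsch superposition with
RMSD/RMSF, and monoisotopic mass bookkeeping for cyclic peptides with
bridge modifications.

## Worked example

```python
from ansamer.descriptor import assign_ansamer
from ansamer.synth_fixtures import make_amatoxin_like, mirror

system = make_amatoxin_like(bridge_height=3.0)   # bridge above the ring
result = assign_ansamer(system)
print(result.descriptor, result.side, round(result.projection, 3))
print(assign_ansamer(mirror(system)).descriptor)
```

prints

```
M_ansa 1 2.121
P_ansa
```

The fixture's bridge apex sits 3 Å above a counter-clockwise (viewed from
+z) N→C ring, so the leading atom projects +2.121 Å onto the oriented ring
normal: side +1, `M_ansa`. The mirror image gives `P_ansa` — the
enantiomer law that any reflection must flip the descriptor.

Mass bookkeeping for the desulfurized macrolactam
cyclo(Asn-Hyp-Ile-Trp-Gly-Ile-Gly-Ala):

```python
from ansamer.masses import ResidueComposition, formula_from_residues, mz_protonated
comp = ResidueComposition(
    residues=("Asn", "Hyp", "Ile", "Trp", "Gly", "Ile", "Gly", "Ala"),
    cyclization="head-to-tail")
print(round(mz_protonated(formula_from_residues(comp)), 4))  # 825.4254
```

More narrative scripts live in `examples/` (descriptor assignment, plane
angles over an ensemble, the combined H-bond/SASA/dihedral/RMSF report,
peptide masses). A thin CLI mirrors the library:
`ansamer assign|angles|analyze|mass|synth` (exit codes: 2 parse, 3
topology, 4 geometric ambiguity).

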