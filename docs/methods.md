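# Methods

## Scope and model

The package treats a bridged macrocyclic peptide as a molecular graph with
3D coordinates: a head-to-tail backbone macrolactam (the *main cycle*), one
side-chain cross-link (the *bridge*) connecting two main-cycle atoms (the
*bridgeheads*), and optionally an ensemble of conformers sharing that
topology. Two configurations exist for such a molecule, distinguished by
which face of the ring carries the bridge; the package's job is to name
them reproducibly (P_ansa / M_ansa) and to quantify the conformational
differences between them.

All coordinates are Angstrom internally; SASA is converted to nm² (×0.01)
only at the amide-classification boundary, because the classification
thresholds are conventionally quoted in nm² while structure formats are in
Angstrom. Atom indexing is 0-based internally; PDB serial numbers are
preserved for reporting.

## Topology perception

*Bond perception* (used only when a file carries no CONECT records) bonds
atoms i, j iff d(i,j) ≤ 1.15 × (r_cov(i) + r_cov(j)), with Cordero-type
single-bond covalent radii and a 0.4 Å minimum to reject overlapping
duplicates. Explicit bonds always take precedence.

*Main cycle*: the largest simple cycle in the subgraph of backbone-named
atoms (N/CA/C; the name set is a parameter so non-standard fixtures can
map their own names). Ties between equal-size candidates are broken by the
lexicographically smallest sorted residue-index tuple; genuinely
indistinguishable candidates raise an ambiguity error rather than picking
silently. The cycle is then oriented N→C — starting at the amide N of the
lowest-index member residue, the traversal must follow the N, CA, C′
repeat — and anything that cannot be so oriented is rejected as "not a
macrolactam". Because the rule uses only names, residue indices and bonds,
it is invariant under any atom-order permutation of the input file.

*Bridge*: a connected component of non-cycle atoms attached to exactly two
distinct main-cycle atoms. Dangling side chains (one attachment) are
ignored; a component touching more than two cycle atoms, or two or more
independent bridge components, is rejected as unsupported multi-bridge
topology. The bridgehead α is the one reached first in N→C traversal, and
the leading atom L is the unique bridge atom bonded to α; if α carries two
bridge substituents the assignment fails loudly rather than attempting
CIP-style sub-ranking.

*Ring arcs*: the bridgeheads split the main cycle into two arcs, both kept
in N→C order and both including both bridgeheads. Segment A is the arc
entered immediately after α in N→C traversal; segment B is the
complement. For the amatoxin-like topology (bridge spanning residues 4 and
8 of an octapeptide) this labels residues {4–8} as A and {8,1–4} as B.

## Geometry

*Plane fits* use the SVD of the centered point cloud; the normal is the
smallest principal axis, and the RMS residual is s_min/√n. The normal is
*oriented* by the right-hand rule applied to the ordered traversal of the
points (Newell polygon normal of the closed traversal): N→C for ring arcs,
α → second bridgehead for the bridge. Near-collinear point sets (second
singular value below 1e-8 of the first) raise a degeneracy error.

*Plane angles* are arccos of the dot product of oriented unit normals, in
[0°, 180°] — deliberately not folded to [0°, 90°]. Folding would erase
exactly the event that distinguishes the two ansamers (an arc or bridge
flipping over is a ~180° change), and observed inter-plane angles above
90° are meaningful in this convention.

*Bridge side*: the sign of (r_L − centroid)·n with n the oriented
main-cycle normal. |projection| < 1e-6 Å is reported as ambiguous rather
than rounded to a side. Unit-norm checks use 1e-9.

*Superposition* is the Kabsch solution computed via
`scipy.spatial.transform.Rotation.align_vectors` (always a proper
rotation); the RMSD is recomputed from the transformed coordinates rather
than taken from the solver's residual, which has a ~1e-7 cancellation
floor that would mask exact matches.

## Descriptor convention

The side sign s maps to the descriptor via one module-level constant:
s = −1 (N→C appears clockwise viewed from L) ⇒ P_ansa, s = +1 ⇒ M_ansa,
mirroring P = plus = right-handed helicity usage. The textual assignment
rules alone do not pin down this sign; it is therefore isolated in
`DESCRIPTOR_FOR_POSITIVE_SIDE` so that calibrating against a deposited
crystal structure of a known isomer flips one constant, not the algebra.
Everything the tests enforce — the enantiomer law, the bridge-side law,
rigid-motion invariance, file-order independence — is independent of this
calibration choice.

Ensemble assignment evaluates every frame against the single shared
topology; frames whose leading atom falls in the mean plane are flagged,
excluded from the constancy vote and warned about, rather than voting with
an arbitrary side.

## Ensemble analyses

*Angle distributions*: per-frame angle triples histogrammed over [0°,
180°] with 5° default bins (a configurable width; the underlying per-frame
values are also returned so no information is lost to binning). Degenerate
frames are skipped, warned about and counted.

*Hydrogen bonds*: geometric criterion, donor–acceptor distance ≤ 3.5 Å
and D–H···A angle ≥ 120°, both configurable and echoed in reports; these
are common MD-analysis defaults, chosen because no single convention is
canonical. Donors default to nitrogens, acceptors to oxygens. When a
structure carries no hydrogens, an amide H is placed implicitly 1.01 Å
from a two-coordinate nitrogen along the outward bisector of its heavy
neighbors (planar sp² amide geometry). Ensemble populations are
weight-averaged presence fractions, and the population filter is a strict
inequality (kept iff population > 0.10 by default): a bond present in
exactly 10% of frames is dropped. Co-occurrence is the Pearson φ of
presence bits; zero-variance bonds yield NaN entries, reported as missing.

*SASA*: Shrake–Rupley with Bondi van der Waals radii, probe 1.4 Å, and a
deterministic golden-spiral grid of 960 points per atom (error well under
1% on an isolated sphere; doubling the grid changes the value by <0.5%).
Implemented in-package because the surface API exposes the radii table and
grid size directly and the algorithm is a page of NumPy; it is validated
against closed-form sphere and two-sphere-overlap areas. The amide group
area is the sum over the backbone N and its bonded hydrogens, matching the
convention of classifying amide-group accessibility.

*Exposure and VT-NMR classes* use strict inequalities at the documented
bounds — SASA < 0.02 nm² shielded / > 0.04 nm² exposed; temperature
coefficient > −3.0 ppb K⁻¹ H-bonded / < −4.6 ppb K⁻¹ exposed — with the
boundary values themselves falling in the intermediate/weak class. Whether
the boundaries should be inclusive is not specified anywhere
authoritative; strictness is the documented choice.

*Dihedrals*: φ/ψ/ω with the IUPAC sign convention (validated against
MDAnalysis as an independent oracle), cyclic wrap-around for head-to-tail
peptides, and the standard |ω| ≤ 90° cis cut.

*RMSF*: frames are Kabsch-fitted to a reference frame first (all atoms by
default; a backbone selection is a parameter). Note that the fit absorbs
the six rigid degrees of freedom, so for pure isotropic jitter of σ per
coordinate the expected mean RMSF is σ√3·√(1 − 2/N) with N atoms — about
2.6% below σ√3 for the 39-atom fixture used in the calibration test, which
is why that test uses a 12-residue ring rather than a tiny one.

## Masses

Residue formulas come from the pyteomics amino-acid composition table,
extended with Hyp (Pro + O), DHIle (Ile + 2O) and OHTrp (Trp + O).
Head-to-tail cyclization adds nothing; linear peptides add H₂O. Built-in
modification deltas: thioether_bridge −H₂, sulfoxide +O, hydroxylation +O,
desulfurization −S (the Cys → Ala outcome of desulfurization is expressed
as a residue substitution, making the identity bicycle − S + 2H =
Ala-monocycle exact at the formula level). Monoisotopic masses use the
IUPAC most-abundant-isotope table shipped with pyteomics (no network);
[M+zH]z+ uses the proton mass 1.007276 Da, not the H-atom mass (the
difference, one electron mass ≈ 0.55 mDa, matters at HRMS precision).
The computed [M+H]⁺ of the bicyclic thioether peptide C₃₉H₅₄N₁₀O₁₀S is
855.3818; a measured HRMS value a few mDa higher is instrument accuracy,
not formula error, so only the desulfurized monocycle value is treated as
an exact reference.

## Synthetic fixtures

The generator emulates the geometry that matters for these algorithms and
nothing more: backbone atoms evenly spaced on a circle in z = 0 (ring
radius set by a uniform 1.5 Å spacing by default), a bridge arc between
the Cα atoms of two chosen residues with a sinusoidal z-profile peaking at
a signed height h, optional i.i.d. Gaussian coordinate noise, and for
ensembles an independent uniformly random proper rotation (quaternion
sampling) plus translation per frame. The construction makes the expected
descriptor a closed form — side = sign(h) for CCW N→C traversal, −sign(h)
for CW — which is the oracle the randomized law tests check against.

These fixtures are geometric idealizations, not chemically valid
conformers: uniform bond lengths, no side chains beyond the bridge, no
hydrogens except where a test adds them. Consequently the tests
demonstrate the correctness of the graph and geometry algorithms, not
force-field realism; on real structures the same code paths run on
PDB-derived coordinates and perceived or recorded bonds. Default study
conditions used by the randomized suites: ring sizes 6–12 residues, bridge
heights 1.5–4 Å (both signs), 1–5 bridge atoms, coordinate noise up to
0.2 Å — noise small enough that the leading atom's projection (≥ ~0.7 Å
at the extremes) stays clearly off-plane, as it does in real bridged
bicycles.

## Problem sizes and determinism

The test suite and the acceptance script use 100–120 randomized fixtures
for the stereochemical laws, 1000 random point sets for the plane-fit
oracle, 100 rigid motions per fixture for invariance, 2000 frames for the
RMSF calibration and 960-point SASA grids — sizes chosen so the full suite
runs in seconds while keeping Monte-Carlo noise far from the asserted
tolerances. Every stochastic path takes an explicit seed (NumPy
`default_rng`); identical spec + seed reproduces fixtures bitwise through
PDB write/read.

## Known limitations

- Single-bridge topologies only: multi-bridge (tryptorubin-like) and
  threaded/lasso entanglements are detected and rejected, not described.
- No CIP machinery: a bridgehead with two bridge substituents fails loudly.
- The P/M calibration constant is fixed by convention, not by a deposited
  reference structure; see above.
- H-bond criteria are geometric defaults; populations from different
  criteria are not numerically comparable.
- PDB support covers ATOM/HETATM/MODEL/ENDMDL/CONECT; mmCIF and compressed
  trajectory formats are out of scope.
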