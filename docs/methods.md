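# Methods

`dbhkit` automates, as reproducible and testable operations, the workflow of
building a biochemically constrained model of a multi-domain metalloprotein
and then assessing it.  The package was developed around human dopamine
β-hydroxylase (DBH, UniProt P09172): a 617-residue copper monooxygenase
whose disulfide inventory, copper coordination distances (from EPR/EXAFS),
domain boundaries and oligomeric state are known biochemically even though
no experimental structure of the full-length protein is available.  Those
biochemical facts are treated as *constraints*; model building is constraint
satisfaction in torsion and rigid-body space, and model assessment is the
measurement of how well a set of coordinates realises the constraints.

## Coordinate model and PDB subset

Structures are chains → residues → atoms with coordinates in Å and 1-based
precursor numbering (so Cys154, His262, Cys528 mean the same thing in every
module).  Metals, waters and ligands are hetero residues addressed like
polymer residues.  The PDB reader/writer supports a strict subset of the
format — ATOM/HETATM/TER/END, one model, no altlocs or insertion codes —
because generated and modeled structures never need more, and strictness
turns malformed input into errors that name the offending line instead of
silently corrupted coordinates.  The writer's output is readable by other
toolkits (the tests cross-check against gemmi).  Spatial queries use a k-d
tree and are contractually identical to the all-pairs scan, which the tests
assert over random fixtures.

Distance criteria are closed (`≤ cutoff`) unless a criterion is explicitly
strict; the one strict criterion in the package is the < 4 Å electrostatic
contact.  All criteria are defined on heavy atoms; hydrogens are never
placed.

## Reference sequence

The package ships the 617-residue DBH precursor sequence as a FASTA data
file.  Its composition — 15 Cys (the 14 disulfide-bonded positions plus the
free Cys212), 64 Asp+Glu, 52 Arg+Lys, net charge −12 on the integer count
model — and every residue identity the analyses address (His262/263/333,
His412/414, Met487, the twelve disulfide cysteines, the Table-style SNP
neighborhoods) are covered by the test suite.  The charge model is the
plain integer count (D+E negative, R+K positive, His neutral, no pKa
model); `molar_mass` is the sum of average residue masses (shipped table,
2-decimal precision) plus one water (18.02 g/mol).

The soluble (secreted) form of the enzyme is defined in this package as
residues 39–617: the removed segment 1–38 comprises the short N-terminal
tail and the uncleaved hydrophobic signal-anchor stretch that ends at
residue 38.  This boundary matters only for the molar mass used in the
partial-specific-volume computation; it gives a soluble-chain mass of
64 920 g/mol, within 0.1 % of the mass back-solved from each of the two
published (volume, v̄) pairs.

## Constraint sets

A `ConstraintSet` bundles: disulfide constraints (intrachain pairs, and
interchain bonds stored per subunit position and expanded over chain pairs
at assembly/validation time), metal-site specifications (ligand atom,
target distance), a secondary-structure prediction string, strand-pair
expectations, named domain ranges, and all analysis cutoffs
(`AnalysisParams`).  The DBH defaults encode: six intrachain disulfides
(154–596, 232–283, 269–295, 390–503, 394–565, 466–488), interchain bonds
at 528 and 530, CuA = 3 His-ND1 at a 1.99 Å target plus one water at
1.94 Å, CuB = 2 His-NE2 plus one water (the unidentified third ligand "X"
is left as an empty slot; Met487 SD is noted as the reduced-state ligand
and not placed), the DOMON (57–173) and two monooxygenase domain ranges,
and the 50–53/193–197 strand pairing.  Cys390–Cys503 is marked `soft`:
validation reports it separately and never fails a structure on it, because
the bond may be unrealisable without distorting the C-terminal domain and
its experimental support is itself uncertain.  Target metal distances are
the spectroscopic values, not distances realised by any particular model:
realised distances are outputs.

Analysis cutoffs (defaults, all overridable): salt bridge ≤ 7 Å between
acidic O and basic N; electrostatic contact strictly < 4 Å on the same
atoms; SNP neighborhood 6 Å any-heavy-atom; first metal coordination shell
≤ 3.0 Å (covers reported Cu–ligand distances up to Met487's 2.93 Å) with an
extended 6.5 Å shell for near-miss candidate ligands (His439/Gln486 class);
S–S bond target 2.05 ± 0.3 Å; H-bond ≤ 3.5 Å with ≥ 120° donor angle;
metal–metal mononuclear floor 7 Å; probe radius 1.4 Å; side-chain C–C
hydrophobic contact ≤ 4.0 Å; clash < 2.4 Å.

## Backbone construction and assembly searches

Backbones are built from per-residue (φ, ψ, ω) dihedrals by natural
extension (NeRF) with ideal geometry: N–CA 1.458, CA–C 1.525, C–N 1.329,
C–O 1.231 Å; angles N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°, CA–C–O
120.8°.  `extract_torsions(build_backbone(seq, t)) == t` to well below
1e-6°, which the tests assert over random torsion sets.  Side chains are
idealized heavy-atom stubs grown from internal-coordinate templates with
fixed rotamers — enough to give every residue its interaction atoms (SG,
ND1/NE2, SD, charged-group O/N, side-chain carbons), with no claim of
rotamer realism.  Fragment grafting splices a fragment's torsions into a
range of the target chain and rebuilds, anchoring the rebuilt chain on the
rigid segment preceding the range; it assumes (and preserves)
ideal-geometry chains.

`linker_search` closes a linker onto disulfide and strand-pair constraints
by a random walk over the linker's φ/ψ only, with ω held trans.  Moves are
exact pivot rotations — a φ move rotates everything downstream of the N–CA
bond, a ψ move everything downstream of CA–C — so ideal internal geometry
is preserved exactly and each move changes exactly one dihedral.  The walk
is simulated annealing with geometric cooling whose temperature is scaled
to the current objective (relative start temperature 0.15, floor 1e-3),
followed by a deterministic per-torsion line-search polish over step sizes
0.5–16°, optionally restarted from the input conformation with independent
random streams.  The returned structure and the score trace track the best
state visited, so the reported trace is monotone non-increasing.  The
objective is Σ(realised − target)² over active constraints plus 10 per
steric clash (< 2.4 Å, sequence separation > 2); residue pairs that are
covalently bonded by design (constrained disulfide partners) are exempt
from the clash count.  The weights are a toolkit convention — the manual
procedure this automates had no explicit objective — and are documented,
not fitted.

`assemble_dimer` searches the 6-dof rigid placement of the second chain so
that the interchain S–S bonds form: a Kabsch-seeded initialisation (mapping
the mobile chain's SG atoms onto points 2.05 Å outside the fixed chain's
SGs) plus random restarts, each refined by derivative-free (Powell)
minimisation of Σ(SG–SG − 2.05)² plus a soft quadratic interchain-overlap
penalty (again exempting the bonded pairs).  `assemble_tetramer` places one
dimer against another with no covalent term — only optional "hint" contacts
pulled to ≤ 4 Å and the overlap penalty — reflecting a strictly
non-covalent dimer–dimer association.  Ties among equal-score placements
resolve to the earliest candidate in seed order, so results are
deterministic given the seed.

## Assessment

**Disulfides.** Detection lists all SG–SG pairs within the cutoff
(default 2.5 Å detection; validation band 2.05 ± 0.3 Å).  Validation maps
every constraint to `satisfied` / `violated` / `missing-atom`, with soft
constraints reported in a separate table.

**Metal sites.** `place_metal` puts the metal at the point minimising
Σ(|p − xᵢ| − tᵢ)² over the ligand atoms (numerical least squares from
multiple starts; the tests check 1000 random candidates never beat it).
One ligand forces the distance exactly, along the direction away from the
ligand residue's centroid (+z for a degenerate centroid).  Waters go at
their target distance in the most sterically free of 64 deterministic
Fibonacci directions.  `analyze_metal_site` reports first-shell N/O/S
ligands, the extended shell, metal–metal distances and the ≥ 7 Å
mononuclear flag.

**Ramachandran.** Classification uses shipped polygonal (φ, ψ) regions — a
coarse, fully documented approximation of the usual favored/allowed
contours, with general, Gly (symmetric, permissive) and Pro (φ-restricted)
cases; the vertex lists live next to the classifier.  The canonical helix
(−57, −47) and strand (−120, +120) fall favored and (+60, −150) is a
general-case outlier by construction.  Reported fractions are over
non-terminal residues, with a cross-tabulation giving the share of outliers
that sit in loop regions.  No claim is made that these polygons reproduce
any specific published server's percentages.

**H-bonds.** Heavy-atom proxy: donor–acceptor ≤ 3.5 Å and an angle ≥ 120°
at the donor between its bonded antecedent and the acceptor (a stand-in for
the unplaced hydrogen).  Donor/acceptor typing covers backbone N (except
Pro), backbone O, the polar side-chain atoms and water.

**Secondary structure.** Torsion-window assignment (helix box
φ ∈ [−100, −30], ψ ∈ [−80, −10]; strand box φ ∈ [−170, −70],
ψ ∈ [90, 180] ∪ [−180, −170]) with runs shorter than 3 relabeled loop and
termini loop by definition.  The chain generator draws helix/strand
torsions inside these windows and loop torsions from a library outside
them, so generator→assignment agreement is high by construction; this
checks internal consistency, not prediction accuracy.

**Interfaces.** Four classes, reported independently (one residue may
appear in several): interchain H-bonds; salt bridges (Asp/Glu O vs Lys/Arg
N within 7 Å — His excluded from the basic set by default, with a toggle);
electrostatic contacts (same atoms, strictly < 4 Å — a provable subset of
the salt bridges, asserted as an invariant); hydrophobic contacts
(side-chain carbons of A/V/L/I/M/F/W/P/Y within 4.0 Å C–C).  Domain shares
of the interface union are emitted both over unique sequence positions and
over per-chain occurrences, since either convention is defensible.

**SNP context.** A variant's neighborhood is every residue (itself
included) with any heavy atom within 6 Å of any heavy atom of the variant
residue.  Surface exposure is Shrake–Rupley accessible area (Biopython
implementation, 1.4 Å probe) relative to Gly-X-Gly maxima, with ≥ 25 %
flagged as surface.  The significance call applies the first matching
rule: *active-site-proximal* (a neighbor is a metal ligand, or the variant
is within 8 Å of a metal), *interface-proximal* (variant or neighbor in
the interface union), *surface-cysteine-risk* (substitution to Cys at a
surface position — the non-native interchain disulfide hazard), else
*likely-neutral*.

**Volume.** Solvent-excluded volume by voxel counting: a voxel center is
occupied if inside any atom sphere inflated by the probe, then the region
is eroded back by the probe radius via a Euclidean distance transform
(two-pass rolling-probe approximation).  Van der Waals and
solvent-accessible volumes are mode flags.  Atom radii are a Bondi-type
set shipped as data.  The estimate converges as spacing shrinks; at 0.25 Å
a single-sphere fixture is within 2 % of the closed form (asserted).
Partial specific volume is v̄ = V·N_A/M with N_A = 6.02214076e23.

## Synthetic data

The generators produce every fixture class the analyses need, because the
study's model coordinates are not otherwise obtainable: chains with
prescribed per-class torsions; metal sites with ligand atoms at *exactly*
the requested distances (deterministic spherical-code directions, host
residues rigidly attached, so planted distances are exact by construction,
not approximately optimised); two-site fixtures at an exact metal–metal
separation; oligomers with planted interchain atom-pair distances satisfied
to 0.01 Å by bounded rigid-body optimisation, with non-planted residue
pairs kept ≥ 4.5 Å clear; isolated-residue pairs with a named atom pair at
an exact separation (for boundary tests at 4.00/3.99/7.00 Å);
sequences with exact composition counts; and MSAs with an exact planted
number of fully conserved columns.  All generators are bit-reproducible
for a fixed seed.  What they do *not* emulate: real side-chain rotamer
distributions, realistic packing density, sequence covariation, or any
energetics — so passing plant-and-recover tests demonstrates the
correctness of the measurement operations and the convergence of the
searches, not accuracy on experimental structures.

## Problem sizes and determinism

The test and acceptance workloads use toy sizes chosen to exercise every
code path with comfortable margins: 12–40-residue chains for the torsion
searches (1 500–6 000 annealing steps, up to 3 restarts), 10-residue
chains for dimer assembly (10 rigid restarts), 20-seed sweeps for the
oracle-equivalence and success-rate properties, and 0.25 Å grids for the
sphere-volume checks.  Every stochastic component takes an explicit seed;
derived seeds come from `numpy.random.SeedSequence` spawning.

## Known limitations

- Side-chain stubs use fixed idealized rotamers; steric results on real,
  densely packed structures would need a rotamer library and are out of
  scope.
- The Ramachandran polygons are a coarse approximation; absolute
  favored/allowed percentages are not comparable to any specific server.
- `assemble_tetramer` is hint-driven rigid placement, not
  shape-complementarity docking; with no hints it only guarantees a
  clash-free arrangement.
- The H-bond criterion is a heavy-atom proxy; explicit-hydrogen geometry
  (and bifurcated bonds) are not modeled.
- Energy minimisation and conformational simulation (e.g. of the reduced
  copper state, where Met487 approaches CuB) are explicitly not provided;
  the toolkit measures geometry, it does not relax it.
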