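# Methods

This note records the models, parameter choices and numerical conventions
behind `cohdoc`, and what the synthetic fixtures do and do not establish.

## Coordinate model

Structures are read through gemmi (PDB and mmCIF) into a typed hierarchy
keyed by **author residue numbering**, because cohesin/dockerin residues are
discussed by author numbers (Ser-40, His-121, …); `label_seq` is kept as
auxiliary metadata. Only the first model of a multi-model file is read.
Alternate locations are resolved per atom name to the highest-occupancy
conformer, ties broken by altloc character order — a deterministic rule so
that every downstream geometry is reproducible. Waters and metal ions are
retained as hetero residues: the calcium analysis needs both. The crystal
structures this package targets contain no hydrogens, so **every geometric
criterion is defined on heavy atoms**.

## Superposition and rmsd

`kabsch_superpose` is the standard SVD formulation of the least-squares
rigid fit with the determinant correction that excludes reflections; the
collinearity guard rejects point sets of rank < 2. The independent check in
the test suite is the quaternion characteristic-polynomial method — a
different algorithm for the same optimum, agreeing to 1e-9 over random
instances.

`superpose_chains` builds the atom pairing by **global sequence alignment**
(identity scoring, affine gaps: match +2, mismatch −1, open −10, extend
−0.5) rather than iterative structural alignment. The chains compared here
are homologous (42–73% identity), so the alignment is unambiguous, and
avoiding outlier-rejection cycles keeps the rmsd definition reproducible.
Published "main-chain carbon" rmsds are evaluated on Cα (the quoted atom
counts are close to residue counts); the `atom_set="main"` option pairs
N/CA/C/O for the internal-symmetry fit, where using the full main chain
stabilizes the two-fold axis.

## Secondary structure

A minimal Kabsch–Sander-style assigner: amide hydrogens are reconstructed
1 Å from N along the previous C=O direction, and the H-bond energy is the
electrostatic model E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)
kcal/mol with a bond below **−0.5 kcal/mol**. Helices require two
consecutive i→i+4 turns; strands come from the parallel/antiparallel bridge
patterns, extended across the single-residue gaps that β-pleating produces,
with minimum strand length 2; sheets are connected components of the
strand-pairing graph, ordered by walking the adjacency from an end strand
(cyclic sheets start at the lowest strand index). Turns, bends, bridges
classes and accessibility are deliberately out of scope. Residues missing
main-chain atoms are labelled C and counted in a warning.

## Interface contacts

Polar contacts use fixed per-residue chemistry tables (side-chain donors
and acceptors; His ND1/NE2 and the hydroxyls of Ser/Thr/Tyr act as both),
main-chain N as donor (except proline) and O/OXT as acceptor. Criteria:
donor–acceptor distance ≤ **3.5 Å** and antecedent–donor–acceptor angle ≥
**90°** — PISA-like defaults suited to hydrogen-free crystal structures. A
pair whose partners both carry formal charge (Lys/Arg N⁺ vs Asp/Glu O⁻)
within **4.0 Å** is tagged a salt bridge, as a *sub-classification* of the
polar contact, not an additional contact. Hydrophobic contacts are apolar
carbon pairs (carbons not covalently bonded to N/O, from a shipped table)
within **4.5 Å**, reported per residue pair at minimum distance because
that is the granularity at which such interfaces are described; the
atom-level list is available behind a flag. Contacts are tagged H1/H3 by
the dockerin residue's helix membership, from the symmetry module's
segmentation.

## Calcium coordination

Ligands are protein O/N atoms and water oxygens within **3.0 Å** of a Ca²⁺
ion (typical Ca–O bonds run 2.2–2.6 Å; the source papers state no cutoff,
so a standard one is used). Residues contributing only main-chain O still
count toward the offset pattern. Classification is exact-set on the
auth-number offsets from the first ligating residue: {0,2,4,11} with ≥ 1
water is canonical, {0,6,12} with ≥ 1 water atypical, anything else —
including extra coordinating residues — is "other". Sites are ordered by
their first coordinating residue, so the N-terminal-repeat site comes
first. Fewer than three ligating residues yields a low-confidence call.

## Internal two-fold symmetry and the binding-mode verdict

Repeat k is anchored at Ca-site k's first coordinating residue and extended
through the longest following helix; the inter-repeat gap is the linker.
With anything other than two Ca sites the chain is split at its midpoint
and flagged low-confidence. The second repeat's main chain is superposed
onto the first; the fitted transform *is* the internal two-fold, and its
rotation angle (from the rotation trace) should be near 180° for a genuine
tandem duplication.

Symmetry mates are read off the superposition pairing (Cα pairs).
Compatibility uses coarse residue classes — nonpolar {A,V,L,I,M,F,W,C,P},
polar {S,T,N,Q,Y,H,G}, positive {K,R}, negative {D,E} — chosen to encode
"would the side chain still fit the hydrophobic pocket"; glycine sits with
the polar/small class. The table is a configuration value, because the
underlying biochemical judgments are qualitative and borderline cases
(e.g. Ala vs Ser) are genuinely arguable.

Contact positions are dockerin residues with ≥ 1 polar or hydrophobic
contact; only those inside helix-1/helix-3 drive the verdict, since those
helices form the cohesin interface — loop contacts are reported but not
decisive. **dual** requires every key contact position to map to a
conserved or compatible mate; one incompatible mate makes it **single**;
an empty interface is **indeterminate**. Mate mapping from the structural
superposition is primary; the sequence fingerprint (below) is the
coordinate-free fallback.

The sequence fingerprint aligns a dockerin sequence to a reference frame in
which position 1 is auth 29, so the diagnostic nonpolar positions #11/#15
are auth 39/43. The shipped reference is a **synthetic** Doc1a-frame
sequence: the residue identities established for Doc1a are placed at their
auth positions and the remaining positions are plausible filler — it fixes
the alignment frame only and is not a deposited sequence.

## ITC single-site model

Perfusion convention: each injection of volume dv multiplies existing cell
concentrations by (1 − dv/V0) before adding titrant — the linear
convention, chosen over the exponential one and switchable in principle by
replacing `totals_after_injections`. The bound concentration is the smaller
root of Ka·(n·Mt − B)·(Lt − B) = B, evaluated in the numerically stable
form 2c/(b + √disc) to avoid cancellation at high Ka; the independent test
oracle solves the same mass action by bisection. Reported heat per
injection is Q_i − Q_{i−1} + (dv/V0)(Q_i + Q_{i−1})/2 + q_offset with
Q_i = B_i·ΔH·V0 in µcal.

Fitting is `scipy.optimize.least_squares` over (n, ln Ka, ΔH, q_offset) —
Ka on a log scale for positivity and conditioning — with a three-point
multi-start on Ka (×10±²) to escape poor initializations. Initial values:
n = 1, ΔH from the largest-magnitude heat scaled by injected moles, Ka from
the steepest-slope injection assuming c ≈ 50 there. Standard errors come
from the residual covariance at the optimum; Ka's SE is propagated from
ln Ka. ΔG = −R·T·ln Ka with R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹ and
TΔS = ΔH − ΔG hold exactly by construction for every fit output. Default
temperature 308 K (rumen temperature, where these titrations are run);
default cell volume 1.4195 mL (a standard perfusion cell). First-injection
exclusion exists but is off by default. A Wiseman c = n·Ka·Mt0 above 10⁴
sets an ill-conditioning flag.

Simulated experiments choose the cell concentration so that **c ≈ 100**
(well-conditioned isotherms) with the syringe at 15× the cell — standard
design practice; the titration schedule is 28 × 10 µL at 220 s intervals.
Heat noise is i.i.d. Gaussian; the 1%-of-maximum level used in the recovery
studies corresponds to a low-noise instrument. At that noise and c ≈ 100,
the fit's Ka uncertainty is ~5% of Ka (the reported SE matches the
replicate spread, i.e. the estimator is at its information limit) — tighter
claimed precisions require proportionally lower noise.

## Synthetic fixtures: what they are and are not

The dockerin generator builds one repeat from internal coordinates
(standard bond lengths/angles; helix φ = −57°, ψ = −47°) and places the
second as an exact copy rotated 180° about a two-fold axis perpendicular to
the helix, 12 Å between helix axes, with a short interpolated Gly linker.
The 11-residue loop dihedrals were designed numerically so that the
ligating residues at offsets 0/2/4 plus the helix N-cap (offset 11) reach a
common ion position at Asp/Glu side-chain extension + a 2.35 Å Ca–O bond,
giving each repeat a canonical coordination shell plus one placed water.
Side chains are geometric idealizations laid out along the outward Cβ
direction (ligand and designated-contact side chains are aimed at their
targets); non-ligand side chains that would stray into the coordination
shell are turned away. The plateau is a two-strand apolar ribbon whose
leucines are placed 4.0 Å from the designated helix-1 contact atoms, with
an optional histidine planted at hydrogen-bond distance from a dockerin
serine.

Fixtures are **geometric, not energetic**: no packing, no electrostatics,
no force-field relaxation. Passing tests on them establishes that the
detectors and the verdict logic implement their definitions correctly —
planted contacts are found at the planted distances, exact symmetry yields
"dual", class-crossing substitutions at contact mates yield "single", and
these calls survive ≤ 0.3 Å coordinate jitter. They do not establish
performance on real coordinates, where side-chain rotamers, lattice
contacts and borderline distances occur; the checks against deposited
entries exist for that purpose and require the entries to be retrievable.

Coordinate jitter (Gaussian, per atom) and two-fold-axis tilt are explicit
generator parameters for robustness testing; both default to 0.

## Degenerate inputs and tie-breaks

- Superposition: < 3 pairs or rank < 2 → geometry error.
- Alignment-based pairing uses only mutually present atoms; < 3 paired
  atoms → geometry error.
- Segmentation without two Ca sites → midpoint split, low-confidence flag.
- Empty interface → "indeterminate" verdict with a warning, not an error.
- Contact deduplication: each donor→acceptor atom pair is reported once;
  when a pair qualifies as both H-bond and salt bridge, the salt bridge
  label wins.
- Sheets walk from a degree-1 strand; ties and cycles start at the lowest
  strand index.

## Known limitations

- The secondary-structure assigner is intentionally partial (no 3₁₀/π
  separation, no β-bridge class); very short or highly irregular strands
  may be merged or dropped relative to full DSSP.
- Hydrophobic-contact chemistry is a fixed table; modified residues fall
  back to no apolar atoms.
- The single-site ITC model has no competitive or multi-site variants and
  no raw-thermogram integration; inputs are integrated per-injection heats.
- The compatibility classes are coarse by design; users can override them
  per call or via `AnalysisConfig`.
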