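# cohdoc

Structural and thermodynamic analysis of **cohesin–dockerin complexes**, the
protein–protein interactions that assemble cellulosomes — the multi-enzyme
nanomachines anaerobic bacteria such as *Ruminococcus flavefaciens* use to
degrade plant cell walls.

A dockerin (Doc) is a ~70-residue calcium-binding module built from two
duplicated repeats, each a Ca²⁺-binding loop followed by an α-helix. A
cohesin (Coh) is a ~140-residue β-sandwich whose flat 8-3-6-5 β-sheet forms
the dockerin-binding plateau. Whether a dockerin can engage its cohesin in
**two orientations related by a ~180° rotation** (the *dual binding mode*)
or in only one (*single binding mode*) depends on the internal two-fold
symmetry of its repeats: the dual mode requires that every cohesin-contacting
residue has a conserved or physicochemically compatible residue at its
symmetry-related position.

`cohdoc` implements the complete analysis chain that answers this question
for a structure, plus the calorimetry model that quantifies the binding:

- **structure model** — typed `Structure → Chain → Residue → Atom` hierarchy
  over PDB/mmCIF (via gemmi), author-numbered, waters and ions retained;
- **geometry** — Kabsch least-squares superposition (SVD, reflections
  excluded), rmsd, and sequence-alignment-guided chain superposition;
- **secondary structure** — a minimal Kabsch–Sander-style assigner
  (main-chain H-bond energies, helix/strand/sheet topology);
- **interface** — hydrogen bonds (≤ 3.5 Å + antecedent angle ≥ 90°), salt
  bridges (charged pairs ≤ 4.0 Å), hydrophobic contacts (apolar C–C ≤ 4.5 Å),
  grouped by dockerin helix (H1/H3);
- **calcium** — Ca²⁺ site detection and EF-hand-like coordination-offset
  classification (*n, n+2, n+4, n+11* + water = canonical;
  *n, n+6, n+12* + water = atypical);
- **symmetry** — repeat segmentation, superposition of the molecule onto its
  own 180°-rotated derivative, symmetry-mate mapping, and the
  single/dual-mode verdict;
- **itc** — the single-site (Wiseman) 1:1 binding model: titration
  simulation, nonlinear least-squares fitting of (n, Ka, ΔH), and the
  identities ΔG = −RT·ln Ka, TΔS = ΔH − ΔG;
- **synthetic** — idealized dockerin/plateau fixtures with tunable internal
  symmetry, so the entire pipeline is testable without downloads.

## The core statistic

For paired coordinate sets P, Q the optimal superposition minimizes

    rmsd² = (1/N) Σᵢ ‖R·pᵢ + t − qᵢ‖²   over proper rotations R (det R = +1)

and the internal two-fold test superposes a dockerin's second repeat onto its
first: the fitted rotation should be ~180°, and the *verdict* is **dual** iff
every key contact position maps to a conserved/compatible symmetry mate.

For ITC, after injection *i* the bound concentration *B* is the smaller root
of `Ka·(n·Mt − B)·(Lt − B) = B` under perfusion dilution, and the observed
heat is the cumulative-heat difference with displaced-volume correction.
Fitted Ka (on a log scale), ΔH and n yield ΔG° = −RT·ln Ka and
TΔS° = ΔH − ΔG° at T = 308 K.

## Worked example

```bash
python examples/itc_fit.py
```

```
simulated 28 injections at T = 308 K, cell 0.85 µM, noise 0.06 µcal

N       0.998 ± 0.003   sites per macromolecule
Ka   1.204e+08 ± 6.56e+06 M^-1   (true 1.18e+08)
ΔG°    -11.39 kcal/mol
ΔH     -50.38 ± 0.26 kcal/mol   (true -50.68)
TΔS°   -38.99 kcal/mol
```

The fit recovers the simulated single-site parameters: a 1:1 stoichiometry,
an association constant within its uncertainty, and enthalpy-driven binding
with an entropic penalty. And the symmetry side:

```bash
python examples/symmetry_verdict.py
```

```
exactly duplicated repeats:
  internal rmsd 0.000 Å, rotation 180.0°
  contact ILE13 -> ILE42: conserved
  contact VAL17 -> VAL46: conserved
  verdict: dual

contact-position mate substituted V -> Q:
  ...
  contact VAL17 -> GLN46: incompatible
  verdict: single
```

A single nonpolar→polar substitution at a contact-position symmetry mate is
enough to abolish the second binding interface — the structural signature of
a single-binding-mode dockerin. The other scripts in `examples/` cover
superposition, interface contacts, calcium sites and sequence fingerprints.

There is also a thin CLI (`cohdoc analyze`, `cohdoc contacts`,
`cohdoc superpose`, `cohdoc symmetry`, `cohdoc calcium`, `cohdoc itc
fit|simulate`, `cohdoc fixtures make-doc|make-itc`) wrapping the same
functions; see `cohdoc --help`.

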