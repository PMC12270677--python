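# Methods

This note records the models, numerical choices and known limitations of
the `lariat` package in one place. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Sequence and mass arithmetic

Peptide masses are sums of standard residue masses plus one water
(`data/residue_masses.tsv`, IUPAC monoisotopic and average tables; the file
header states provenance). Oxidation removes two hydrogens per disulfide.
`ppm_error` uses the *theoretical* value as denominator — with the
observed/theoretical pairs for this system, the observed-denominator
convention would differ visibly in the first decimal (397.3 vs 397.2), so
the two conventions are distinguishable and the theoretical-denominator one
reproduces all three quoted figures. The quoted "theoretical [M+H]+" values
for the oxidized peptides sit ≈ 0.1 Da above the neutral average oxidized
mass and ≈ 0.9 Da below average-mass [M+H]+; instrument software
conventions vary, so `MassReport` exposes every variant (reduced/oxidized ×
monoisotopic/average, plus protonated forms) and comparisons use the
neutral-average interpretation with a 0.15 Da tolerance.

## Connectivity inference by exhaustive embedding

*Representation.* One Cα pseudo-atom per residue (consecutive virtual bonds
3.8 Å) plus one Sγ per cysteine tethered at 2.5 Å; a disulfide is an
Sγ–Sγ = 2.05 Å constraint. Restraints referencing other atoms are projected
onto the residue's Cα with a +1.5 Å pad.

*Sterics.* Nonbonded pairs carry soft contact floors: 4.0 Å for Cα–Cα
(the Cα bead carries side-chain volume; nonbonded Cα pairs in folded
proteins rarely approach closer) and 3.0 Å for pairs involving Sγ; the four
atoms of a bonded disulfide unit are exempt. These floors matter: with
upper-bound-only restraints, nothing but sterics prevents a wrong matching
from being satisfied by over-compaction, and target functions of the CYANA
family include van-der-Waals terms for the same reason.

*Target function.* TF = Σ max(0, d − upper)² over distance restraints,
plus w·(angle excess in radians)² over dihedral restraints (w = 1 rad⁻²Å²).
Violations are counted only beyond the reporting cutoffs, default 0.2 Å and
2.5°, both configurable (angle cutoffs of 5° are in use for comparable
systems). Chain bonds, tethers, imposed disulfides and steric floors are
model constraints, not restraints: they are enforced by the optimizer at
30× (bonds) and 5× (sterics) the restraint weight and do not enter TF.

*Omega restraints at Cα resolution.* A coarse chain has no peptide-plane
atoms, so cis/trans information is carried by the Cα(i−1)–Cα(i) virtual
bond: ≈ 3.8 Å trans, ≈ 2.9 Å cis. `proline_omega_toggle` writes ordinary
ω ranges (0° ± 10° / 180° ∓ 10°); the embedder maps them to the virtual
bond and the scorer evaluates them through the same proxy with ±0.1 Å
slack (real dihedrals are evaluated whenever N/C atoms are present).
Consequence, verified in tests: scoring a trans-built chain under a cis
toggle raises TF strictly.

*Optimization.* Each candidate matching is minimized from
`n_seeds` = 20 starts: start 0 is a distance-geometry embedding (classical
MDS on shortest-path distances through the bond/restraint graph), the rest
alternate fresh random coils with basin-hopping perturbations (σ = 1.5 Å)
of the best solution so far. Every start runs a steric-free L-BFGS stage —
letting the chain pass through itself removes topological traps — followed
by the full potential (analytic gradients; 200 + 400 iterations). A start
that reaches TF below the 10⁻³ Å² floor with zero violations ends the
search early, which is sound because TF ≥ 0. All randomness flows from an
explicit seed; identical inputs and seed give identical output.

*Assignment rule.* Candidates sort by (TF, violations, canonical pair
order). `assigned` requires a winner with zero violations whose runner-up
TF is at least 3× larger (TF values below the floor count as zero, so a
board of all-zero TFs is `undetermined` — the no-information case).
The factor 3 is a permissive envelope of the ≥ 15× and ≥ 30× separations
seen in practice for well-determined systems; it is configurable.

*Measured behaviour.* At the generator's default conditions (below), the
planted matching ranks first with zero violations in 18 of 20 replicates
(`tests/test_acceptance.py`). The two failures are genuine information
degeneracies, not optimizer misses: upper bounds cannot forbid proximity,
so when a fold places two bonded sulfur pairs in one spatial cluster, a
rewiring of that cluster satisfies every restraint exactly, several
matchings tie at TF = 0, and the tie-break cannot recover the answer. The
experimentally observed phenomenology is the same: poorly determined
isomers yield many zero-violation matchings and the connectivity call is
`undetermined`.

## Synthetic data: what it emulates and what it does not

`GeneratorConfig` defaults define the study conditions: 24 residues,
cysteines at (1, 8, 14, 15, 23, 24), granulin planted matching
(1–14, 8–23, 15–24), restraint cutoff 5 Å, 10% one-sided bound noise
(upper = d·(1 + 0.1u), u ~ U(0,1)), no decoys, strand windows 11–15 and
19–24 with +0.3 ppm offsets (−0.1 ppm elsewhere).

Reference structures are random self-avoiding Cα walks (3.8 Å steps, mild
persistence) relaxed under the planted disulfides, typed steric floors and
a spherical wall of radius 2.95·n^⅓ Å, in two weight stages, then verified:
bonds within ±0.01 Å, disulfides within ±0.05 Å, no nonbonded pair closer
than 2.0 Å; failing attempts retry with a fresh sub-seed. The wall radius
and steric floors were calibrated once against folded-peptide statistics —
Rg ≈ 5.5–6 Å, nonbonded S–S ≥ 3 Å, ≈ 2 restraints per residue at the 5 Å
cutoff — comparable to real disulfide-rich peptides of this size.

Restraints cover every Cα/Sγ pair with sequence separation ≥ 2 within the
cutoff; the Sγ–Sγ bounds that would name the planted disulfides are
withheld. Decoy mode (`decoy_restraint_fraction` = 1) replaces the set with
equally many tight bounds on random far pairs. The emulation is at
pseudo-atom resolution: no proton-level NOE network, no dihedral-angle
restraint generation, no secondary-structure realism. Passing recovery
tests therefore demonstrate the *inference machinery*, not performance on
real NOESY data, whose much denser restraint webs discriminate more
sharply.

The threaded-lariat toys are built geometrically: two disulfide-closed
circles (radius 4.8 Å, virtual-bond discretization) on one chain, placed
either as a Hopf pair or well separated, with each circle's closure gap
rotated so that the segment crossing the other loop's disc is real
backbone rather than the Sγ bridge.

## Topology

*Linking numbers.* The primary route counts signed crossings between the
projected closed polylines (projection re-drawn deterministically on
degeneracy: a crossing at a segment endpoint, or near-parallel segments
that touch); half the signed crossing sum is the linking number, and a
residual > 0.25 from integrality falls back on the Gauss sum. The
independent oracle is the midpoint-rule Gauss double integral over
subdivided segments; both routes agree on 50/50 random smooth loop pairs
(and the Hopf fixture, sign included). The numeric oracle needs the
curves' separation to exceed its discretization scale; comparisons skip
pairs closer than 0.4 Å (`curve_separation`), where the quadrature error
is unbounded although the crossing count remains exact.

*Lasso closure.* Open chain pieces are closed by extending both endpoints
radially away from the loop centroid to a sphere of 10× system diameter
and joining them along a great circle. The closure is insensitive to local
geometry for well-separated curves; curves touching within tolerance raise
an error advising perturbation.

*Threading and the DLK.* Because disulfide loops on one chain may nest or
overlap, the tail of one lariat can coincide with part of another's loop
backbone, where a literal loop-vs-tail linking number is undefined.
Threading of loop *i* is therefore computed against the maximal chain
pieces strictly outside loop *i*'s residue span (anchor residues excluded,
so curves share no points), and a piece attributes its threading to every
other lariat whose span it overlaps. For covalently disjoint lariats this
reduces exactly to loop-vs-closed-tail linking. A DLK requires two
distinct lariats that thread each other.

*Handedness.* The signed virtual torsion of every consecutive Cα quadruple
along the cyclically-extended loop is summed; verdicts are `right`/`left`
beyond ±30° total, else `indeterminate` (planar loops give zero; collinear
quadruples are skipped). The scalar is rotation/translation invariant and
flips sign under reflection. The ±30° threshold and the specific choice of
torsion-sum as the chirality-odd scalar are package conventions; mapping
its sign onto any particular experimental turn-direction nomenclature
would require calibration against reference structures.

## Superposition

Kabsch via SVD with determinant correction; reflections are never allowed,
so chirality is preserved (important when handedness is analyzed after
superposition). Rank-deficient (collinear) point sets are rejected. Loop
comparisons default to fit-on-self over the loop's backbone/Cα atoms, and
`subset_rmsd` makes fit and report selections explicit. RMSF superposes
all models onto an iteratively refined mean (3 iterations). For isotropic
per-coordinate jitter σ, the expected mean RMSF is σ√3·√(1 − 2/N) for N
fitted atoms — the √(1 − 2/N) factor is the six rigid degrees of freedom
absorbed by the fit, visible in the tests at N = 20–24.

## File formats

CYANA-style `.upl`/`.aco` dialects and a TSV equivalent for restraints;
TSV and a minimal NMR-STAR v3 `_Atom_chem_shift` loop (BMRB export subset)
for chemical shifts, parsed by a small dedicated reader that reports the
offending line on malformed input; multi-model PDB (via gemmi) for
structures, with models required to share an atom table.

## Problem sizes

Defaults keep every analysis interactive on one CPU: 15 matchings ×
20 starts × (200 + 400) L-BFGS iterations per ranking (~10–15 s), 20
replicates for recovery statistics, 1000 models for RMSF checks, 50 curve
pairs for the linking oracle.

## Known limitations

- Upper-bound-only restraints cannot forbid proximity; connectivity
  degeneracy in sulfur-clustered folds is intrinsic at this resolution.
- The coarse model carries no φ/ψ chemistry; cis/trans effects reduce to
  virtual-bond lengths.
- Threading uses linking numbers with lasso closure, not minimal-surface
  piercing; extremely shallow threadings near the loop plane may be
  closure-sensitive.
- The shift generator plants rectangular strand offsets; real secondary
  shifts taper at strand edges.
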