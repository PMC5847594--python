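# Methods

## The prediction problem

A class I MHC molecule presents a peptide of 8–11 residues in a groove
that is closed at both ends. Re-docking — reconstructing the
crystallographic pose of the peptide starting from a randomized
conformation, with the receptor held rigid — is the standard control
experiment for binding-mode prediction. The obstacle is dimensionality:
each peptide carries its 6 rigid-body degrees of freedom plus one torsion
per rotatable bond, typically 29–41 for MHC binders, and stochastic
samplers degrade rapidly beyond roughly 10 torsions.

`incdock` addresses this with incremental meta-docking: an outer loop
grows the peptide fragment by fragment, delegating the sampling and
scoring of each fragment to an inner docking engine. Fragments are
overlapping subsets of the ligand — the ligand is grown in place, never
assembled from independently docked pieces.

## Fragment decomposition

The ligand is decomposed into rigid groups connected by rotatable bonds.
A bond is rotatable iff it is a single acyclic bond between two heavy
atoms, each of which has at least one further heavy-atom or polar-hydrogen
substituent. Amide C–N bonds (backbone and side chain), guanidinium
bonds, and ring bonds (including the proline ring) are rigid. Hydroxyl,
thiol and terminal-ammonium torsions are rotatable even though they move
only hydrogens, because they carry hydrogen-bond geometry. Under these
rules tri-alanine has 6 torsions, the 9-mer EVDPIGHLY has 32, and the
8-mer KAKAYAAG has exactly 29.

The default root-selection heuristic (`max_hbond`) chooses the atom whose
initial fragment — its rigid group plus the groups reached by the first
`window_size` breadth-first rotatable bonds — contains the most
hydrogen-bond donors and acceptors; ties go to the lowest atom serial.
Rounds are planned with a sliding window: round 1 activates the
`window_size` (default 6) bonds nearest the root; each later round adds
`advance` (default 3) new bonds with their atoms and keeps the most
recently added `window_size` bonds active, freezing the rest at their
best sampled values. The total round count is
`1 + ceil(max(0, D − window) / advance)`; a 29-DoF ligand takes 9 rounds.
`advance = 3` is this package's choice: it reproduces the 9-round
schedule for a low-DoF 8-mer while keeping 50% window overlap; the bond
increment per expansion is not uniquely fixed by the method description.

## Scoring

Scoring follows the AutoDock-4 semi-empirical functional form, united-atom
(nonpolar hydrogens merged, polar hydrogens explicit):

- 12-6 dispersion/repulsion with arithmetic-mean radii and
  geometric-mean well depths (C/aromatic C: 4.0 Å, 0.15 kcal/mol;
  N: 3.5 Å, 0.16; O: 3.2 Å, 0.20; S: 4.0 Å, 0.20; polar H: 2.0 Å, 0.02);
- 12-10 hydrogen bonding between donor hydrogens and acceptor N/O
  (r_eq 1.9 Å, depth 5.0 kcal/mol);
- Coulomb electrostatics with the Mehler–Solmajer sigmoidal
  distance-dependent dielectric;
- Gaussian-volume pairwise desolvation (σ = 3.6 Å) with charge-dependent
  atomic solvation parameters;
- a torsional entropy penalty of 0.2983 kcal/mol per active rotatable
  bond.

Term weights are 0.1662 / 0.1209 / 0.1406 / 0.1322 (vdW / H-bond /
electrostatic / desolvation). Pairwise 12-6/12-10 wells are smoothed over
a 0.5 Å window around the equilibrium distance (the distance is shifted
up to 0.25 Å towards r_eq before evaluation): this flattens the well
bottom without moving the minimum, and is essential at reduced sampling
budgets — without smoothing the hydrogen-bond wells are so narrow that
local search cannot enter them. Pair energies are clamped at 1e5 kcal/mol
so clashes stay finite. Partial charges come from a package-own
per-residue template table in which every neutral residue sums to zero
and charged groups (Asp/Glu −1, Lys/Arg +1, NH3+/COO− termini ±1) to
their formal charge.

Receptor contributions are precomputed on a lattice over the binding box
(default spacing 0.375 Å, default box = ligand bounding box + 6 Å margin)
with an 8 Å nonbonded cutoff: one affinity map per ligand atom class, an
electrostatic map, and two desolvation maps. A pose is scored by
trilinear interpolation plus intramolecular terms for ligand atom pairs
more than three bonds apart; atoms leaving the box incur a
distance-proportional penalty (100 + 50·d kcal/mol per atom). A fast
compiled kernel produces total energies for the sampler; a NumPy path
produces per-term breakdowns, and the two agree to ~1e-12 relative.

## Sampling

The inner engine is a real-coded Lamarckian genetic algorithm over
(translation, orientation quaternion, active torsions). Defaults follow
the published engine configuration: 50 runs per job, population 150,
250 000 energy evaluations, 27 000 generations, elitism 1, gene mutation
rate 0.02 (Cauchy steps for translations/torsions, small random rotations
for the quaternion), two-point crossover at 0.8, and Solis–Wets local
search applied to 6% of individuals per generation with the improved
genotype written back. Tournament selection (size 2) replaces
proportional selection; this is a reference implementation of the
functional design, not a bit-exact clone. Each GA run draws from its own
generator seeded `seed + run_id`, so results are bit-identical across
repeats and across serial/parallel execution.

Two engine-layer refinements proved necessary at desk-scale budgets and
are this package's own design choices: (i) each round's top poses are
polished with a deterministic Powell line search (strongest in the final
round), because best-of-batch selection by energy otherwise prefers
half-converged decoys over near-native poses; (ii) the expansion seeds
are taken run-diverse (each GA run's best first), so alternative
placements survive expansion instead of one run's population filling the
whole top-k. Round 1, which carries the global placement search, gets a
doubled evaluation budget.

In expansion rounds the GA population is built from the seed poses: exact
copies, jittered clones, and members that inherit a seed's placement and
frozen torsions but draw the newly activated torsions uniformly — the
incremental paradigm applied to initialization. Round 1 is initialized
from fully randomized poses (uniform placement in the box, uniform
orientation, uniform torsions), which is what makes a re-docking
experiment honest: the search never sees the reference pose.

## Meta-docking, batches, escalation

One job executes the round schedule; after each round the top 10
conformations (by energy) are expanded and seed the next round. A batch
runs 20 independent jobs (seeds `base_seed + i`, no shared mutable state;
serial and parallel execution are bit-identical) and its result is the
lowest-energy full-ligand pose. Re-docking succeeds when the
receptor-aligned all-atom RMSD of that pose versus the reference is
strictly below 2 Å; otherwise the next of five protocols is tried:
P1 default, P2 random root, P3 slower growth (advance 2), P4 wider
expansion (top-k 20), P5 doubled GA budget — at most 100 jobs.

## Evaluation metrics

All metrics use heavy atoms only (crystal references carry no hydrogens,
so this is the only correspondence-safe choice), paired by residue number
and atom name with no symmetry correction for chemically equivalent atoms
(a possible ≤ 0.3 Å pessimistic bias, documented rather than corrected).
Receptor-aligned RMSDs superpose the receptors on shared alpha carbons
(all shared heavy atoms for synthetic pockets without CAs) and measure
the peptide deviation in the receptor frame; LRMSDs superpose the two
peptide copies themselves and measure pure conformational difference.
Batch summaries report mean, sample SD, maxima, fractions below 2.0 /
2.2 / 2.5 Å, and Pearson correlations against covariates such as peptide
length or DoF count. Sequence identity is ungapped, position-wise,
floored to an integer percent.

## Synthetic fixtures

Real benchmarks require crystal structures; the fixture generator builds
self-contained substitutes. A peptide is constructed from sequence
(topology and an embedded conformation from RDKit, backbone set to
φ = −135°, ψ = +135°, trans amides), aligned to the x axis, and cast into
a shape-complementary pocket: lattice sites (1.6 Å spacing) within a
4.2–5.5 Å shell of the peptide's heavy atoms become pocket pseudo-atoms,
sites above the backbone rim are removed so the cleft stays open towards
the solvent, and the cast closes naturally around the peptide ends —
like the MHC groove. Shell sites facing a peptide donor or acceptor
become complementary polar atoms (extended patches, smooth electrostatic
funnels towards the planted registry). A separately exported groove
builder produces generic open-ended/closed-ended grooves with a tunable
donor/acceptor density.

The planted reference is produced in two stages: a Powell relaxation of
the as-built pose, then the package's own sampler seeded at that pose
digs the basin to its bottom (otherwise later searches would find poses
deeper than the reference itself, making recovery ill-defined). An
instance is rejected and reseeded when any sampled pose more than 2.5 Å
from the reference scores within 0.4 kcal/mol of it — the planted pose
must be the apparent global minimum — or when the planted pose fails to
beat at least 95% of 200 random poses. The randomized start is checked to
be more than 2 Å from the reference.

These design choices mean the planted minimum is a minimum of this
package's own scoring function: recovery experiments measure search
performance, not scoring realism, and passing them says nothing about
accuracy on real crystal structures.

## Benchmark panel

The recovery benchmark is a fixed panel of ten validated synthetic
instances (sequence + generator seed), selected once by an offline
campaign that kept instances whose planted pose was re-found by a
reduced-budget pilot batch; the panel plays the role a fixed list of PDB
complexes plays in a crystallographic benchmark. Panel membership is
frozen in the code; the test-time searches still draw fresh seeds, so
recovery remains a genuine stochastic event. Panel peptides are short
(2–4 residues) and mostly aliphatic: at reduced budgets, chemically
similar polar groups (e.g. Ser hydroxyl vs Asp carboxylate) make
registry-swapped decoys nearly degenerate with the native pose, and an
extended strand's approximate screw symmetry does the same for
axis-flipped poses; central bulky side chains (Val/Leu/Ile) break that
symmetry best.

Reduced test budgets (4 GA runs × 15 000 evaluations, population 80,
2-job batches, grid spacing 0.375 Å, box margin 4 Å) keep the full suite
within minutes on one CPU; these sizes are the package's test-scale
choices, two to three orders of magnitude below the production defaults.

## Numerical choices and edge cases

- Torsions are deltas relative to the reference conformation, right-hand
  rule about the parent→child axis, stored in (−π, π].
- The global rotation acts about the root rigid group's reference
  centroid; translation is applied afterwards.
- Quaternions are normalized at decode; uniform random orientations use
  the Shoemake construction.
- Altloc ties in crystal input keep the alphabetically first altloc;
  "first copy" of multi-copy crystals = first chain set in file order
  (a chain is dropped when its full residue sequence repeats an
  already-kept chain's).
- Missing polar hydrogens are rebuilt with ideal geometry (bisector rule
  where two heavy neighbours exist, cone construction otherwise).
- Atom serials above 99999 are rejected at write time (toy scale never
  reaches the PDB field limit).
- Degenerate superpositions (fewer than 3 points, collinear sets) raise
  rather than return silently wrong transforms.

## Known limitations

- The receptor is rigid throughout; induced fit is out of scope.
- The scoring function is a reference implementation; absolute energies
  are not calibrated against experiment, and no claim of parity with any
  external engine's numbers is made.
- The frozen-torsion scheme never revisits bonds frozen more than one
  window ago (except through the final round's back-fill); strongly
  coupled torsion sets can therefore require escalation or fail.
- Synthetic fixtures have smooth, fully complementary pockets; real
  clefts are rougher and partially hydrated, so recovery rates here are
  an upper bound on real-structure behaviour.
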