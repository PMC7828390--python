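# Methods

This note documents the models implemented in `fragscreen`, the parameter
choices that matter, what the synthetic data generator does and does not
emulate, and the numerical decisions taken where the design was open.

## Spectral-change scoring

Each assigned backbone amide gives one HSQC correlation; a fragment added to
the sample perturbs correlations of residues near its binding site. Two
change classes are scored per correlation:

- **CSP** (fast exchange): the combined shift
  `CSP = sqrt(0.5·[ΔδH² + (s·ΔδN)²])` with the ¹⁵N scale `s = 0.14`
  (the standard combined-shift convention; the scale compensates the larger
  ¹⁵N dispersion). Weak iff `0.01 < CSP < 0.025` ppm (strict lower bound),
  strong iff `CSP ≥ 0.025` ppm.
- **LBE** (intermediate exchange): fractional intensity decrease, weak if
  `> 0.40`, strong if `> 0.90`, both strict, so a decrease of exactly 90% is
  weak. A reference peak absent from the perturbed list is a complete
  broadening (decrease 1.0, strong).

Weak scores 1, strong scores 2. A correlation showing both a CSP and an LBE
scores the **maximum** of the two classes, not the sum: both report the same
physical binding event and summing would double-count it. Peaks found only
in the perturbed list cannot be an assigned perturbation and are ignored
with a warning; peaks without intensities are scored on CSP alone.

**Aggregation filter.** Broadening across strictly more than 30% of all
correlations indicates fragment aggregation rather than site binding; such
data are discarded before any further analysis.

**Specificity call.** A fragment screened side by side against homologs A
and B binds a target iff its summed spectral-change score reaches
`binder_threshold` (default 2 — one strong or two weak perturbations; a
single weak shift is within HSQC reproducibility). Binding one target only
is a specific call, both is dual, neither is a non-binder; aggregation on
either target disqualifies the fragment outright. The threshold is exposed
as a parameter, not asserted as a community standard.

All thresholds live in `ScoringParameters` and classification boundaries are
exactly those parameters.

## Grand-canonical probe sampling

The cosolvent stage is a deliberately simplified stand-in for full
GCMC/MD cosolvent simulations: rigid probes (by default one single-site
probe per representative solute — benzene, propane, methanol, formamide,
acetaldehyde, imidazole, methylammonium, acetate) are inserted, deleted,
translated and rotated in a fixed external field built from Gaussian
wells/barriers and hard-core exclusions.

- **Ensemble.** Standard grand-canonical acceptance with activity
  `z = c_target·exp(μ_ex/k_BT)` (particles/Å³), so `μ_ex = 0` reproduces the
  0.25 M set-point exactly in a flat field. Insertions/deletions carry the
  `zV/(N+1)` and `N/(zV)` prefactors; translations/rotations are plain
  Metropolis. Probe–probe interactions are ignored — at 0.25 M the solution
  is nearly ideal, and the estimator this stage feeds (field recovery) does
  not require them. Explicit water is not modelled; its competitive role is
  folded into the effective field. Both are stated limitations, not hidden
  approximations.
- **μ controller.** The raw law is `μ ← μ − k_BT·ln(c_obs/c_target)`,
  retuned every 3 cycles, with a fixed point at the set-point and a
  ±0.5 kcal/mol step bound. At desk-scale box volumes the instantaneous
  particle count is O(1), and a full-gain three-cycle controller random-walks
  instead of regulating (the log of a small-count mean is strongly
  noise-biased). `c_obs` is therefore averaged over a `mu_window` of 150
  cycles and only `mu_gain = 0.02` of the log error is applied per retune —
  an integrating controller whose loop gain per window is ≈1. The flat-field
  time-averaged concentration lands within ~1% of 0.25 M.
- **Implementation.** Sets of single-site probes are independent in this
  ideal-dilute model, so they dispatch to a compiled (numba) per-type chain;
  multi-site rigid probes and runs started from an explicit state use a
  general Python loop. Streams are deterministic per (seed, params); the
  first 20% of cycles are burn-in and excluded from snapshots.

## FragMap construction

Probe atoms are binned per map type into 1 Å cubic voxels with half-open
intervals (a boundary atom belongs to the higher-index voxel); atoms outside
the grid are tallied, never silently dropped. Occupancies are divided by a
bulk expectation — either the analytic `c·N_A·V_voxel·n_frames` or the
empirical mean over a 2-voxel margin shell at the box faces — and Boltzmann
inverted, `GFE = −k_BT·ln p`, at 298 K. The shell strategy is preferred
whenever a strong site shifts the box-average concentration away from
nominal: the well/bulk occupancy ratio is activity-independent, so shell
normalization cancels any controller drift.

Unsampled and barely sampled voxels are assigned a finite cap (default
+3 kcal/mol) with the probability floor set to `exp(−cap/k_BT)`, making the
transform continuous at the cap and invertible above it; the finite cap
keeps downstream Monte Carlo scores bounded.

Generic maps combine specific ones by **voxelwise minimum GFE** (equivalently
maximum probability): APOLAR over benzene/propane carbons, HBDON over the
donor hydrogens, HBACC over the acceptor heteroatoms, MAMN and ACEO pass
through. The minimum preserves the most favorable accessible interaction of
each class. Difference maps are voxelwise A−B on a shared grid; producing
the two targets in a common frame is the caller's responsibility (synthetic
systems are constructed aligned; real use would superpose structures
upstream).

**Resolution bias.** Averaging the Boltzmann factor over a 1 Å voxel makes a
planted Gaussian well of depth −2.0 kcal/mol and width σ = 2.0 Å appear as a
−1.94 kcal/mol voxel minimum (computed by quadrature and confirmed by direct
rejection sampling). Recovery tests compare against the planted depth with a
tolerance that absorbs this.

Snapshot cadence is irrelevant to the estimator given exchangeable frames;
frames are treated as i.i.d. samples, and their correlation only inflates
the variance (see problem sizes below).

## Docking and LGFE

A pose's LGFE is the sum over classified atoms of the trilinearly
interpolated GFE of that atom's class map at its position (nearest-voxel
interpolation is available for oracle comparisons). Multi-class atoms score
their most favorable applicable map — one atom never counts against several
maps. Unclassified atoms contribute 0 and are logged; atoms outside the
interpolation hull score the cap. Interpolation nodes are voxel centers, so
the hull excludes the outer half-voxel shell.

`mc_dock` starts from a uniformly random placement, orientation and torsion
state inside its sampling box and runs two Metropolis stages on ΔLGFE: a
10,000-step exploration at 300 K with moves up to 1.0 Å / 180° / 180°
(translation / rigid rotation about the centroid / dihedral), then 40,000
simulated-annealing steps with the temperature decaying linearly from 300 K
to 0 K and moves up to 0.2 Å / 9° / 9°. Translations are uniform in a
sphere, rotations are axis–angle with a uniform random axis, dihedrals are
uniform within the bound; there is no intramolecular strain term (rigid
bonds and angles). The ligand centroid is confined to the sampling box —
without the constraint a walker that drifts off the mapped volume
random-walks in featureless (capped) space and may never return. **The
reported pose of a run is the lowest-LGFE configuration visited** (the
annealing stage starts from the exploration endpoint and tracks its best),
so annealing can never worsen the reported score; at 0 K the chain is
greedy and any uphill move is rejected.

**Hotspots.** Cubic sampling boxes of edge 14.14 Å tile the target extent
(the tiling is centered so the overhang is symmetric). Per fragment and box,
`n_replicates` independently seeded runs are launched (1000 at full scale).
Round 1 removes redundancy per fragment by greedy leader clustering of pose
centroids (cutoff 2.0 Å; leaders visited in LGFE order, so each cluster's
representative is its best pose). Round 2 clusters the representatives
across fragments (cutoff 3.0 Å) into hotspots ranked by the mean LGFE of
their members' best poses, most favorable first. The cutoffs are exposed in
`ClusterParams`.

**NMR-consistent pose selection** picks, among a fragment's hotspot poses,
the one contacting the most NMR-perturbed residues (any residue–ligand atom
distance ≤ 5.0 Å, a typical heavy-atom contact radius); ties break toward
the lower LGFE. In the screen report the NMR call stays authoritative; the
LGFE ordering across the two targets is annotated as consistent or
inconsistent with it, never allowed to override it.

## Synthetic two-homolog systems

`make_system` builds a pair of interaction fields over a 30×16×16 Å box with
four Gaussian sub-sites (σ = 1.8 Å, centers on voxel centers, pairwise
separations well above twice the width): a shared apolar/acceptor pocket, an
A-exclusive pocket with strong donor/acceptor character, a purely
hydrophobic B-exclusive pocket, and a second shared "interface" pocket.
Exclusive sites have zero depth in the other field; shared sites are
identical in both. Each pseudo-protein is a cloud of 84 point residues — six
lining each site on a 3 Å sphere, the rest scattered clear of all sites.
Point residues suffice for contact-based pose selection and site labelling;
they are not atomic structures, and nothing in the closure tests speaks to
protein flexibility, sterics, or real spectral overlap.

`make_fragments` ships five planted fragments, one per outcome class. Their
chemistry mirrors the contrast real homolog screens show: the B-specific
fragment is all-carbon with zero donor classes; the A-specific fragment
carries one donor and four acceptors; the dual binder mixes apolar and
acceptor atoms; the non-binder is a charged amine whose only classified atom
(MAMN) matches no planted well; the aggregator's chemistry is irrelevant
because it is discarded at the NMR stage.

`make_peaklists` plants, for each binder on its target protein, strong CSPs
(combined magnitude uniform in 0.03–0.06 ppm, randomly partitioned between
¹H and ¹⁵N) on all six lining residues — inside the strong band so recovery
is robust to small threshold changes — plus an intensity drop in (0.5, 0.95]
on every second lining residue. Aggregators broaden 35% of peaks of both
proteins. Every peak of a perturbed spectrum carries measurement noise
(σ = 0.003 ppm ¹H, 0.02 ppm ¹⁵N, 5% intensity), chosen at typical HSQC
reproducibility; at these levels the probability that noise alone produces
even one weak CSP in an 84-residue spectrum is ~10⁻⁵ per spectrum, and the
suite verifies zero false binder calls across 20 noise seeds. What the
generator does **not** emulate: realistic lineshapes, exchange kinetics,
peak overlap, assignment errors, or temperature/buffer effects — passing
tests show the scoring chain is correct, not that real spectra are this
clean.

## Problem sizes and verification experiments

All sizes below are the package's own desk-scale choices; every experiment
is deterministic per seed.

- **Well recovery** (`experiments.recover_planted_well`): one benzene-like
  probe at 0.25 M in a 20³ Å box over a planted −2.0 kcal/mol well,
  200,000 cycles × 100 steps (20 M GCMC steps, ~4 s compiled), shell bulk
  normalization. Across seeds the recovered minimum is −1.93 ± 0.03
  kcal/mol against the −1.94 discretized expectation, within a voxel of the
  planted center. An exchange-heavy move mix (45% insert / 45% delete) is
  used because insertions and deletions decorrelate the slowly exchanging
  well occupancy far faster than local translations.
- **Docking oracle** (`experiments.docking_enumeration_agreement`): a rigid
  two-atom apolar ligand on a 10³ Å³ map with a −3 global and a −2 decoy
  well; exhaustive enumeration over a 0.5 Å translation lattice × 128
  Fibonacci-sphere bond orientations is the independent reference. Full
  protocol runs (10k + 40k steps) agree with the enumeration minimum within
  0.1 kcal/mol in ≥95% of 50 seeded runs.
- **End-to-end closure**: the default pipeline (24,000 GCMC cycles × 40
  steps per protein; docking 1,500 + 3,000 steps × 8 replicates per box,
  12 boxes, 4 fragments, 2 proteins) recovers all five planted labels and
  ranks every planted site among the top hotspots of the correct protein in
  well under a minute.

## Known limitations

- The effective-field GCMC is a calibrated estimator testbed, not a
  replacement for cosolvent simulations on real proteins; absolute LGFEs on
  synthetic maps are not comparable to published per-compound values.
- Map quality at desk scale is sampling-limited: unsampled bulk voxels sit
  at the cap and barely sampled ones carry ±0.2–0.5 kcal/mol noise, which
  bounds how shallow a planted feature can be and still be resolved.
- Atom typing is a small rule table over elements, bonds and formal charges
  (carbon is apolar with fewer than two N/O neighbours; H on N/O donates;
  non-positive N/O accepts; N⁺ and carboxylate O are the charged classes) —
  adequate for fragment-sized molecules, not a general force-field typer.
- Difference maps assume pre-aligned grids; no superposition is performed.
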