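# Methods

This note documents the models, the numerical choices, and what the
synthetic generators do and do not emulate. It is the design record for
maintainers; the README covers usage.

## Sequence model and mutation notation

Sequences are fixed-length strings over the 20 canonical amino acids.
Noncanonical letters (X, B, Z, U, O, gaps, stops) are rejected at parse
time rather than remapped: every downstream model assumes the 20-letter
alphabet, and silent remapping would defer the failure to a less
diagnosable place. Positions are 1-based in all user-facing notation
("K2A") and converted to 0-based indices exactly once, at the module
boundary. Mutation lists are kept sorted by position; duplicate positions
are rejected. Insertions and deletions are out of scope — the population,
the crossover operator, and every pairwise MD analysis assume one common
length.

## Mutation strategies

All three strategies share one sampling path: the number of substitutions
per offspring is drawn uniformly from {1, ..., max_mutations} (only the
maximum is a meaningful protocol parameter; the uniform draw spreads
proposals over neighborhood sizes), positions are sampled uniformly
without replacement inside the editable region (whole sequence by default
— no assumption about active sites is built in), and a replacement residue
is drawn per position. Self-substitutions are excluded throughout
(transition-matrix diagonals are zero; predictor candidates equal to the
current residue are skipped): a proposal identical to its parent would
waste a fitness evaluation.

* **Masked predictor (`llm`).** The predictor contract takes a residue
  string plus masked positions and returns ranked (residue, score)
  candidates per position, deterministically. One residue is chosen per
  position from the top `candidates_per_position` (default 3) — either
  uniformly (`sample`) or the top-ranked legal candidate (`argmax`); both
  modes exist because ranked-candidate selection is underdetermined in
  principle, and the choice is visible in the config. The package ships a
  target-oracle predictor (ranks a known target's residue first; used
  wherever a landscape's optimum is known) and a hash-ranked predictor (no
  signal; plumbing and null baselines). Adapters to pretrained protein
  language models can implement the same contract; none is required or
  downloaded.
* **Smart matrix.** Estimated from an MSA by column-wise pair counting:
  in each column, every ordered pair of residues from two distinct
  sequences is one from→to event; identical pairs are discarded (only
  actual substitutions are informative) and gap characters are skipped.
  Rows are normalized; a residue never observed substituting falls back to
  the uniform row so the matrix remains usable for arbitrary parents. The
  count of homology-search iterations that produced a user's MSA is
  provenance of the input, not code.
* **Basic matrix.** Exactly 1/19 off-diagonal — the analytic
  no-information control.

Duplicate offspring are resampled up to 50 times; an exhausted
neighborhood returns fewer offspring with a warning instead of failing,
since tiny editable regions legitimately have few distinct mutants.

## The genetic algorithm

Defaults follow the protocol the toolkit emulates: population 500, 30
generations, top-80% truncation selection. Survivor count is
`ceil(retain_fraction · n)`; ties are broken by ascending sequence string
so selection is reproducible across platforms. Refill slots are produced
by single-point crossover of two distinct survivors with probability
`crossover_rate` (default 0.8; a uniform-crossover alternative sits behind
`crossover_kind`) and a survivor copy otherwise, followed by one round of
strategy mutations. Elitism (the best member always survives unmodified)
makes the best-score trajectory monotone and the reported "best mutant"
well defined.

The maximum-mutation budget is enforced against the *original wild type*,
not the immediate parent: mutants are characterized by their distance to
WT, and crossover of two in-budget parents can otherwise drift to twice
the budget. A child exceeding the budget has a random subset of its
excess substitutions reverted to the WT residue. All randomness flows from
one seeded generator recorded in the result, so a run is a pure function
of (inputs, config, seed). The stopping criterion is the generation
budget, optionally tightened by `stop_on_score`; a fitness function that
raises or returns a non-finite value costs that member its slot (with a
warning) rather than poisoning selection.

## Fitness models

Embedders are a deterministic string → fixed-length-vector contract. Two
implementations ship: a hash-projection embedder (sha256-seeded Gaussian
vector; stable across processes, carries no signal — used for plumbing and
as the fallback for strings a lookup table has never seen) and a
lookup-table embedder the synthetic generator fills with its latent
coordinates (used for model-recovery tests). Pretrained chemistry/protein
embedding models are optional adapters behind the same contract, not
dependencies.

* **Feasibility.** Random forest, 100 trees, Gini splitting,
  five-fold stratified CV with per-held-out-fold AUC, final refit on all
  rows. The score is the uncalibrated vote fraction for the "reported"
  class: 0.5 is the conventional decision boundary and calibration would
  change no rank-based conclusion. Negative rows are generated by
  independently permuting the substrate, product, and enzyme columns of
  the reported set, re-permuting on collision with any reported triple.
* **Turnover.** XGBoost regression on log₁₀ kcat with the stated
  hyperparameters (learning_rate 0.09, max_delta_step 1.19,
  min_child_weight 2.82, reg_alpha 1.94, reg_lambda 4.95); 200 trees by
  default. Base-10 logarithm is the package convention (any base gives the
  same ranks; the base is configurable and recorded). Metrics (MSE, R²,
  Pearson r) come from a random 80/20 held-out split by reaction, seed
  recorded, before a final refit on all rows. A raw-scale fit
  (`log_transform=False`) is kept for ablation and is evaluated on the log
  scale so the two fits are comparable; on log-normally distributed kcat
  the log-scale fit has lower held-out MSE, which is the motivation for
  the transform. Products are not used as turnover features — for a fixed
  transformation they duplicate the substrate's information.
* **Δ statistics.** ΔX = X_mutant − X_WT per reaction, paired by reaction
  id. Group comparisons use a Mann–Whitney U test built in-house because
  its exact branch is part of the contract: full enumeration of group
  assignments when n_A + n_B ≤ 12 with no ties (enumeration is cheap there
  and removes approximation error), normal approximation with tie and
  continuity corrections otherwise. The median split assigns values equal
  to the median to the high group.

## Convergence evaluation

First-hit iteration is the 1-based index of the first generation attaining
the trajectory maximum. The reference distribution is the point mass at
iteration 1 (ideal one-step convergence); distances use
`scipy.stats.wasserstein_distance`, which against that reference equals
mean |x − 1|. Runs that never reach a known optimum within the budget are
censored at budget + 1 — a documented convention, since an uncensored
"first hit of its own maximum" would reward strategies for stalling
early. Pairwise strategy comparisons use the Wilcoxon signed-rank test on
per-(reaction, seed) paired first hits when both strategies cover the same
complete grid, falling back to the rank-sum test otherwise; the choice is
recorded per comparison in the output table.

### Scaled comparison grid

The harness runs 3 strategies × 3 max-mutation levels (5/10/15) × 5 seeds
× 3 synthetic reactions at 15 iterations with population 100 — the same
cycle count and population as the full-scale protocol it mirrors, with
fewer seeds and reactions so the grid finishes in well under five minutes
on one CPU. Each "reaction" is a target-match landscape whose WT is
planted at Hamming distance equal to the cell's mutation budget from the
hidden target, so the optimum is reachable exactly when the budget is
used; the informative strategy is the target-oracle masked predictor
(argmax selection), `smart` is estimated from an MSA of target homologs
(12 sequences, 15% mutation rate), and `basic` is the uniform control.

The grid and the planted-recovery experiment use retain_fraction 0.2
rather than the full-scale default 0.8. This is a deliberate scaling
choice: at population 500 with 80% retention the full-scale protocol
explores 100 fresh proposals per generation, while a population-50 run at
80% retention would explore only 10 — starving the search and turning the
experiment into a test of refill rate rather than of the strategy. A 20%
retention restores roughly the full-scale exploration rate (40 fresh
proposals per generation at population 50).

## MD analytics

The package consumes dihedral tables (`time_ps, residue, phi_deg,
psi_deg`), not trajectories: running MD, force fields, and
dihedral extraction from coordinates belong to the MD suite that produced
the data. Snapshot grids must be uniform (100 ps in the emulated
protocol) and identical between WT and mutant; no interpolation is
attempted. The default analysis window is the trailing 20 ns.

The deviation statistic is implemented exactly as its formula is printed:
the WT is frozen at t′ while the mutant runs over t ∈ [t′, t_max], and the
denominator is (t_max − t′)·i_max even though the sum has one more term
than that — t′ = t_max is excluded to keep the denominator positive. The
frozen-WT reading and the denominator are both deliberate fidelity
choices; because the prose description ("deviations from the WT dihedral
angles") equally admits a running-time comparison, a `time-matched`
variant using θ^wt(t) is available behind a flag, with the printed form as
default. Angle differences are minimal signed circular differences in
(−180°, 180°], so the statistic is invariant to a common rotation of both
trajectories and well behaved across the ±180° seam, which the plain
formula does not address.

Per-residue Pearson correlations are computed between raw WT and mutant
angle series per angle kind; zero-variance residues are skipped with a
warning, and the per-mutant distribution is summarized by median and IQR.
Correlation distributions are across residues within one mutant (the
aggregation level is an explicit parameter of the reporting, since
"distribution" is ambiguous between residues, windows, and mutants).

Control generators: random controls re-mutate exactly the best mutant's
positions, drawing uniformly from the alphabet excluding the best mutant's
residue there *and* the WT residue — the stricter exclusion (flagged in
config) guarantees controls are genuine mutations at every position.
Proline controls substitute (never insert) five consecutive prolines into
a uniformly chosen window of a uniformly chosen annotated helix of length
≥ 5; substitution preserves length, which every pairwise analysis
requires, and positions already holding proline are simply left in place.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of its spec and seed.

* **Landscapes.** `target_match` scores the fraction of positions equal
  to a hidden target (optimum 1.0); `additive_site_weights` sums per-site
  weights (optimum = sum of column maxima). Both have closed-form optima
  so GA tests are parameter-recovery tests. `plant_mutations` places the
  WT at a chosen Hamming distance from the target — necessary because the
  mutation budget is enforced against the WT, so an optimum beyond the
  budget would be unreachable by construction.
* **Reaction corpora.** Each record draws a latent Gaussian vector; the
  reported and random classes sit at ±δ/2 along a unit direction of the
  concatenated latent space, giving the closed-form Bayes ceiling
  AUC = Φ(δ/√2) (≈ 0.983 at the default δ = 3). The shift is
  concentrated on the first two coordinates of each component's block:
  the ceiling depends only on ‖shift‖, but axis-concentrated shifts keep
  the signal learnable by axis-aligned tree splits, which is what the
  generator exists to test. kcat is a named monotone function of two
  enzyme-latent coordinates on the log₁₀ scale with optional log-normal
  noise (matching the heavy right tail of measured turnover numbers).
  Molecule strings are syntactically plausible placeholders with unique
  suffixes — no real chemistry — and the lookup embedders reproduce the
  latents from them deterministically.
* **Trajectories.** Each residue follows a sinusoidal base profile
  (equilibrium angle away from the ±180° seam, slow oscillation,
  amplitude 20°) shared by WT and mutant; both add independent thermal
  noise (8° sd), so unperturbed pairs correlate strongly and differ only
  by noise. Perturbations add a constant angular shift inside a residue ×
  time window, emulating a localized conformational change. Defaults (200
  snapshots × 100 ps = 20 ns) match the analysis window.

Passing tests on these generators show that the machinery recovers known
structure under the stated conditions. They do not show that real
BRENDA-scale corpora are separable, that pretrained embeddings carry the
assumed signal, or that real MD trajectories look like sinusoids with
Gaussian noise; headline real-data metrics therefore cannot be, and are
not, reproduced here.

## Problem sizes used in tests and the acceptance script

Oracle equivalences run on 200 random trajectories (≤ 5 residues × ≤ 10
snapshots) and exhaustive selection instances up to n = 8. The GA
recovery experiment is L = 12, 3 planted substitutions, population 50,
budget 30 generations, 30 seeds. The strategy grid is the scaled design
above (135 runs). Model recovery uses n = 500 (feasibility, δ = 3) and
n = 1000 (turnover, noiseless). These sizes were chosen so the whole
suite and the acceptance script each finish in well under a minute of
compute apiece while leaving the measured quantities far from their
thresholds.

## Known limitations

* Fixed-length substitution-only search; no indels, no multi-objective
  fitness, no island/parallel topologies.
* The feasibility score is an uncalibrated vote fraction; treat 0.5 as a
  conventional boundary, not a probability statement.
* The turnover model's product-free features assume one substrate per
  record; multi-substrate reactions need a richer schema.
* Foldability (pLDDT-style) scoring is an interface stub: it requires an
  external structure-prediction model by design.
* MD analytics require identical snapshot grids; resample externally if
  your WT and mutant runs were saved at different strides.
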