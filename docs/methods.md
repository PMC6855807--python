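# Methods

`xldock` reconstructs the computational arm of an integrative study of a
multidomain guanine-nucleotide exchange factor (GEF): cross-link-restrained
coarse-grained docking of rigid domains, HDX-MS differential-uptake analysis,
and nucleotide-exchange kinetics. This note records the models, the
parameters that matter, the synthetic data the tests run on, and the design
choices made where the design was genuinely open.

## Coarse-grained representation

Every modeled residue is one bead. Crystallographically resolved regions are
rigid bodies whose beads sit on the source structure's Cα positions; linkers
and unresolved termini are flexible strings with one independently movable
bead per residue. All distances in restraints and satisfaction metrics are
Euclidean bead–bead (Cα–Cα) distances. Bead radius defaults to 3.0 Å
(configurable per residue); no experimental radius is implied — it sets the
soft-sphere contact distance (6 Å for two default beads), roughly the closest
approach of non-bonded Cα pairs in packed structures. Residue numbering is
1-based with inclusive ranges. A rigid body may group ranges from several
chains (e.g. an N-terminal helix bound to its ubiquitin partner), and a body
can be declared "split" at a residue range, which converts the range to
flexible beads and the flanks to independent bodies — the fused/split
catalytic-core comparison is expressed this way in the topology file.

Flexible beads are initialized on a straight path between their anchoring
beads with seeded Gaussian jitter (σ = 1 Å); unanchored segments are laid out
as 3.8 Å random walks. This is an initialization, not a prior: the sampler
relaxes linkers within a few hundred sweeps.

## Scoring

The posterior score is a sum of negative log terms.

**Cross-link likelihood.** A cross-link observed between residues at model
distance d is assigned probability `p = ψ + (1 − 2ψ)·f(d)` with the logistic
forward model `f(d) = 1/(1 + exp(α(d − d0)))`. ψ ∈ (ψ_min, 0.5] is the
uncertainty that the identification is a true restraint: ψ → ψ_min trusts the
data, ψ = 0.5 makes the term flat in the coordinates. ψ is a sampled nuisance
parameter (default: one ψ per linker chemistry; a single global ψ is
configurable), with a uniform prior on (0.01, 0.5] whose constant negative
log is reported as zero. α defaults to 0.3 Å⁻¹. The switch distance d0 is
per-linker: 34 Å for DSS and DSG — the Cα–Cα reach of a lysine–lysine
cross-link once both side chains are counted, and the same distance at which
the ensemble analysis counts a link as satisfied — and 20 Å for the
shorter-reach DSSO chemistry and unknown linkers. Setting the switch far
below the chemistry's reach misclassifies genuinely observed long links as
noise; the posterior then prefers ψ → 0.5 over docking (we verified this mode
inversion numerically on the synthetic system).

**Excluded volume.** `k_ev·Σ max(0, r_i + r_j − d_ij)²` over non-bonded bead
pairs. Pairs within one rigid body (fixed distances) and sequence-adjacent
pairs (governed by the tether below) are excluded, so the term is zero
exactly when no inter-body or linker overlap exists. k_ev = 1.

**Connectivity.** Sequence-consecutive residues not held in the same rigid
body are tethered with `k_c·max(0, d − 4.0 Å)²`, k_c = 1. 4.0 Å is just above
the 3.8 Å trans Cα–Cα distance.

Score evaluation is incremental: per-term caches (one value per
excluded-volume pair, tether, and cross-link) are updated only for the terms
a move touches, via a numba kernel; a full re-evaluation agrees with the
cache to 1e-9 after arbitrary move sequences (tested).

## Sampling

Replica-exchange Gibbs sampling on Metropolis Monte Carlo. Moves: rigid-body
translation (uniform in a ball, ≤ 4 Å) plus rotation about a random axis
(≤ 0.03 rad) as one proposal; single flexible-bead translation (≤ 5 Å);
Gaussian ψ perturbation (σ = 0.02) reflected into (0.01, 0.5]. All proposals
are symmetric. One Gibbs sweep visits each rigid body five times
(`body_moves_per_sweep`), then every flexible bead once, then every ψ class:
a body carries six pose degrees of freedom and would otherwise receive one
proposal per sweep against dozens of bead proposals. Eight geometrically
spaced temperatures span [1.0, 2.5]; adjacent rungs attempt configuration
swaps (probability `min(1, exp((1/T_a − 1/T_b)(S_a − S_b)))`, temperatures
staying with the rungs) every `swap_interval` sweeps on alternating pairs.
Only coldest-replica frames are saved.

Runs start from seeded random configurations: body centroids uniform in a
sphere (`init_radius`, default 40 Å) and orientations perturbed by a random
rotation of at most `init_rot_max` = 1 rad about the input model's pose
(`None` gives fully uniform orientations). The bound reflects what the move
set can equilibrate: at 0.03 rad per move a replica traverses roughly one
radian of orientation space in a few thousand sweeps, and docking pipelines
of this kind start from a prebuilt full-length model whose domain
orientations are approximately physical. Production-scale defaults are
500,000 saved models from 100 starts; the benchmark and tests scale down to
10,000 models from 2 starts. Each start uses independent seeded RNG streams
per replica plus a dedicated swap stream, so a fixed seed reproduces the
ensemble bit-exactly in a single-threaded run.

## Ensemble analysis

The 200 best-scoring models (ties broken by sweep/start for determinism) are
superposed onto the best-scoring model over a reference domain using a
proper-rotation Kabsch fit (reflections excluded), then clustered by k-means
(k = 3 default, best of 10 seeded restarts) on the flattened coordinates —
a Euclidean metric proportional to coordinate RMSD. Each cluster's center is
re-extracted as the medoid (member with the lowest mean RMSD to co-members)
and its precision is the mean RMSD of members to that center; a singleton
cluster has precision 0. Cross-link satisfaction counts Cα–Cα distances
strictly below 34 Å; per cluster we report the best-scoring model's
fraction, the maximum single-member fraction, and the aggregate fraction
(links satisfied by at least one member). Convergence is checked by an
equal split of the saved ensemble — random by default, or by sampling start
to expose independent runs stuck in different basins — comparing per-half
best scores and the two-sample Kolmogorov–Smirnov statistic (non-converged
above 0.1).

## Synthetic data

The generator produces the conditions every end-to-end test runs under; all
randomness flows from one master seed through named substreams (system, xl,
hdx, kinetics), so each dataset regenerates bit-identically and
independently.

**Toy system.** Bodies are rod-shaped serpentine lattice Cα traces (2×2
cross-section, exact 3.8 Å steps; a 60-residue body is ~53 Å long) joined by
15-residue flexible linkers. The rod proportions matter: a body whose extent
is comparable to the linker reach has its orientation constrained by where
the links anchor, which a compact ~11 Å blob does not. Bodies are placed in
mutual contact (consecutive centroids 14 Å apart, every pair within 1.3×
that spacing, ≥ 6.5 Å clearance between bead surfaces, and each junction
bridgeable by its linker's contour length); ground-truth linker paths are
slack circular arcs at 3.8 Å spacing. The frozen configuration is the
ground truth.

**Cross-links.** 40 true links sampled uniformly from inter-body residue
pairs with ground-truth distance ≤ 30 Å, plus 4 decoys sampled from
intra-body pairs with distance > 45 Å — inside a rigid body the pair
distance is invariant, so decoys are unsatisfiable in every configuration
and exercise exactly the role ψ exists for. Quality fields are drawn to
pass the identification filter; records are shuffled and unlabeled, with
the truth bookkeeping retained separately.

**HDX.** Reference-state uptake follows a per-peptide saturating exponential;
a variant state is offset by known per-peptide deltas; replicates get
Gaussian centroid noise (σ = 0.15 Da default); optional per-(peptide,
timepoint) dropout emulates peptide disappearance. A separate envelope-level
generator produces undeuterated / partially labeled / fully deuterated
isotope envelopes with a configurable back-exchange loss for testing the
normalization.

**Kinetics.** Single-exponential decays sampled at uniform times with
Gaussian noise and condition metadata (enzyme, μM, additive).

What the generator does not emulate: isotope fine structure, peptide-level
intrinsic exchange-rate heterogeneity, detector noise models, and real
cross-link false-positive geometry (decoys here are maximally adversarial in
class but fixed in distance). Passing tests therefore demonstrate method
correctness under the stated statistical structure, not instrument-level
realism.

## HDX analysis

Neutral centroid mass is the intensity-weighted mean m/z minus one proton
mass (1.007276 Da) times the charge. Uptake is the centroid difference to
the undeuterated reference; back-exchange normalization divides by a fully
deuterated control's uptake and scales by the peptide's exchangeable-amide
count (length − 1 − prolines beyond the second residue). Differential
classification per peptide and timepoint: Welch's two-sided t-test with
p < 0.05 and |Δ| ≥ 0.5 Da (both configurable); peptides present in only one
state are a first-class `missing` category; timepoints are treated
independently. Per-residue maps average deltas over covering peptides and
are written to the B-factor column of a bead PDB, with 999.99 marking
residues without coverage.

## Kinetics

Each fluorescence trace is fit to `Y(t) = (Y0 − plateau)·exp(−k_obs·t) +
plateau` by least squares (lmfit), initialized from the first point, last
point, and ln 2 over half the time range; fits with k_obs SE exceeding k_obs,
non-convergence, or non-positive rate are flagged unreliable but returned.
Initial-rate estimation is deliberately absent: at the enzyme concentrations
of interest reactions can be past the initial linear phase, which is the
reason the decay fit is the primary estimator. Catalytic efficiency is
`(k_obs − k_intr)/[GEF]` in μM⁻¹·s⁻¹ (M⁻¹·s⁻¹ by flag); k_intr comes from a
no-GEF trace in the same run when present, else from configuration. Condition
comparisons are fold changes of mean efficiency with seeded percentile
bootstrap CIs (2,000 resamples default); dose series are summarized by the
Spearman rank correlation of efficiency with dose (ρ = 0 for an all-tied
series).

## Benchmark problem sizes and known limitations

The end-to-end benchmark (`xldock.benchmark.run_toy_recovery`, also run by
`scripts/acceptance.py`) uses the three-body toy with 8 temperature rungs and
2 starts × 5,000 sweeps (10,000 saved models, a few minutes on one core).
Under these conditions the best-scoring model reliably satisfies ≥ 90 % of
the true links and the split-half diagnostic passes, and replica-exchange
relaxation started from the truth confirms the truth basin is the global
score minimum. However, random-start runs at this budget usually settle in
satellite basins a few score units higher and 15–30 Å from the truth: the
0.03 rad rotation cap limits orientational diffusion to about one radian per
run, and inter-arrangement barriers far exceed the T ≤ 2.5 ladder ceiling,
so unimodal pose recovery (best-model RMSD below the top cluster's
precision) is not robust at desk scale. This is a sampling-reach limitation
of the prescribed move set, not of the scoring function, and it is the
reason production settings use many more starts. Binary distance restraints
also admit near-mirror arrangements whose scores differ only through anchor
geometry; rod-shaped bodies mitigate but do not eliminate this degeneracy.
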