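# Methods

This note documents the models, estimators and numerical conventions in
`msmpath`, and the design choices made where several defensible options
existed.

## Markov state model estimation

Transition counts `C_ij` are collected at a fixed lag τ (frames), never
across trajectory boundaries. The default counting mode is *sliding* (every
pair (t, t+τ) counts), which maximizes data use; *strided* counting
(t = 0, τ, 2τ, …) is available for strictly independent pairs. The
transition matrix is the plain maximum-likelihood row normalization
`T_ij = C_ij / Σ_j C_ij`, estimated on the largest strongly connected
component of the count graph (the *active set*); this non-reversible
estimator is the default deliberately — it follows the counting definition
exactly and makes no detailed-balance assumption. States outside the active
set carry zero weight in every downstream quantity.

The stationary distribution π is the left eigenvector of T for eigenvalue 1,
clipped to non-negative and normalized. Model constructors assert
row-stochasticity (1e-12) and the fixed-point property (1e-10) so invalid
models cannot circulate.

Implied timescales are `t_i = −τ/ln λ_i` for eigenvalues sorted by modulus.
Eigenvalues with |Im λ| > 1e-10 or λ ≤ 0 are reported as NaN (undefined
relaxation), and λ = 1 beyond the stationary process as +∞. Lag selection
follows the usual diagnostic: choose τ where the slow timescales stop
drifting on a log scale.

Free energies use `G_i = −k_B T ln π_i` with k_B = 0.0019872 kcal/mol/K and
a default temperature of 300 K, shifted so the minimum is zero (barrier
heights are differences, so the shift is a pure convention). Zero
populations are masked (NaN), never propagated as −∞.

### Equilibrium reweighting

Adaptive sampling biases the raw frame distribution, so equilibrium
expectations weight each frame by `π_state / n_frames_in_state`. Weighted
free-energy landscapes histogram these weights over one or two observables
and set `G_bin = −k_B T ln(w_bin / max_bin w)`; empty bins are masked.
Conditional probabilities are ratios of weighted frame masses,
`P = W(condition ∧ outcome) / W(condition)`; a zero-weight condition is an
error, not a zero.

## Featurization and discretization

TICA solves the generalized eigenproblem `C_τ v = λ C_0 v` after mean
removal, with the *symmetrized* lagged covariance `(C_τ + C_τᵀ)/2` — this
guarantees a real spectrum on finite, non-reversible data. `C_0` is
ridge-regularized by `ε · trace(C_0)/F` with ε = 1e-8 on the diagonal, which
silently handles constant or collinear features (a warning fires when the
condition number indicates the ridge is load-bearing). Components are
ordered by eigenvalue; the retained count is the smallest reaching the
requested fraction of kinetic variance (cumulative λ² over total λ²).

One practical caveat, learned from the recovery experiments: the TICA
projection scales directions by kinetic content, so *fast* but structurally
distinct states (e.g. an unbound basin exchanging quickly with a pocket-entry
basin) can be compressed together in the projected metric. For state-count
recovery against a known generator we therefore cluster z-scored raw
features; TICA remains the right tool for extracting slow coordinates from
high-dimensional feature sets.

k-means uses seeded k-means++ with 10 restarts (best inertia kept), and the
stored assignments are recomputed as exact nearest-center labels so the
Voronoi invariant holds regardless of the optimizer's last step.

VAMP2 scores a discretization by the summed top squared singular values of
the half-weighted propagator `C00^{-1/2} C0t Ctt^{-1/2}` built from
indicator functions of the discrete states; the stationary process
contributes 1. Cross-validation splits *by trajectory*: k-means is fitted on
the training split, held-out frames are assigned to those centers, and the
score is computed from held-out counts. Because the CV score keeps creeping
upward with K long after the slow processes are resolved, hyperparameter
selection uses a parsimony rule — the smallest K (then smallest variance
fraction) whose score reaches 95% of the grid maximum — rather than argmax.
On the six-state binding generator this rule selects K = 6 consistently
where argmax selects the largest K offered.

## Transition path theory

The forward committor solves `q_i = Σ_j T_ij q_j` with q = 0 on the source
and q = 1 on the sink; before solving, states from which the sink is
unreachable are detected by graph search and reported by name (the linear
system would be silently singular otherwise). The backward committor is the
committor toward the source on the time-reversed chain
`T̃_ij = π_j T_ji / π_i`.

Reactive flux is `F_AB = Σ_{i∈A} Σ_{j∉A} π_i T_ij q_j⁺` per lag, and the
mean first-passage time is `MFPT = τ · π_A / F_AB`. A convention note: this
MFPT normalizes by the source population. It equals the equilibrium time
spent in A per completed A→B passage, which coincides with the conventional
hitting time for metastable two-state systems but differs from the per-run
hitting time of a dense chain. Other TPT conventions normalize the rate by
`Σ_i π_i q_i⁻` instead; the two agree for two-state systems. The validation
suite checks the implemented formula against its matching simulation
estimator — time-in-source per passage counted in a long equilibrium kinetic
Monte Carlo run — rather than against per-run hitting times.

Macrostates are defined as the n (default 5) states with the highest raw
frame counts among those whose descriptors satisfy a user region predicate;
count ties break toward lower state index, and regions holding fewer than n
states are taken whole with a warning.

## Kinetic Monte Carlo

Each step draws a uniform R ∈ [0, 1) and jumps from state i to the state j
whose cumulative-probability interval [s_{i,j−1}, s_{i,j}) contains R, with
`s_ij = Σ_{k≤j} T_ik`; each step advances time by τ·frame_dt. Trajectories
store original state labels and can be dressed with frame references drawn
uniformly from each visited state's frame pool (uniform, not
density-weighted, stitching). Ensemble utilities (`first_passage_times`,
`empirical_committor`) advance many walkers in lockstep and serve as
simulation cross-checks for the linear-algebra kinetics.

## Ensemble comparison

The symmetrized Kullback–Leibler divergence is the **sum** of both directed
divergences, computed on bins shared by both samples over their common range
(30 bins, pseudocount 1e-10 by default); identical samples give exactly
zero, and a degenerate common range is defined as zero. For the unit-variance
Gaussian pair with unit mean shift the summed symmetrization equals
(μ₁−μ₂)²/σ² = 1 nat, which the validation suite uses as a closed form.
Per-residue scores average the divergences of all features involving the
residue.

Dihedral mutual information uses fixed histograms over [−180°, 180°) (24
bins per axis), MI in nats normalized by the smaller marginal entropy and
clipped to [0, 1]; a constant series has zero entropy and is assigned 0.
Because finite-sample MI is never exactly zero, the "nonzero MI" edge gate
uses a per-pair permutation null (20 shuffles, 97.5th percentile) rather
than a literal > 0. Network edges additionally require contact distance
< 6 Å; edge traversal cost is −ln(nMI) clipped at a ceiling (default 50),
so minimum-cost Dijkstra paths follow maximum information flow. Nodes are
inserted in ascending order, making tie-breaks deterministic.

## Bootstrap uncertainty

Each round draws N = round(0.8 · n_trajs) trajectories — with replacement by
default (`resample`); `subsample` draws without replacement — keeps the
original discretization labels fixed, re-estimates the MSM from the summed
per-trajectory count matrices, and evaluates the statistic (state free
energies, stationary distribution, landscape bin free energy, conditional
probability, MFPT, flux; custom callables allowed). The default is 200
rounds. Rounds that break a statistic's preconditions (e.g. the resampled
active set loses the sink) are recorded as failures and skipped, not
imputed. Reported spread is the sample standard deviation over successful
rounds, labeled as such.

## Synthetic generators: what they emulate and what they do not

All generators are hidden Markov chains with diagonal-covariance Gaussian
emissions — the simplest model that makes TICA/k-means/MSM recovery
nontrivial but exactly solvable. All randomness flows from one integer seed
through `numpy` `SeedSequence` spawning; no global RNG state is touched.

- **binding_landscape** — six states along a ligand-binding coordinate:
  unbound (25 Å), pocket entry (21 Å), two antagonist-like poses (17.5 and
  14.5 Å, distinguished by chain-dihedral sign), and an agonist-like pose
  (11 Å) split into positive- and negative-dihedral sub-states; a
  toggle-switch-like χ₂ angle rotates (90° → 0°/−90°) and a TM3–TM6-like
  distance opens (7.5 → ~9.5 Å) only in the agonist-like pose. The topology
  forces passage through the antagonist-like poses on the way in. Basin
  means follow the axes of the motivating binding study loosely; the exact
  numbers are configuration, not claims. Emissions are separated by roughly
  5σ between adjacent basins so that state recovery is well-posed, and
  exchange rates put the slowest relaxation at ~26 frames — metastable
  enough that the basins are real, fast enough that a 10⁶-step trajectory
  contains tens of thousands of independent samples.
- **double_well_1d** — a 17-bin grid whose potential is the lower envelope
  of two parabolas with minima on grid points, so the configured basin gap
  (default 1.0 kcal/mol) is exact by construction; Metropolis birth-death
  dynamics make the Boltzmann weights the exact stationary law. The default
  2.2 kcal/mol barrier yields several hundred well-to-well crossings per
  500k frames, putting the statistical error of a recovered gap near
  0.03 kcal/mol.
- **two_state** — symmetric escape chain for closed-form checks.
- **bottleneck** — an uphill six-state chain (forward 0.01 / backward 0.10
  per step) on which a single trajectory stalls near the start while
  least-counts restarts push the frontier; used for the adaptive-sampling
  comparison (25 rounds × 4 trajectories × 50 steps versus one trajectory of
  the same total budget).
- **dihedral ensembles** — residues along a planted path are wrapped-normal
  noisy copies of their predecessors (noise σ = 150°·(1−coupling)); off-path
  residues are independent. The shared contact map places consecutive path
  residues at 4.5 Å, keeps everything else beyond 6 Å, and adds short decoy
  contacts that always involve at least one off-path residue — two on-path
  residues are genuinely coupled through the chain, so a contact between
  them would be a legitimate information channel rather than a decoy. The
  paired "partial-agonist-like" ensemble shifts the mean dihedral of a
  configured off-path residue subset by 70°.

What these generators do **not** emulate: continuous-space dynamics within
basins (emissions are i.i.d. given the hidden state, so there is no
intra-basin diffusion for TICA to resolve beyond the state structure),
non-Gaussian or multimodal emissions, state-dependent noise correlations,
memory effects from projecting out solvent, or the heavy-tailed trajectory-
length distributions of real adaptive-sampling campaigns. Passing recovery
tests therefore demonstrates correctness of the estimators under Markovian,
well-separated conditions — not robustness to the projection errors of real
MD featurizations.

Adaptive sampling restarts resume the *hidden chain* from the hidden state
of the selected frame (a real campaign restarts from coordinates; the hidden
state is the generator's analogue). Least-count ties break uniformly at
random under the run seed.

## Numerical choices and degenerate inputs

- Covariance ridge ε = 1e-8 · trace/F; near-singularity warns.
- Committor solutions are clipped to [0, 1] against round-off.
- Cumulative transition rows are forced to end exactly at 1 so a uniform
  draw of 0.999… cannot fall off the row.
- k-means ties and initialization are fixed by the seed; macrostate count
  ties break by ascending state index.
- Landscape bins with zero weight are masked; the surface minimum is 0 by
  construction and asserted.
- Bootstrap statistics over varying active sets are embedded into the full
  state space (NaN for missing states) before averaging.

## Validation protocol sizes

`msmpath.protocols` runs each recovery experiment at the scale it was
designed at: 100 × 10,000-step trajectories for transition-matrix recovery;
500,000 frames for basin-gap recovery; 10 random ergodic chains with 10,000
walkers per committor estimate and ≥10,000 counted passages per MFPT; 10⁶
kMC steps for occupancy; 100,000 draws for the Gaussian K-L closed form;
three 12-residue fixtures for path recovery (cross-checked by exhaustive
simple-path enumeration); 200 bootstrap rounds; 20 paired seeds for the
adaptive-sampling sign test; and 200 seeded kMC runs for the binding-pathway
visit order. The full set completes in about a minute on one CPU.

## Known limitations

- The MSM estimator is non-reversible; no reversible maximum-likelihood or
  Bayesian posterior estimator is provided, so error bars come from the
  trajectory bootstrap only.
- No PCCA+ or hidden-Markov coarse-graining: macrostates are defined by
  descriptor regions plus raw-count ranking.
- The MFPT convention is the source-population normalization discussed
  above; users comparing against packages that normalize by Σ π_i q_i⁻
  should expect differences away from two-state-like systems.
- Mutual information uses fixed-width binning; estimators with adaptive
  partitioning or k-nearest-neighbor MI would behave better for very small
  samples.
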