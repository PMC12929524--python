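# Methods

## Model

Parcellated BOLD signals `x[k] ∈ R^n` (one sample per TR, `k = 0..T`) are
modelled as a discrete-time linear time-invariant system driven by unknown
low-dimensional inputs:

```
x[k+1] = A x[k] + B u[k] + w[k]
```

`A ∈ R^{n×n}` couples the ROIs, `B ∈ R^{n×p}` maps `p` unobserved input
channels onto the cortex, and `w[k]` is process noise.  No hemodynamic
observation model is included: the state *is* the BOLD signal, and the
estimated inputs are drivers of regional BOLD, an indirect reflection of
neural drive.  Linearity and stationarity are modelling choices, not
claims about the brain — at macroscopic scale and short horizons linear
models are strong predictors of fMRI dynamics, and the estimated inputs
absorb what linear autonomous dynamics cannot explain (external stimuli,
neuromodulatory drive, unmodelled nonlinearity).

## Estimating A

Resting runs are used for `A` because unaccounted external inputs bias the
estimate (see "Input-bias experiment" below).  Two prediction dialects are
implemented:

- **one-step** (`objective="onestep"`, the pipeline default): predict each
  sample from the measured previous sample; the minimiser of the pooled
  squared error is closed form (SVD least squares; the normal-equations
  solution computed without squaring the conditioning).  For
  stochastically driven stationary series this is the statistically
  appropriate regression.
- **free-run** (`objective="freerun"`): predict by autonomous simulation
  from each run's first sample and minimise the summed simulation error
  across subjects with L-BFGS (gradients by reverse accumulation through
  the recursion; overflow returns an infinite cost so the line search
  backtracks).  This is the literal simulated-trajectory reading of the
  group cost.  On noise-driven stationary data the simulated trajectory
  decays to the fixed point after a few time constants, so the criterion
  sees mostly the initial transient and recovery degrades; it is the right
  tool for near-deterministic or transient-rich data, which is why it is
  shipped but not the default.

Runs are per-ROI z-scored by default (toggleable).  Z-scoring conjugates
`A` by a diagonal matrix, leaving eigenvalues (hence all spectral
statistics) invariant, while putting the sparsity weight λ on a common
scale across subjects and runs.

## Estimating the unknown inputs

With `A` fixed, each stimulus run is decomposed by minimising

```
Σ_k ||z[k] − x[k]||² + λ ||U||₁ + λ pen(B)
s.t.  z[k+1] = A z[k] + B u[k],   z[0] = z0   (default z0 = x[0])
```

Defaults: λ = 0.5, p = 10 at full scale (p = 3 in the desk-scale demo).
`pen` is elementwise l1 by default; a squared-total-l1 (`l1_squared`, with
an exact sort-based prox) and a column-group `l21` dialect are available —
the elementwise form is the convex penalty that induces the intended
sparsity without imposing an unwritten rank penalty.

Because `z` is linear in `U` for fixed `B` *and* linear in `B` for fixed
`U`, both alternating steps are exact convex minimisations of the same
objective: the U-step is an l1-penalised least squares over the stacked
impulse-response design (solved by FISTA on its Gram form with the exact
Lipschitz constant, monotone via best-iterate tracking and adaptive
restart; λ = 0 short-circuits to exact least squares), and the B-step is
the analogous problem in `vec(B)` with per-sample coefficient matrices
accumulated by the recursion `C_j[k+1] = A C_j[k] + u_j[k] I`.  Warm
starts make the recorded objective trace non-increasing by construction;
an increase beyond round-off raises an internal-consistency error.  `B`
is initialised with seeded random orthonormal columns; convergence is a
relative objective change below 1e-6 (at most 50 alternations).

A standalone `estimate_B` solves the one-step latent regression
`z[k+1] − A z[k] ≈ B u[k]` (exact least squares at λ = 0); inside the
alternation the B-step minimises the full simulated-trajectory objective
instead, because regressing on constraint-satisfying trajectories is
degenerate there (the residual is exactly `B_old U`, so the penalised step
could only shrink).

**Gauge.**  `B c` and `U / c` describe the same data; the reported
optimum keeps the optimisation gauge (so the stored trace recomputes
exactly from the stored quantities), and `EstimationResult.normalized()`
produces the analysis gauge — unit-norm `B` columns, scale absorbed into
`U` — which the input-pattern statistics require.  Individual columns are
only identified up to permutation and sign; subspace metrics (principal
angles) and the sign-flip selection rule downstream are the
gauge-invariant readouts.

**Support convention.**  The l1 solution carries small spurious
activations from fitting noise; the estimated support keeps entries above
10% of the largest estimated magnitude.

**Input dimension.**  `select_input_dim` takes the smallest number of
principal components of the one-step residuals reaching a target explained
variance.  The PCA is uncentred (residuals are nominally zero-mean), which
also makes constructed spectra exact (isotropic residuals in `R^10` at
target 0.7 give exactly 7).

## Eigenmode analysis

Eigenvalues `λ_i = |λ_i| e^{iθ_i}` of a fitted `A` are reported with
frequency `f_i = θ_i / (2π dt)` (angles folded to `[0, π]`, so a conjugate
pair shares its frequency and `f ≤ 1/(2 dt)`, the Nyquist limit) and
stability `ρ_i = ln|λ_i| / dt` in s⁻¹.  Classification: metastable when
`||λ| − 1| ≤ 0.01` (the tolerance is a reporting convention), else stable
or unstable.  Modes are ordered canonically (descending magnitude, ties by
ascending angle) for reproducible reports; a near-defective eigenvector
matrix triggers a warning and downstream statistics rely on eigenvalues
only.  `z = V* x` projects a panel onto the (unit-normalised) eigenvector
basis without dimensionality reduction.

## Cluster statistics

Modes from all states are pooled; the clustering feature of a mode is the
elementwise magnitude of its unit eigenvector — a real, nonnegative,
unit-norm vector invariant to the sign/phase gauge of the eigensolver,
under which conjugate twins coincide.  k-means (squared Euclidean,
k-means++, one initialisation per repetition) is repeated many times per k
(100,000 at full scale; hundreds in tests, identical code path).  Each
repetition's centroids are aligned to the first repetition's by the
Hungarian algorithm on negated Pearson correlations (a constant centroid
row correlates 0, with a warning), and labels and outputs are reordered
accordingly.

Per cluster and repetition, one-way fixed-effects ANOVAs test stability
and frequency across states; Cohen's f = sqrt(η²/(1−η²)).  P-values are
BH-FDR corrected across all repetitions × clusters per (k, measure), and
the per-cluster percentage of significant repetitions is reported with two
reliability metrics: percent variance of the first principal component of
the matched centroids, and the distribution of centroid–reference
correlations.  A cluster-repetition in which some state contributes fewer
than two observations is skipped and counted, never imputed.

**Conjugate pairs count once.**  A conjugate pair is one oscillatory mode:
its twins share stability and frequency exactly, and pooling both doubles
every group size without adding information — empirically this inflated
null FDR-significance rates several-fold (a cluster holding one pair per
state has zero within-group variance).  The ANOVA therefore uses one
observation per pair by default (`conjugate_pairs_as_one=False` restores
the pooled reading); clustering always uses all modes.

Cluster-quality indices (Calinski–Harabasz, Davies–Bouldin, Silhouette)
are provided as diagnostics only; eigenvector clusters have no single
optimal resolution, which is why a range of k is scanned.

## Input-pattern statistics

Per state, subjects' unit-norm `B` columns are concatenated and decomposed
by **uncentred** PCA over the ROI dimension (principal axes of the second
moment).  Uncentred is deliberate: the unit-column gauge fixes each map
only up to sign, and the uncentred decomposition is exactly invariant
under flipping any column — centring would leak the arbitrary sign choices
into the components and break the downstream guarantee that upstream sign
flips change no reported decision.  Components are sign-canonicalised
(largest-|entry| coordinate positive) and matched one-to-one across states
by Hungarian assignment on absolute Pearson correlation, with sign
alignment to the reference state.

For a matched component, each subject contributes the single column with
the highest |loading| (score), negated when the loading is negative (ties
break to the lowest column index and are logged).  Per-ROI one-way ANOVAs
across states with BH-FDR across the n ROIs produce the significance mask
and per-state group-average maps.

## State classification

Features concatenate the selected vectors of the four leading matched
components (length 4n per subject × state).  Within every training fold:
per-feature z-scoring, PCA retaining 95% of the variance, then a linear
one-vs-rest SVM (C = 1).  Evaluation is stratified, seeded 5-fold
cross-validation; accuracy, the confusion matrix (rows = true class) and
per-class ROC/AUC from the held-out signed decision values are reported.
PCA and scaling are fit strictly inside each training fold — corrupting
held-out rows provably changes nothing about the fitted transforms.

## Synthetic cohorts

The generator mirrors the target study's shape: four states
(awake / light / deep / recovery), N subjects per state sharing a single
state-level system, 256-sample rest and 155-sample stimulus runs at
TR = 2 s (`T = 255 / 154` transitions under the `k = 0..T` convention),
n = 30 ROIs at desk scale (n = 100 available for demos).

- **Systems.**  `make_stable_system` builds a real `A = V D V^{-1}` from a
  planted eigenvalue spec (real canonical blocks) and a random orthogonal
  basis (normal `A` by default, so modal projections are isometries; a
  non-normality knob exists for robustness work).  `make_modular_system`
  confines eigenvector support to disjoint 6-ROI blocks with block-local
  orthogonal mixing — eigenvector-magnitude features then cluster exactly
  by block.  Every conjugate pair receives a unique eigenvalue
  (block-level magnitudes 0.78–0.92, within-block spread ±0.01, unique
  angle grid): repeating identical eigenvalues across blocks makes the
  fitted matrix near-degenerate and estimation noise mixes eigenvectors
  across blocks, destroying cluster recovery; multiplicity > 1 likewise
  makes single-run identification genuinely rank deficient.
- **Noise.**  `w[k] ~ N(0, noise_sd² I)` i.i.d. (the minimal assumption
  consistent with least-squares fitting), default `noise_sd = 0.1` on
  z-scored-scale signals.  Initial states are drawn from approximate
  stationarity by a 100-sample discarded burn-in, avoiding transient bias.
- **State effects.**  `make_state_ensemble` shifts planted eigenvalue
  magnitudes/angles per state while sharing the eigenvector basis — the
  deep state's default `−0.15` magnitude shift on one block is the planted
  "stabilisation under deep sedation".
- **Inputs.**  `make_sparse_inputs` plants white ±amplitude impulses with
  an exact nonzero count; `make_block_inputs` plants sustained boxcar
  events.  The distinction matters: white impulses are uncorrelated with
  the lagged state, so unaccounted impulses add excitation as much as
  equation noise and barely bias one-step estimation, whereas sustained
  (stimulus-like) inputs correlate with the regressor and produce the
  genuine bias that motivates rest-based estimation of `A`.  The bias
  experiment therefore uses boxcar drivers at group level.
- **Input-map cohorts.**  `planted_input_profiles` gives every subject one
  tight stimulus-locked map `w1` (subject noise 0.05) plus two shared
  secondary patterns with higher inter-subject variability (0.25).  The
  variability asymmetry makes `w1` the unambiguous leading component
  (unit-norm columns split energy between pattern and noise, so noisier
  patterns carry less second-moment weight) and keeps the max-|loading|
  selection non-adaptive — selecting among near-identical copies of the
  same pattern provably distorts ANOVA calibration.  The secondary
  patterns anchor the cross-state Hungarian match and are orthogonalised
  against both `w1` and the flip direction.  The deep-state change is a
  sign flip of `w1` (a Rademacher pattern) on the planted ROIs: exactly
  norm-preserving, each planted ROI moves by `2/√n`, untouched ROIs are
  bit-identical under the gauge.

What the generator does **not** emulate: hemodynamic convolution,
physiological/motion artifacts, spatial autocorrelation of real parcels,
inter-subject anatomical variability, and non-stationarity.  Passing tests
therefore validate the estimators and statistics under the model's own
assumptions — they do not certify performance on real fMRI, where the
model is at best an approximation.  The study's empirical noise scale is
unknown; `noise_sd` is a test parameter, not a claim.

## Validation experiments (tests and `scripts/acceptance.py`)

All validation runs on seeded synthetic cohorts at the sizes above, chosen
so the full suite runs in minutes on one CPU; every number is recomputed
at run time.  Highlights of the design where it was genuinely open:

- Group-vs-single and bias comparisons use the one-step dialect for both
  arms (a like-for-like comparison at the pipeline default).
- Null calibration of the repeated-clustering statistics is averaged over
  four independent cohorts × 50 repetitions: within one cohort every
  repetition re-clusters the same fitted eigenvalues, so independent
  cohorts carry the calibration information.
- The per-ROI ANOVA power study reports the mean sensitivity and false
  discovery proportion over 20 planted-cohort replicates.
- End-to-end determinism reruns the demo pipeline into a fresh directory
  and compares every artifact byte for byte (the run log, which records
  wall-clock timings, is the one excluded file).

## Known limitations

- Free-run group estimation can fail on long stochastic runs (by design it
  fits the transient); use the one-step dialect there.
- Columns of `B` are identified only up to permutation/sign/scale;
  cross-cohort comparisons must go through the unit-column gauge and the
  matched-component machinery, or use subspace metrics.
- The alternating fit converges slowly in its gauge directions (objective
  plateaus while `B`/`U` rescale); the subspace stabilises long before the
  literal convergence flag — bounded alternation counts are appropriate.
- ANOVAs treat modes (or subjects) as independent observations; for modes
  of one fitted group-level matrix this is an approximation, partially
  mitigated by the conjugate-pair deduplication, and the reliability rates
  should be read as descriptive summaries rather than exact error rates.
- p > number of true input channels is benign (extra columns shrink to
  zero under the l1 penalty); p too small folds drivers together.
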