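# neuromodes

Eigenmode and unknown-input analysis of linear time-invariant (LTI) brain
dynamics from parcellated BOLD time series.

## The problem

How do large-scale brain dynamics change as consciousness fades under
sedation, and what external drivers shape the brain's response to a
stimulus in each state?  `neuromodes` addresses both questions with a
single dynamical model of parcellated fMRI signals
(ROI-by-time matrices, e.g. XCP-D `*_timeseries.tsv` output at TR = 2 s):

```
x[k+1] = A x[k] + B u[k] + w[k]
```

where `x[k] ∈ R^n` is the BOLD signal across `n` ROIs, `A` the coupling
(dynamics) matrix, `u[k] ∈ R^p` unknown low-dimensional external inputs
entering through the spatial map `B ∈ R^{n×p}`, and `w[k]` process noise.

The analysis proceeds in stages, each exposed as an importable module:

1. **System identification** (`neuromodes.sysid`).  `A` is estimated from
   resting runs — where external drive is minimal, because unaccounted
   inputs bias the estimate — either by closed-form one-step least squares
   pooled over subjects or by quasi-Newton minimisation of the free-run
   (simulated-trajectory) group cost.  Holding `A` fixed, stimulus runs
   are decomposed into sparse inputs `U` and their map `B` by alternating
   convex steps on `Σ_k ||z[k] − x[k]||² + λ||U||₁ + λ||B||₁` subject to
   `z[k+1] = A z[k] + B u[k]` (λ = 0.5, p = 10 by default; the input
   dimension can be chosen from the residual PCA spectrum).
2. **Eigenmodes** (`neuromodes.eigenmodes`).  Each eigenvalue
   `λ_i = |λ_i| e^{iθ_i}` of `A` gives a spatial mode (its eigenvector)
   with oscillation frequency `f_i = θ_i / (2π·dt)` Hz and damping rate
   (stability) `ρ_i = ln|λ_i| / dt` s⁻¹; `|λ_i| < 1` decaying, `> 1`
   growing, `≈ 1` meta-stable.  `z = V*x` projects data onto the modes.
3. **Cluster statistics** (`neuromodes.cluster_stats`).  Eigenmodes of all
   condition groups are pooled and repeatedly clustered (k-means on
   eigenvector magnitudes, k = 3…20); centroids are aligned across
   repetitions with the Hungarian algorithm on a negated-correlation cost,
   and per-cluster ANOVAs (with Cohen's f and Benjamini–Hochberg FDR) test
   whether stability or frequency shifts across states.  The percentage of
   repetitions that stay significant is the reliability proxy.
4. **Input patterns** (`neuromodes.input_patterns`).  Per state, every
   subject's unit-norm `B` columns are pooled and decomposed by PCA;
   components are matched across states (Hungarian, |correlation|), each
   subject contributes its highest-|loading| column (sign-flipped if the
   loading is negative), and per-ROI ANOVAs with FDR flag regions whose
   stimulus-driven input differs across states.
5. **State classification** (`neuromodes.classify`).  A linear SVM on the
   concatenated selected vectors of the four leading matched components,
   with per-training-fold z-scoring and PCA (95% variance), stratified
   5-fold cross-validation, confusion matrix and per-class ROC/AUC.

A first-class synthetic-data generator (`neuromodes.synthetic`) emulates
the target study's shape — N subjects × 4 sedation states, 256-sample rest
and 155-sample stimulus runs at TR = 2 s — from known systems with planted
eigenvalue shifts and sparse inputs, so every stage can be validated
against a recoverable truth.

## Worked example

`examples/` holds one short script per capability.  For instance,
recovering sparse stimulus drivers (`examples/04_unknown_inputs.py`):

```
$ python examples/04_unknown_inputs.py
input-support F1 with the true map given = 0.96 (timing/channel of the sparse drivers)
alternating fit: objective 464.8 -> 60.3 over 30 alternations (never increases)
span(B) recovered to 6.0 deg principal angle (<10 deg means the planted input subspace was found)
```

The F1 of 0.96 says the l1-penalised estimator found the timing and
channel of essentially every planted input impulse; the 6° principal angle
says the alternating fit, given only the data and the rest-derived `A`,
recovered the planted input subspace.  Detecting planted state effects in
eigenmode stability (`examples/03_cluster_state_effects.py`) prints, for
the cluster carrying a planted deep-sedation stabilisation,

```
cluster   measure  significance_rate
      2 stability              100.0
      2 frequency                0.0
```

i.e. the stability shift is detected in 100% of 200 clustering repetitions
while frequency stays at the null — magnitudes, not angles, were shifted.

## Command line

The full pipeline is also shell-runnable:

```bash
neuromodes run-all --config demo.json --seed 1
```

with stage subcommands `simulate`, `fit-a`, `eigenmodes`, `cluster-stats`,
`fit-inputs`, `input-pca`, `classify`.  Configurations are JSON or YAML
(see `neuromodes.pipeline.demo_config` for the desk-scale demo: n = 30
ROIs, 8 subjects, 4 states, 200 clustering iterations).  All artifacts are
deterministic TSV/JSON stamped with the config hash and seed; rerunning
with the same seed reproduces them byte for byte.

## Documentation

`docs/methods.md` describes the model, estimation procedures, statistical
machinery, generator design and known limitations.
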