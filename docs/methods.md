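# Methods

## Model

Two nonnegative, subject-aligned matrices are factorized jointly: `M`
(subjects × regions) holds two-visit brain-volume loss, `X` (subjects ×
tasks) two-visit severity increase on neuropsychological subtasks, both
column-min-max normalized to [0, 1]. The coupled factorization

```
L_NMF(V, Y, W) = ||M − VY||² + ||X − VW||² + ω (||V||₁ + ||Y||₁ + ||W||₁)
```

with V, Y, W ≥ 0 shares the subject-membership factor V between modalities,
so each latent component ("computational phenotype") couples a pattern of
regional atrophy (row of Y) with a pattern of cognitive decline (row of W).
Memberships are graded, as in fuzzy clustering: a subject can express
several phenotypes at once.

The supervised extension adds, with weight λ, the hinge losses of three
linear SVM heads on `[V, demo]` (demo = inter-visit interval in years, sex,
age, standardized over the supervised training subjects), one per diagnostic
contrast (AD vs MCI, AD vs CN, MCI vs CN), each trained on a stratified 80%
subject split drawn once per fit. The held-out 20% is the evaluation set
for AUC. Hinge losses are averaged within each contrast by default
(`hinge_aggregate="mean"`); the summed form is available but at desk scale
lets the supervised term overwhelm the reconstruction terms and degrade
held-out discriminability.

Key assumptions: deterioration is monotone (negative deltas are measurement
or treatment artifacts and are clipped to zero; ventricles invert), the
two modalities share one membership structure, and severity orientation per
task instrument is known (declared in a `FeatureDirectionMap`; the shipped
battery maps ADAS-Cog and FAQ items as gain-is-signal, MMSE items as
loss-is-signal).

## Optimization

`(V, Y, W)` are updated by projected adaptive-gradient steps with the heads
held fixed; heads are refit from scratch (deterministic linear SVM, C = 1)
at iteration 0 and every `svm_refit_every = 200` iterations, and once more
on the final memberships (plus a pooled AD+MCI-vs-CN head used only for
evaluation). Defaults: learning rate 0.05, 1000 iterations, no early
stopping (an optional relative-change tolerance is off by default). The
hinge subgradient is zero at the kink and flows only into membership rows of
supervised training subjects.

Numerical choices that matter:

- **Initialization** — NNDSVD on the stacked matrix `[M | X]` with small
  seeded random fill of zeros (`init="nndsvdar"`). Random uniform
  initialization (`init="uniform"`, scaled so E[VY] matches the data mean)
  is kept as an option, but its basin-to-basin scatter is larger than the
  effect of ω = 0.1, which makes paired variant comparisons noisy.
- **Optimizer** — Adam by default; Adagrad (`optimizer="adagrad"`) is
  available but its monotonically decaying steps leave desk-scale fits
  visibly under-converged within 1000 iterations.
- **Scale equilibration** — after every step the exact l1-minimizing
  diagonal rescale `(V/c, cY, cW)` with
  `c_r = sqrt(|v_r|₁ / (|y_r|₁ + |w_r|₁))` is applied. The reconstruction
  is invariant under this rescale and the l1 term is minimized by it, so it
  is an exact descent step along the scale ambiguity of the objective.
  Without it the penalty spends the whole iteration budget rebalancing
  ||V||₁ against ||Y||₁ + ||W||₁ (V has many more entries per component)
  instead of sparsifying involvements. Optimizer state is rescaled
  consistently.
- **Projection** — entries are clamped to [0, ∞) after every step; the l1
  subgradient is the constant ω on the nonnegative orthant.
- **Degenerate inputs** — constant delta columns normalize to zero (no
  phenotype signal); all-zero involvement rows score Gini sparsity 1 and
  cosine 0 by convention; a single-class AUC test set and an R < 2 overlap
  are flagged missing rather than raised.

## Evaluation metrics

- **AUC** per stage contrast, computed by the Mann–Whitney rank statistic
  (ties count ½) on head decision values over held-out subjects. The
  AD+MCI-vs-CN contrast has no head inside the objective; a post-hoc head is
  trained on the pooled training subjects for it.
- **Sparsity** — mean Gini sparsity index over the rows of Y and W
  (0 = uniform involvement, (n−1)/n → 1 = one dominant feature).
- **Overlap** — mean pairwise cosine similarity between phenotype rows,
  averaged within Y and within W, then across the two. The literal
  feature-column reading is available (`vectors="feature"`) but measures
  region-pair rather than phenotype-pair similarity, contradicting the
  metric's purpose, so phenotype rows are the default.
- **MSE** — per-entry mean squared reconstruction error, per modality.

The comparison harness fits the four variants (plain, +SVM, +l1, +l1+SVM)
on identical resampled 80/20 splits per trial, so within-trial contrasts are
paired, and reports mean (sd) over trials.

## Phenotype profiling

Candidate phenotypes are screened by one multivariate logistic regression
per stage contrast — the binary outcome on all membership columns plus the
inter-visit interval (sicker subjects have shorter follow-up; the covariate
absorbs that bias) — keeping phenotypes with a Wald p ≤ α (default 0.05,
optional Benjamini–Hochberg across phenotypes, off by default to match the
unadjusted screening convention). Prevalence is the fraction of subjects
with membership > 1e−5. Biomarker change between visits is tested with a
membership-weighted paired t-test: with normalized weights w̃ over
differences d, d̄ = Σ w̃ᵢ dᵢ, s² = Σ w̃ᵢ(dᵢ − d̄)² / (1 − Σ w̃ᵢ²),
n_eff = 1 / Σ w̃ᵢ², t = d̄ / √(s²/n_eff) on n_eff − 1 degrees of freedom,
flagged at p < 0.1. The (1 − Σ w̃ᵢ²) correction makes uniform weights reduce
exactly to the ordinary paired t-test; fewer than two positive-weight
subjects (or n_eff ≤ 1) yields a flagged missing result rather than a
number. An unpaired weighted Welch variant is available behind
`paired=False`. Expert curation of the screened candidates (merging,
naming, clinical reading) is deliberately left to the user.

## Synthetic cohorts

The generator plants `V_true` (absolute Gaussians with group-dependent mean
shifts of size `label_separation` on designated axes, so axis r favors
diagnostic group r mod 3), and row-sparse nonnegative `Y_true`, `W_true`
(`factor_sparsity` fraction of entries zeroed per row). Products are scaled
into [0, 1] at generation, Gaussian noise (`noise_sd`) is added, values are
clipped at zero and column-min-max normalized — the same
measure-then-clip-then-normalize order as real delta preparation.
Demographics: gamma inter-visit interval (shape 4, scale 0.5 years),
Bernoulli sex, Gaussian age (73 ± 7). One root seed feeds independent
sub-streams per block, so outputs are bitwise reproducible and adding a
field cannot shift existing draws.

Defaults are 300 subjects (30/40/30% AD/MCI/CN), 40 regions, 25 tasks, true
rank 4, noise 0.05, factor sparsity 0.3, label separation 1.0 — a desk-scale
emulation of a multi-hundred-subject two-visit cohort. What it does *not*
emulate: item-level test response processes, site and scanner effects,
missing-data mechanisms, more than two visits, correlated measurement error,
and the extreme zero-inflation of real clipped deltas. Passing tests
therefore demonstrate correctness of the machinery and the qualitative
behavior of the regularizers, not clinical validity on real cohorts.

The comparison harness and the acceptance script fit at rank 10 on this
rank-4 cohort: a rank above the truth gives the l1 penalty redundant
components to prune, the regime a deliberately generous rank (such as 30 on
real data of unknown rank) represents, while keeping 4 variants × 10 trials
comfortably inside a desktop run. The paired l1 effect on reconstruction
error is asserted on the combined (M plus X) error: at ω = 0.1 the penalty
can redistribute error between modalities, but the total rises consistently.

## Known limitations

- No out-of-sample membership projection for unseen subjects; the
  factorization is transductive.
- The supervised term affects only training subjects' membership rows, so
  with a strong hinge weight (`hinge_aggregate="sum"` at λ ≈ 1) training
  memberships can drift away from the held-out distribution and hurt
  transfer; the mean-aggregated default avoids this.
- Wald p-values from the logistic filter are unadjusted for multiplicity by
  default and can be non-estimable under perfect separation (flagged, not
  raised).
- The Gini/overlap/MSE trade-off is reported, not optimized; rank and ω
  selection beyond a grid of variants is out of scope.
- Min-max normalization subtracts the column minimum and thus adds one
  rank-one component to an otherwise exactly low-rank matrix; exact-rank
  recovery experiments should generate with `normalize=False`.
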