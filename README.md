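# phenofactor

Multimodal computational phenotyping of progressive neurodegenerative
disease by **supervised coupled nonnegative matrix factorization (C-NMF)**.

Progression in Alzheimer's disease shows up in two modalities at once:
regional brain volumes shrink on longitudinal MRI, and neuropsychological
test (NPT) scores worsen. `phenofactor` turns two-visit measurements of both
into *computational phenotypes* — latent patterns that tie together a set of
brain regions, a set of cognitive tasks, and the graded memberships of
subjects to each pattern. It is written for biostatisticians and imaging
researchers who have subject-aligned longitudinal feature tables (e.g.
FreeSurfer volumes and ADAS-Cog/MMSE/FAQ subtask scores) and diagnostic
stage labels (AD / MCI / CN).

## The model

Inputs are two nonnegative, subject-aligned delta matrices on [0, 1]:
`M` (subjects × regions, volume **loss**) and `X` (subjects × tasks,
severity **increase**). Both are factorized with a shared subject factor:

```
L(V, Y, W) = ||M − VY||² + ||X − VW||²
           + ω (||V||₁ + ||Y||₁ + ||W||₁)          V, Y, W ≥ 0
           + λ · (loss_ADvsMCI + loss_ADvsCN + loss_MCIvsCN)
```

- `V` (subjects × R): membership of each subject to each phenotype;
- `Y` (R × regions), `W` (R × tasks): involvement of regions and tasks;
- the l1 term (weight `ω`, reference value 0.1) shrinks unimportant
  involvements so phenotypes stay interpretable;
- the supervised term is the hinge loss of three linear SVM heads
  `f([V, demo]) = θ·[V, demo] + b` (demo = inter-visit interval, sex, age),
  trained on a stratified 80% subject split, pushing memberships to separate
  diagnostic stages.

Optimization alternates projected adaptive-gradient updates of `(V, Y, W)`
(default Adam, lr 0.05, 1000 iterations, clamped to ≥ 0 after every step)
with SVM head refits every 200 iterations.

Around the factorization the package provides the full pipeline:

| module | what it does |
| --- | --- |
| `delta_prep` | forward-fill of task scores, imaging/task visit alignment, direction-clipped deltas (ventricles gain, everything else loses; severity-oriented task scores), column min-max normalization |
| `synthetic` | coupled cohorts with planted nonnegative factors, separable labels and demographics, truth retained for recovery scoring |
| `cnmf` | the factorization: objective, hinge loss, SVM heads, projected adaptive-gradient fit |
| `evaluation` | held-out AUC (4 stage contrasts), Gini sparsity, phenotype overlap, reconstruction MSE, and the 4-variant × multi-trial comparison harness |
| `profiling` | prevalence (membership > 1e−5), top contributing features, multivariate logistic filtering with interval covariate, membership-weighted paired t-tests |
| `io` / `cli` | CSV dialect, YAML config resolution, `phenofactor` subcommands |

## Worked example

Fit four phenotypes to a synthetic 300-subject cohort with planted rank-4
structure (`examples/03_fit_phenotypes.py`):

```python
import phenofactor as pf

m, x, cohort, truth = pf.generate(pf.SyntheticConfig(seed=42))
result = pf.fit(m, x, cohort, pf.FitConfig(rank=4, omega=0.1, lambda_sup=1.0, seed=0))
```

prints

```
objective: 517.9 -> 346.8 (recon_M 176.51, recon_X 136.69, l1 32.43, hinge 1.12)
mean matched cosine to planted factors: 0.921
P1: top regions region_024 (1.94), region_031 (1.76), region_019 (1.54)
```

The objective falls monotonically from its initial value; the Hungarian-
matched cosine of 0.92 between fitted and planted (Y, W) rows means each
recovered phenotype corresponds to one planted pattern almost exactly; the
top-feature lists are what a profile of a real cohort would report per
phenotype. The regularization-variant comparison
(`examples/04_compare_variants.py`, 5 resampled trials, mean (sd)):

```
                auc_AD_vs_CN         sparsity          overlap            mse_M
variant
cnmf         0.9895 (0.0077)  0.6314 (0.0047)  0.2945 (0.0052)     0.0101 (0.0)
cnmf-l1      0.9907 (0.0079)  0.7551 (0.0039)  0.1599 (0.0049)  0.0096 (0.0001)
cnmf-l1-svm  0.9907 (0.0079)  0.7535 (0.0013)  0.1608 (0.0019)     0.0096 (0.0)
cnmf-svm     0.9901 (0.0067)  0.6272 (0.0009)  0.2986 (0.0011)     0.0101 (0.0)
```

Adding the l1 penalty raises sparsity (0.63 → 0.76) and nearly halves
phenotype overlap (0.29 → 0.16) at a small cost in total reconstruction
error, while the supervised heads keep held-out discriminability — the
qualitative pattern the method is designed to produce.

The same pipeline is scriptable from a shell:

```bash
phenofactor simulate --seed 42 --out-prefix sim
phenofactor fit --m sim_M.csv --x sim_X.csv --cohort sim_cohort.csv \
    --rank 4 --variant cnmf-l1-svm --seed 0 --out run1/
phenofactor evaluate --m sim_M.csv --x sim_X.csv --cohort sim_cohort.csv \
    --variants all --trials 10 --rank 10 --seed 11 --out report/
phenofactor profile --run run1/ --cohort sim_cohort.csv
```

and `phenofactor prep` builds the delta matrices from raw two-visit tables
(see `examples/01_prepare_deltas.py`).

## Documentation

`docs/methods.md` describes the model and its assumptions, what the
synthetic generator does and does not emulate, the numerical choices in the
optimizer (initialization, scale equilibration, projection), and known
limitations.
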