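# depimpute

Covariate-driven weighted K-nearest-neighbor imputation of **entirely
missing paired samples** in expression matrices, together with a
differential-expression test that accounts for the statistical dependence
the imputation induces.

## The problem

In paired tumor/normal expression studies (e.g. miRNA profiling of a cancer
cohort) it is common for some subjects to lack one arm of the pair entirely
— no normal tissue was collected, so *every* feature of that subject's
normal sample is missing at once. Dropping those subjects (case deletion)
wastes the fully observed tumor arm and loses power. Imputing the missing
rows recovers power, but the imputed rows are **linear combinations of
observed rows**, so imputed and observed subjects are no longer independent
— and a paired t-test that pretends they are will overstate its evidence
and lose control of the false discovery rate.

`depimpute` implements both halves of the remedy, for analysts of paired
designs with whole-sample missingness:

1. **Covariate-KNN imputation.** Subjects are compared on fully observed
   demographic/lifestyle covariates: Euclidean distance over standardized
   continuous covariates and Manhattan distance over binary ones, each
   min-max scaled to [0, 1] and averaged into one between-subject
   dissimilarity. For a normal-missing subject *i* with sorted neighbor
   distances *D*<sub>i1</sub> ≤ … ≤ *D*<sub>ik</sub> and maximum distance
   *D*<sub>i(max)</sub> over all complete cases,

       w_il = 1 − D_il / D_i(max),      a_il = w_il / Σ_t w_it,

   and the missing row is the convex combination
   x̂<sub>ij</sub> = Σ<sub>l</sub> a<sub>il</sub> x<sub>i<sub>l</sub>j</sub>,
   or in matrix form X̂ = AᵀX with A the (N−S)×S weight matrix.

2. **Dependence-aware GLS paired t-test.** With subjects ordered complete
   cases first, the imputation induces the per-feature covariance structure
   (at unit variance)

       Sigma = [[ I,  A ],
                [ Aᵀ, AᵀA ]],

   and the tumor−normal differences D_j satisfy D_j = 1·μ_j + ε with
   Var(ε) = σ_j² V, V = I + Sigma. The GLS estimates

       μ̂_j = (1ᵀV⁻¹1)⁻¹ 1ᵀV⁻¹D_j,
       σ̂_j² = (D_j − 1μ̂_j)ᵀ V⁻¹ (D_j − 1μ̂_j) / (N−1),
       t_j = μ̂_j / sqrt( σ̂_j² (1ᵀV⁻¹1)⁻¹ ),

   referred to Student t with N−1 df and Benjamini–Hochberg adjusted across
   features. Setting V = I instead recovers the classical (dependence-
   ignoring) analysis.

A simulation framework reproduces the benchmark design that demonstrates
why this matters: the dependence-aware test keeps the empirical FDR below
the nominal level, the dependence-ignoring test does not.

## Worked example

```python
from depimpute import SimConfig, simulate_dataset, knn_impute_paired, run_de_analysis
from depimpute.evaluate import confusion_metrics

cfg = SimConfig(N=200, G=2000, missing_fraction=0.5, seed=7)
pes, cov, truth = simulate_dataset(cfg)          # 100 normal rows missing
res = knn_impute_paired(pes, cov, k=10)          # completed matrix + Sigma

for mode in ("dependent", "independent"):
    table = run_de_analysis(pes, imputation=res, mode=mode, alpha=0.05)
    m = confusion_metrics(table["significant"].astype(bool), truth.de_indicator)
    print(f"{mode:>11}: {int(table.significant.sum()):4d} features called, "
          f"TPR={m.tpr:.3f}, empirical FDR={m.fdr:.3f}")
```

prints

```
  dependent:  289 features called, TPR=0.703, empirical FDR=0.028
independent:  497 features called, TPR=0.910, empirical FDR=0.268
```

The dependence-ignoring analysis calls 208 more features, but over a quarter
of its calls are false discoveries (FDR 0.268 ≫ 0.05); the dependence-aware
analysis trades some power for a controlled FDR (0.028 ≤ 0.05). The
`examples/` directory has this and three more narrative scripts (imputation,
choosing k, the full benchmark grid).

## Command line

The same operations are exposed as a thin CLI:

```bash
depimpute simulate --n 200 --missing-fraction 0.5 --out-dir sim/
depimpute impute --normal sim/normal.tsv --tumor sim/tumor.tsv \
    --covariates sim/covariates.tsv --binary-cols gender,menopause --k 10 \
    --out-dir imputed/
depimpute test --normal sim/normal.tsv --tumor sim/tumor.tsv \
    --covariates sim/covariates.tsv --binary-cols gender,menopause \
    --mode dependent --alpha 0.05 --out de_table.tsv
depimpute study --grid "100:0.3;400:0.5" --reps 5 --out-dir study/
```

All I/O is delimited text (`NA` = missing); every output directory gets a
`manifest.json` with the effective config, seed and input checksums.

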