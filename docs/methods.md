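# Methods

## Setting and model

The package targets paired two-arm expression studies (tumor and normal
sample per subject, N subjects × G features) in which some subjects are
missing the normal arm **entirely** — whole-sample missingness, as opposed
to scattered missing cells. Partial rows are rejected at validation: the
method's covariance algebra is defined only for whole-sample missingness.
Imputation is justified when the missingness is MCAR or MAR given the
observed covariates; nothing in the package can rescue MNAR data.

Expression values are treated as already on the analysis scale (e.g.
log-transformed upstream); the package performs no normalization.

### Covariate distance

Subjects are compared only on fully observed covariates, split into a
continuous block (Euclidean distance) and a binary block (Manhattan
distance, i.e. a disagreement count). Each block is min–max scaled to
[0, 1] over its **off-diagonal** entries — so the structurally zero diagonal
cannot distort the range — and the blocks are combined as a weighted
average, default weights (0.5, 0.5).

Two choices here were genuinely open and are exposed as configuration:

- **Standardization of continuous covariates** before the Euclidean
  distance is ON by default. Covariates arrive in wildly different units
  (years, kcal, kg/m²); without standardization the largest-scaled column
  dominates the distance. With it, the aggregated distance is invariant to
  affine rescaling of any continuous column (a tested property).
- **Block weights** default to equal. No principled asymmetry suggests
  itself, and downstream results are insensitive to moderate changes.

Min–max scaling can break the triangle inequality; only symmetry,
nonnegativity and a zero diagonal are guaranteed (and asserted).

### Weighted KNN imputation and the induced covariance

For a normal-missing subject *i*, the k nearest complete cases are taken
(ties at the k-boundary broken in stable subject order, for determinism;
tied neighbors get equal weight anyway). With D_i(max) the maximum distance
from *i* over **all** complete cases — not just the selected k — the raw
weights w_il = 1 − D_il/D_i(max) are normalized to a_il summing to one, so
every imputed value is a convex combination of its neighbors' values. Edge
cases: a neighbor sitting exactly at D_i(max) keeps weight 0 (it is
retained, contributing nothing); a subject at distance 0 from everyone gets
uniform weights with a warning. Default k = 10; `k="auto"` gives the
square root of the complete-case count rounded to the nearest odd integer.

Because imputed rows are linear maps X̂ = AᵀX of observed rows, the joint
covariance of all N rows at unit feature variance is the block Gram
structure Sigma = [[I, A], [Aᵀ, AᵀA]] (complete cases ordered first; the
permutation is recorded so callers can map back). Sigma is stored at unit
variance; the per-feature σ_j² enters only in the test.

### The GLS paired t-test

Per feature, the tumor − normal differences follow D_j = 1 μ_j + ε with
Var(ε) = σ_j² V and V = I + Sigma. V is feature-independent, so it is
Cholesky-factored once; all G features are then tested in whitened
coordinates at O(N²) per feature. The estimates are the standard GLS ones
(μ̂ by weighted mean, σ̂² by the whitened residual sum of squares over
N − 1, t referred to Student t with N − 1 df, two-sided). Benjamini–
Hochberg adjusts across features; BH is used because plain FDR control is
wanted and no dependence-adapted procedure is required — under the
dependence-aware V the p-values are calibrated (their null uniformity is a
tested property).

V is positive definite by construction — Sigma = CᵀC with C = [I A] is a
Gram matrix, so I + Sigma has eigenvalues ≥ 1 — but the Cholesky check is
kept and raises rather than regularizing, as a guard against malformed
inputs.

Mode-specific conventions:

- **independent** uses V = I on the completed data. (Replacing Sigma by the
  identity gives V = 2I; t is invariant to scaling V, so V = I is
  equivalent and makes the mode coincide exactly with the classical
  one-sample t, a tested equivalence.)
- **case_deletion** analyzes the N − S complete pairs with V = I and
  df = N − S − 1 — the natural df for the reduced sample.
- The difference direction is tumor − normal; two-sided p-values make the
  sign convention immaterial.
- Zero residual variance (all differences identical) reports t = ±inf with
  p = 0 (t = 0, p = 1 when the common value is 0), with a warning.

## The synthetic-data generator

The generator emulates a paired miRNA cohort: every normal value and every
non-DE tumor value ~ N(2, 1.25²); a 20% fraction of tumor features is
shifted to mean 2.5 at the same SD; G = 2000 features; N ∈ {50…400};
10–50% of subjects lose their whole normal row, completely at random.

Covariates are made informative by construction: z = 20 features are drawn
from the truly-DE tumor set, and each of five continuous covariates is a
linear function of them (slopes uniform on [0.02·min, 0.02·max] of the
covariate's range, noise variance 10% of the covariate's variance) while
each of five binary covariates comes from a logistic model with slopes
U[−0.5, 0.5], min–max rescaled across subjects and thresholded at 0.5 (the
rescaling forces variability; an all-equal probability vector degenerates
to zeros with a warning). The slope interval is taken as
[frac·min, frac·max] of the covariate's range; the alternative reading
±frac·range would only flip some slopes' signs and does not change any
qualitative behavior. Linear predictors are not re-truncated to the
covariate's observed range. The DE feature set and the z drivers are
redrawn per replicate (seeded).

The base characteristics of the ten covariates (age mean 65 y, BMI mean 27
kg/m², …) are **synthetic stand-ins** for a cancer-cohort demographic
profile; they are overridable and nothing downstream depends on their
specific values.

What the generator does *not* emulate — and hence what passing tests do not
show about real data:

- Expression is exactly Gaussian and features are independent; real miRNA
  data are noisy, often non-normal, and co-expressed.
- Normal and tumor values of a subject are drawn independently, and the
  covariates are functions of **tumor** expression only. Covariate
  similarity therefore predicts tumor-profile similarity (a tested
  Spearman property) but carries no information about the *normal* values
  being imputed. Two consequences worth stating plainly:
  - The RMSE-vs-k profile (steep fall, flattening after k ≈ 10) is driven
    by the shrinking Σ_l a_il² variance term, not by neighbor relevance.
  - Under this generator covariate-KNN **cannot** beat a per-feature
    column-mean baseline on RMSE: KNN's error variance is
    σ²(1 + Σa²) ≈ σ²(1 + 1/k) against the baseline's σ²(1 + 1/(N−S)).
    The corresponding benchmark expectation in the acceptance suite fails
    honestly for this reason. On real cohorts where covariates do predict
    the missing arm, the comparison can go the other way.
- Missingness is MCAR whole-row; no MAR-on-covariates or MNAR mechanism is
  simulated.

Null-calibration runs keep the DE labeling machinery but set
mu_de = mu_null; scoring then treats the truth as all-null, since features
drawn from the same distribution are not differentially expressed.

## Numerical and reproducibility choices

- Weight normalization tolerance 1e-12 (tested); V factored once per
  analysis; per-feature work after factorization is a triangular solve.
- Text I/O prints 12 significant digits, making write/read round trips
  bit-identical for such representations; `NA` (case-sensitive) or an
  empty cell mean missing.
- Every randomized operation draws from a `numpy` Generator; studies spawn
  one child stream per (grid cell, replicate) from the top-level seed via
  `SeedSequence`, in a fixed order, so entire studies are bit-reproducible
  and methods sharing a replicate see identical data.
- Benchmark problem sizes: the headline grid cell is run at N = 400,
  G = 2000, 50% missing, k = 10 with 5 replicates; the k-sweep at N = 200,
  30% missing with 3 replicates; the RMSE grid at N ∈ {100, 400} ×
  {10%, 50%} with 3 replicates. Replicate means are stable at these sizes
  because each replicate already averages over 2000 features (and, for
  RMSE, over ≥ 10⁴ imputed cells).

## Known limitations

- Only two covariate blocks (continuous, binary) are supported; ordinal
  covariates must be coerced to one of them.
- The test assumes a common per-feature variance across subjects and
  Gaussian errors; no moderated (empirical-Bayes) variance shrinkage is
  applied.
- Feature-space KNN (imputing scattered cells from similar *features*) is
  out of scope; the package imputes whole subject rows from similar
  *subjects*.
- Multiple-imputation approaches (MCMC, EM-with-bootstrap) are not
  implemented; case deletion and column-mean filling are the only built-in
  comparators.
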