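"""Benchmark the analysis modes over a (sample size x missingness) grid.

For each grid cell and replicate: simulate paired expression with linked
covariates, mask normal rows, impute by covariate-KNN, and test for
differential expression with the dependence-aware GLS test, the
dependence-ignoring test, and case deletion. Reports mean power (TPR) and
empirical FDR per cell and method.
"""

from depimpute import run_study

report = run_study(
    grid=[(100, 0.3), (200, 0.5)],
    methods=("knn_dependent", "knn_independent", "case_deletion", "full"),
    n_reps=3,
    seed=99,
)

summary = report.groupby(["N", "missing_pct", "method"])[["tpr", "fdr"]].mean().round(3)
print(summary)

print("\nReading the table: 'full' is the no-missingness upper bound on power;")
print("'knn_independent' approaches it but its FDR column exceeds the nominal")
print("0.05; 'knn_dependent' gives up a little power to keep FDR controlled;")
print("'case_deletion' is valid but least powerful, using only complete pairs.")
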