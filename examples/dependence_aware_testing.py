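"""Differential-expression testing that accounts for imputation-induced
dependence.

Imputed rows are linear combinations of observed rows, so after imputation
the subjects are no longer independent. This script runs the paired GLS
t-test twice on the same imputed data set — once with the induced covariance
V = I + Sigma (dependence-aware) and once pretending the imputed values are
real observations (V = I) — and counts the features each calls significant.
"""

from depimpute import SimConfig, knn_impute_paired, run_de_analysis, simulate_dataset
from depimpute.evaluate import confusion_metrics

cfg = SimConfig(N=200, G=2000, missing_fraction=0.5, seed=7)
pes, cov, truth = simulate_dataset(cfg)
res = knn_impute_paired(pes, cov, k=10)

for mode in ("dependent", "independent"):
    table = run_de_analysis(pes, imputation=res, mode=mode, alpha=0.05)
    m = confusion_metrics(table["significant"].astype(bool), truth.de_indicator)
    print(f"{mode:>11}: {int(table.significant.sum()):4d} features called, "
          f"TPR={m.tpr:.3f}, empirical FDR={m.fdr:.3f}")

print("\nThe dependence-ignoring analysis calls more features (higher TPR) but a")
print("large share of its extra calls are false: its empirical FDR exceeds the")
print("nominal 0.05, while the dependence-aware analysis stays below it.")
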