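"""Pick the neighbor count k by sweeping imputation RMSE.

Simulates paired data at N = 200 subjects with 30% missing normal rows and
imputes every replicate at a range of k values. RMSE falls steeply for small
k (few neighbors = noisy convex combinations) and flattens after about 10,
which is why k = 10 is the default.
"""

from depimpute import k_sweep

sweep = k_sweep(N=200, missing_fraction=0.3, ks=(1, 2, 5, 10, 15, 20, 25),
                n_reps=3, seed=11)
mean = sweep.groupby("k")["rmse"].mean()

print("k    mean RMSE")
for k, v in mean.items():
    print(f"{k:<4d} {v:.4f}")

print(f"\ndrop from k=2 to k=10:  {mean[2] - mean[10]:.4f}")
print(f"drop from k=10 to k=25: {mean[10] - mean[25]:.4f}")
print("The improvement beyond ten neighbors is marginal; imputation is")
print("insensitive to k in the 10-25 range.")
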