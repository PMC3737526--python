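"""Removing a known batch effect from correlation features.

Two classes split across two laboratories; each lab adds its own
gene-wise offset, so first-order correlations group samples by lab, not
by disease class.  The batch-indicator update C1' = C1 + lambda * B
(-1 for same-lab pairs, +1 for different-lab pairs) penalises same-lab
similarity before iterating.
"""

import ipcc

data, batch_of = ipcc.simulate_batch_confounded(
    n_classes=2, n_batches=2, samples_per_class=20,
    relevant_genes_per_class=5, noise_fold=10, sigma=0.3,
    batch_shift=1.0, seed=4,
)
X, labels = data.expression, data.labels
sids = X.sample_ids

plain, _ = ipcc.ipcc(X, max_order=4, tol=1e-300)
design = ipcc.BatchDesign(batch_of=batch_of, lam=0.5)
adjusted = ipcc.ipcc_batch(X, design, max_order=4)

for name, feats in [("unadjusted", plain), ("batch-adjusted", adjusted)]:
    acc = ipcc.clustering_accuracies(feats[-1], labels, sids, k=2, n_runs=50, seed=2)
    print(f"{name:>15} order-4 features: mean k-means accuracy {acc.mean():.3f}")

batch_as_truth = ipcc.clustering_accuracies(plain[-1], batch_of, sids, k=2,
                                            n_runs=50, seed=2)
print(f"{'unadjusted':>15} order-4 features recover the *batch* labels "
      f"with accuracy {batch_as_truth.mean():.3f}")

# Without adjustment the iterated features lock onto the laboratory
# split (batch recovery near 1.0, class recovery near chance 0.5); the
# adjusted features shift accuracy back towards the disease classes.
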