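# ipcc — iterative Pearson correlation features for expression data

Disease class discovery from gene-expression profiles suffers from the
curse of dimensionality: tens of thousands of genes, a few dozen to a few
hundred samples, and most genes irrelevant to the classes of interest.
`ipcc` implements an unsupervised feature-extraction method that replaces
each sample's expression profile by its vector of Pearson correlations
with all samples, and then *iterates* that construction.

Given an expression matrix with profiles x_i (sample i across n genes),
the first-order features of sample i are

    C1[i, j] = r(x_i, x_j)      (Pearson correlation, j = 1..m)

and the order-t features are obtained by re-correlating the rows of the
previous matrix:

    Ct[i, j] = r(C_{t-1}[i, :], C_{t-1}[j, :])

Off-diagonal entries converge rapidly to +1 or -1 as t grows, which
amplifies weak sample-similarity structure buried under noise genes and
reduces dimensionality from n genes to m samples. The package also
includes a supervised batch-effect adjustment of the first-order matrix
(`C1' = C1 + λ·B` with a batch-indicator matrix B), the simulation
generators used to characterise the method, and the evaluation battery
(repeated k-means with Hungarian-matched accuracy, leave-one-out Gaussian
naive Bayes, intra/inter-class similarity statistics, Welch t-tests).

Intended users: computational biologists analysing bulk or single-cell
expression matrices who want a drop-in sample-similarity representation
for clustering or classification, plus a reproducible harness to study
when it helps.

## Worked example

```python
import ipcc
from ipcc.simulate import SimulationSpec

spec = SimulationSpec(noise_fold=50, sigma=0.3, seed=7)   # 306 genes, 150 samples
data = ipcc.simulate_class_data(spec)
sids = data.expression.sample_ids

acc = ipcc.clustering_accuracies(data.expression, data.labels, sids,
                                 k=3, n_runs=100, seed=1)
print(f"order 0 (raw genes): {acc.mean():.3f}")

features, trace = ipcc.ipcc(data.expression, max_order=5, tol=1e-300)
for C in features:
    acc = ipcc.clustering_accuracies(C, data.labels, sids, k=3, n_runs=100, seed=1)
    print(f"order {C.order} (correlation): {acc.mean():.3f}")
```

prints

```
order 0 (raw genes): 0.830
order 1 (correlation): 0.974
order 2 (correlation): 0.977
order 3 (correlation): 0.991
order 4 (correlation): 0.987
order 5 (correlation): 1.000
```

Each number is the mean fraction of the 150 samples that 100 restarts of
k-means assign to the correct predefined class (best one-to-one mapping
of clusters to classes). On the raw 306-gene features, noise genes leave
k-means stuck in local optima (83%); on the iterated correlation
features the three classes are recovered essentially perfectly.

The `examples/` directory holds one short script per capability: toy
convergence, simulated clustering, naive Bayes classification, batch
adjustment and the null-data negative control. A thin CLI exposes the
same pipeline from the shell:

```bash
ipcc simulate --sigma 0.3 --fold 50 --seed 7 --out-prefix sim
ipcc transform --input sim.expression.tsv --order 5 --out-prefix feats
ipcc evaluate cluster --features feats.order3.tsv --labels sim.labels.tsv \
     --k 3 --runs 100 --seed 1
```

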