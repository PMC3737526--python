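# Methods

## The transform

An expression data set is an n-genes × m-samples matrix X. The
first-order correlation features are the m × m matrix C1 with
C1[i, j] = r(x_i, x_j), the Pearson correlation between the profiles of
samples i and j. Treating row i of C1 as a new feature vector for
sample i, the order-t features are Ct[i, j] = r(C_{t−1}[i, :],
C_{t−1}[j, :]). By construction every Ct is symmetric with unit
diagonal and entries in [−1, 1]; these invariants are asserted at every
order in the test suite. Because Pearson correlation is invariant to a
positive affine rescaling of either argument, the features are
unchanged when any sample's profile is replaced by a·x + b (a > 0) —
the representation depends on the *shape* of a profile, not its scale
or location.

Empirically the off-diagonal entries converge to ±1 within a handful of
iterations. For the archetypal 3-sample configuration with pairwise
correlations (−1, x, −x), one iteration maps the weak entry x to
f(x) = (4x/3)/√(x⁴/3 + 10x²/9 + 1/3), which is strictly increasing on
(0, 1) with fixed point 1; the test suite verifies numerically that the
recursion saturates (1 − 1e−6) within 20 steps from any starting point
in (0, 1). No general convergence proof is attempted: matrices whose
rows are exactly orthogonal (e.g. the 3 × 3 pattern with a fully
uncorrelated third sample) are non-trivial fixed points, so the limit
is configuration-dependent.

Orientation: expression files store samples as columns, while the
transform correlates samples; the loader transposes internally. Entries
are clipped to [−1, 1] after each iteration purely to absorb floating
point overshoot; no other regularisation is applied.

## Degenerate inputs

- A constant expression profile makes Pearson correlation undefined
  (zero norm). The transform raises by default; `on_constant="drop"`
  removes the offending samples instead. Silently emitting 0 would
  corrupt subsequent iterations, so it is never done.
- A constant row of an intermediate matrix likewise raises.
- m = 2 is accepted for the first-order matrix but rejected for
  iteration: every row of a 2 × 2 correlation matrix has only two
  entries and the row-correlation map collapses to ±1 or degenerates.
- Iteration stops early when the maximum absolute change between
  successive orders falls below `tol` (default 1e−9). The primary
  control is `max_order`; `tol` is a safety stop for matrices that hit
  a fixed point.

A Spearman kernel is available for all operations as an exploratory
option (ranks replace values before correlating); the rapid ±1
convergence that motivates the method is specific to the Pearson
kernel, and the default is Pearson everywhere.

## Batch adjustment

With known batch membership, the first-order matrix is updated
additively, C1' = C1 + λ·B, where B[i, j] is `within_value` (default
−1) for same-batch pairs and `between_value` (default +1) otherwise,
and λ ≥ 0 (default 0.5) weighs the adjustment; iteration then proceeds
from C1'. The defaults penalise same-laboratory similarity and reward
cross-laboratory similarity. Only the within/between *contrast*
matters: adding one constant to every entry changes nothing from order
2 on, because the row-correlation map is location-invariant (this is
tested directly). The diagonal of B is treated as within-batch and the
diagonal of C1' is deliberately not forced back to 1 — the following
iteration is insensitive to a shared diagonal convention, and forcing
it would be an extra undocumented step. λ = 0 reduces exactly to the
unadjusted pipeline.

## Synthetic data

`simulate_class_data` emulates a noisy multi-class expression study:
3 classes × 50 samples by default, 2 relevant genes per class drawn
N(1, σ) for that class's samples, and noise genes drawn N(0, σ) for
everyone, with `noise_fold` ∈ {0, 10, 50, 100} times as many noise
genes as informative genes (150 samples × 6/66/306/606 genes). Relevant
genes *outside* their own class are drawn N(0, σ): only the in-class
distribution is part of the design, and matching the noise distribution
outside the class is the minimal choice that creates class structure at
all. σ defaults to 0.3, the middle of the 0.1–0.5 range the simulation
study sweeps. Classes are contiguous in sample order. One RNG stream
per data set, seeded explicitly; replicate seeds are derived from the
base seed.

`simulate_null_data` produces structureless 150 × 150 matrices from a
standard normal, uniform [0, 1], or discrete uniform {−1, 0, 1}
distribution, as negative controls.

`simulate_batch_confounded` adds a laboratory effect to the class
design: each batch receives a fixed offset vector drawn N(0,
batch_shift) *per gene*, added to all of that batch's samples, with
batches interleaved across classes. A single constant shared by all
genes would be invisible to Pearson correlation (it only moves a
profile's mean), so a gene-wise offset — the standard location-shift
picture of a batch effect — is what this generator uses;
`batch_shift = 0` reduces exactly to the unbatched generator. With
batch_shift at its default 1.0 the batch signal dominates: iterated
features recover the *batch* partition essentially perfectly while
class recovery sits at chance, which is the regime the supervised
adjustment is for.

These generators make no attempt to mimic real microarray intensity
distributions, probe effects, dropout or missingness. Passing tests on
them demonstrates the transform's behaviour under idealised Gaussian
class/noise/batch structure, not performance on any particular
platform's data.

## Evaluation battery

- **Preprocessing** (for intensity-scale inputs): clamp to
  [floor, ceil] (defaults 100, 16000), keep genes with max/min ≥ 5 and
  max − min ≥ 500 across samples, then log10. The four thresholds are
  the conventional ones for two-colour-era leukemia intensity data and
  are all exposed as parameters.
- **Gene selection**: per-gene one-way ANOVA F statistic, vectorised,
  with explicit conventions — zero between-class variance gives F = 0
  (ranked last), zero within-class variance with positive between gives
  F = +∞ (ranked first) — and stable descending sort so duplicated
  genes keep input order. Cross-checked against an independent
  per-gene ANOVA implementation in the tests.
- **Clustering**: Lloyd k-means with uniform-random data-point
  initialisation (not k-means++), one initialisation per run, max 300
  iterations, tolerance 1e−6, repeated with derived seeds. The
  run-to-run dispersion across random restarts is part of what is
  measured, which is why the greedier modern seeding is deliberately
  not used. Accuracy of a run is the fraction of samples matched under
  the optimal one-to-one assignment of clusters to classes (Hungarian
  algorithm on the contingency table); with k ≤ 3 this agrees with
  exhaustive matching.
- **Classification**: leave-one-out Gaussian naive Bayes with empirical
  class priors and variance floor 1e−9 × (largest feature variance).
- **Similarity statistics**: mean feature value over unordered
  same-class pairs (intra) and different-class pairs (inter), diagonal
  excluded — including the constant unit diagonal would inflate the
  intra mean by construction — and their difference, which approaches
  2 under ideal ±1 separation.
- **Comparison of accuracy distributions**: Welch (unequal-variance)
  two-sided t-test; at the replicate counts used the difference from
  the equal-variance form is immaterial, and Welch is the safer
  default. Zero-variance degenerate inputs get the limiting convention
  (t = 0, p = 1 when equal; t = ∞, p = 0 when separated).

## Problem sizes in the checked experiments

The simulation experiments in the test suite and the acceptance script
use the full 150-sample design at the stated σ and noise folds, with
100 k-means restarts per setting for the low-noise clustering figures,
10 replicate data sets per σ for the pooled naive Bayes figures, 20
paired replicates for the order-3 ≥ order-0 directional comparison
(5 restarts per arm), and 50 repeats of a reduced null-data design
(60 × 60 matrices, 9 data sets per repeat, 3 restarts per data set) for
the negative control. These sizes were chosen so each experiment's
Monte Carlo error is small relative to the effect it measures while the
whole battery stays quick to run.

## Known limitations

- Convergence to ±1 is an empirical observation with a closed-form
  account only in the 3-sample family above; pathological exactly
  orthogonal configurations remain fixed.
- High orders can merge genuinely distinct but similar classes into
  one (the features saturate); the useful order depends on the noise
  level and on how fine a partition is wanted. Low orders can be
  *worse* than raw features for supervised classification when the
  class signal is still spread across many noisy similarities.
- The batch adjustment is supervised (batch labels required), additive,
  and single-strength (one λ for all pairs); it does not model
  location/scale per gene and is not a substitute for gene-level batch
  correction when that is appropriate.
- The intra/inter similarity statistic weights every pair equally, so
  unbalanced classes weight the larger class's pairs more heavily in
  the intra mean.
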