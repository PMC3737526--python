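"""Evaluation battery: preprocessing, gene selection, clustering and
classification accuracy, and class-separation statistics.

The clustering protocol deliberately mirrors classic expression-analysis
practice: plain Lloyd k-means restarted many times from uniform-random
initial centres, so that the run-to-run variability caused by local
optima is itself part of what is measured.  Clustering accuracy is the
fraction of samples matched under the best one-to-one assignment of
predicted clusters to true classes (Hungarian algorithm on the
contingency table).  Classification uses leave-one-out Gaussian naive
Bayes; class separation is summarised by the mean within-class versus
between-class entry of a correlation-feature matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.naive_bayes import GaussianNB

from .core import CorrelationFeatures, ExpressionMatrix
from .errors import (
    AllGenesFiltered,
    DegenerateClass,
    InsufficientReplicates,
    KLargerThanM,
    SampleMismatch,
    SingleClass,
    UnknownSample,
)


def sample_feature_matrix(features) -> np.ndarray:
    """Samples-as-rows feature array from any supported container.

    ExpressionMatrix (order-0 features) is transposed so rows are
    samples; CorrelationFeatures rows are already per-sample feature
    vectors; a bare array is used as-is.
    """
    if isinstance(features, ExpressionMatrix):
        return features.sample_profiles()
    if isinstance(features, CorrelationFeatures):
        return features.values
    return np.asarray(features, dtype=float)


def align_labels(labels: Mapping[str, str], sample_ids: Sequence[str]) -> np.ndarray:
    """Label array aligned to ``sample_ids``; unlabeled samples are an error."""
    missing = [s for s in sample_ids if s not in labels]
    if missing:
        raise UnknownSample(f"samples without labels: {missing}")
    return np.asarray([labels[s] for s in sample_ids], dtype=object)


# --- preprocessing ------------------------------------------------------

def preprocess_floor_ceil_filter_log(
    X: ExpressionMatrix,
    floor: float = 100.0,
    ceil: float = 16000.0,
    min_ratio: float = 5.0,
    min_diff: float = 500.0,
) -> ExpressionMatrix:
    """Classic microarray intensity preprocessing.

    Values are clamped to [floor, ceil]; a gene is kept only if, across
    samples, max/min >= min_ratio and max - min >= min_diff; surviving
    values are log10-transformed.  The defaults are the conventional
    thresholds for two-colour-era leukemia intensity data.
    """
    if not floor < ceil:
        raise ValueError("floor must be < ceil")
    if floor <= 0:
        raise ValueError("floor must be positive (values are log-transformed)")
    clamped = np.clip(X.values, floor, ceil)
    gmax = clamped.max(axis=1)
    gmin = clamped.min(axis=1)
    keep = (gmax / gmin >= min_ratio) & (gmax - gmin >= min_diff)
    if not keep.any():
        raise AllGenesFiltered("no gene passed the variation filter")
    kept_ids = [g for g, k in zip(X.gene_ids, keep) if k]
    return ExpressionMatrix(
        values=np.log10(clamped[keep]), gene_ids=kept_ids, sample_ids=list(X.sample_ids)
    )


# --- gene selection -----------------------------------------------------

def gene_f_statistics(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """One-way ANOVA F statistic per gene (rows), vectorised.

    Conventions for degenerate genes: zero between-class variance gives
    F = 0; positive between-class with zero within-class variance gives
    F = +inf (a perfect separator).
    """
    classes, inv = np.unique(labels, return_inverse=True)
    k = classes.size
    if k < 2:
        raise DegenerateClass("F-test needs at least 2 classes")
    counts = np.bincount(inv)
    if counts.min() < 2:
        raise DegenerateClass("every class needs at least 2 samples")
    n = values.shape[1]
    grand = values.mean(axis=1, keepdims=True)
    group_sums = np.zeros((values.shape[0], k))
    np.add.at(group_sums.T, inv, values.T)
    group_means = group_sums / counts
    ss_between = ((group_means - grand) ** 2 * counts).sum(axis=1)
    centered = values - group_means[:, inv]
    ss_within = (centered**2).sum(axis=1)
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms_between / ms_within
    f[ms_between == 0.0] = 0.0
    f[(ms_within == 0.0) & (ms_between > 0.0)] = np.inf
    return f


def f_test_select(
    X: ExpressionMatrix, labels: Mapping[str, str], top_k: int
) -> ExpressionMatrix:
    """Keep the ``top_k`` genes with the largest one-way ANOVA F statistic.

    Ties (and the final ordering) are broken by input gene order, so the
    selection is stable under duplicated genes.
    """
    if top_k < 1 or top_k > X.n_genes:
        raise ValueError(f"top_k must be in [1, {X.n_genes}]")
    y = align_labels(labels, X.sample_ids)
    f = gene_f_statistics(X.values, y)
    order = np.argsort(-f, kind="stable")[:top_k]
    return ExpressionMatrix(
        values=X.values[order],
        gene_ids=[X.gene_ids[i] for i in order],
        sample_ids=list(X.sample_ids),
    )


# --- clustering ---------------------------------------------------------

def kmeans_runs(
    features, k: int, n_runs: int = 1000, seed: int = 0
) -> list[np.ndarray]:
    """Repeated Lloyd k-means from uniform-random initial centres.

    Each run draws its own derived seed, picks k data points uniformly at
    random as initial centres (no k-means++ seeding) and iterates to
    convergence; the dispersion of outcomes across runs reflects the
    local-optimum landscape of the feature space.
    """
    x = sample_feature_matrix(features)
    m = x.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > m:
        raise KLargerThanM(f"k={k} exceeds the number of samples m={m}")
    run_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_runs)
    partitions = []
    for s in run_seeds:
        km = KMeans(
            n_clusters=k,
            init="random",
            n_init=1,
            max_iter=300,
            tol=1e-6,
            algorithm="lloyd",
            random_state=int(s),
        )
        partitions.append(km.fit_predict(x))
    return partitions


def match_accuracy(predicted: Sequence, truth: Sequence) -> float:
    """Clustering accuracy under the optimal one-to-one cluster-to-class map.

    Builds the contingency table between predicted cluster ids and true
    class labels and maximises the matched count with the Hungarian
    algorithm; the result is invariant to any renaming of the predicted
    clusters.
    """
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise SampleMismatch(
            f"predicted ({pred.shape}) and true ({true.shape}) labelings differ in length"
        )
    _, pi = np.unique(pred, return_inverse=True)
    _, ti = np.unique(true, return_inverse=True)
    table = np.zeros((pi.max() + 1, ti.max() + 1), dtype=int)
    np.add.at(table, (pi, ti), 1)
    rows, cols = linear_sum_assignment(-table)
    return float(table[rows, cols].sum()) / pred.size


def clustering_accuracies(
    features, labels: Mapping[str, str], sample_ids: Sequence[str],
    k: int | None = None, n_runs: int = 1000, seed: int = 0,
) -> np.ndarray:
    """Matched accuracy of each of ``n_runs`` k-means runs against ``labels``.

    ``k`` defaults to the number of distinct classes.
    """
    y = align_labels(labels, sample_ids)
    if k is None:
        k = int(np.unique(y).size)
    parts = kmeans_runs(features, k=k, n_runs=n_runs, seed=seed)
    return np.asarray([match_accuracy(p, y) for p in parts])


# --- classification -----------------------------------------------------

def loocv_gaussian_nb(
    features, labels: Mapping[str, str] | Sequence, sample_ids: Sequence[str] | None = None,
    var_smoothing: float = 1e-9,
) -> float:
    """Leave-one-out accuracy of a Gaussian naive Bayes classifier.

    For each sample, per-class per-feature Gaussian densities (with a
    small variance floor of ``var_smoothing`` times the largest feature
    variance) and empirical class priors are fitted on the other m - 1
    samples and the held-out sample is assigned to the maximum-posterior
    class.
    """
    x = sample_feature_matrix(features)
    if isinstance(labels, Mapping):
        if sample_ids is None:
            raise ValueError("sample_ids required when labels is a mapping")
        y = align_labels(labels, sample_ids)
    else:
        y = np.asarray(labels, dtype=object)
    if y.size != x.shape[0]:
        raise SampleMismatch("labels and feature rows differ in length")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise DegenerateClass("leave-one-out needs >= 2 samples per class")
    m = x.shape[0]
    correct = 0
    idx = np.arange(m)
    for i in range(m):
        train = idx != i
        clf = GaussianNB(var_smoothing=var_smoothing)
        clf.fit(x[train], y[train])
        correct += int(clf.predict(x[i : i + 1])[0] == y[i])
    return correct / m


# --- similarity statistics ----------------------------------------------

def intra_inter_similarity(
    C: CorrelationFeatures, labels: Mapping[str, str]
) -> tuple[float, float, float]:
    """Mean within-class and between-class similarity, and their difference.

    Averages the feature matrix over unordered sample pairs i < j with
    equal (intra) or different (inter) class labels; self-pairs (the
    diagonal) are excluded.  A difference near 2 means ideal separation
    (+1 within classes, -1 between).
    """
    y = align_labels(labels, C.sample_ids)
    if np.unique(y).size < 2:
        raise SingleClass("inter-class similarity needs at least 2 classes")
    m = C.n_samples
    iu = np.triu_indices(m, k=1)
    same = (y[:, None] == y[None, :])[iu]
    vals = C.values[iu]
    intra = float(vals[same].mean())
    inter = float(vals[~same].mean())
    return intra, inter, intra - inter


# --- comparison of accuracy distributions -------------------------------

def accuracy_ttest(acc_a: Sequence[float], acc_b: Sequence[float]) -> tuple[float, float]:
    """Welch two-sided t-test between two accuracy samples.

    Degenerate zero-variance inputs get the limiting convention: equal
    constant samples give (0, 1), separated constant samples (inf, 0).
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientReplicates("need at least 2 values per group")
    if a.var() == 0.0 and b.var() == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


# --- report -------------------------------------------------------------

@dataclass
class EvalReport:
    """Summary container written by the CLI as JSON."""

    accuracies: list[float] = field(default_factory=list)
    intra_mean: float | None = None
    inter_mean: float | None = None
    difference: float | None = None
    statistic: float | None = None
    p_value: float | None = None

    def to_dict(self) -> dict:
        out: dict = {}
        if self.accuracies:
            acc = np.asarray(self.accuracies)
            out["accuracies"] = [float(a) for a in acc]
            out["mean_accuracy"] = float(acc.mean())
            out["quantiles"] = {
                q: float(np.quantile(acc, float(q))) for q in ("0.05", "0.25", "0.5", "0.75", "0.95")
            }
        for name in ("intra_mean", "inter_mean", "difference", "statistic", "p_value"):
            v = getattr(self, name)
            if v is not None:
                out[name] = float(v)
        return out
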