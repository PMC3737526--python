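"""Synthetic expression data generators and toy fixtures.

The class-structured generator emulates the simulation design used to
study how correlation features behave as noise grows: three sample
classes of 50 samples each, two *relevant* genes per class drawn
N(1, sigma) for samples of that class and N(0, sigma) otherwise, plus
0-, 10-, 50- or 100-fold *irrelevant* genes drawn N(0, sigma) for every
sample.  ``noise_fold`` is the ratio N/I of irrelevant to informative
genes, so the four settings give 6, 66, 306 and 606 genes for 150
samples.

Null generators produce completely random 150 x 150 matrices (standard
normal, uniform on [0, 1], discrete uniform on {-1, 0, 1}) with no
sample structure at all, and the toy fixtures are tiny hand-written
first-order correlation matrices whose behaviour under iteration is
known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CorrelationFeatures, ExpressionMatrix
from .errors import InvalidSpec, UnknownKind, UnknownToy


@dataclass
class SimulationSpec:
    """Parameters of the class-structured simulation.

    noise_fold is N/I, the ratio of noise genes to informative genes;
    sigma is the common standard deviation of all genes.
    """

    n_classes: int = 3
    samples_per_class: int = 50
    relevant_genes_per_class: int = 2
    noise_fold: int = 10
    sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.samples_per_class < 1 or self.relevant_genes_per_class < 1:
            raise InvalidSpec("class count, class size and relevant gene count must be positive")
        if self.noise_fold < 0:
            raise InvalidSpec("noise_fold must be >= 0")
        if self.sigma <= 0:
            raise InvalidSpec("sigma must be positive")

    @property
    def n_informative(self) -> int:
        return self.n_classes * self.relevant_genes_per_class

    @property
    def n_noise(self) -> int:
        return self.noise_fold * self.n_informative

    @property
    def n_genes(self) -> int:
        return self.n_informative + self.n_noise

    @property
    def n_samples(self) -> int:
        return self.n_classes * self.samples_per_class


@dataclass
class LabeledDataset:
    """An expression matrix together with per-sample class labels."""

    expression: ExpressionMatrix
    labels: dict[str, str]

    def label_array(self) -> np.ndarray:
        return np.asarray([self.labels[s] for s in self.expression.sample_ids], dtype=object)


def simulate_class_data(spec: SimulationSpec) -> LabeledDataset:
    """Generate a class-structured data set.

    Classes are laid out contiguously in sample order (samples 1..50 in
    class 1, and so on).  Each class's relevant genes are N(1, sigma)
    within the class and N(0, sigma) outside it; noise genes are
    N(0, sigma) everywhere.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.n_samples
    values = rng.normal(0.0, spec.sigma, size=(spec.n_genes, m))
    gene_ids: list[str] = []
    labels: dict[str, str] = {}
    sample_ids = [f"s{i + 1}" for i in range(m)]
    for c in range(spec.n_classes):
        cls = f"class{c + 1}"
        cols = slice(c * spec.samples_per_class, (c + 1) * spec.samples_per_class)
        rows = slice(c * spec.relevant_genes_per_class, (c + 1) * spec.relevant_genes_per_class)
        values[rows, cols] += 1.0
        gene_ids += [f"{cls}_gene{g + 1}" for g in range(spec.relevant_genes_per_class)]
        for s in sample_ids[cols]:
            labels[s] = cls
    gene_ids += [f"noise{k + 1}" for k in range(spec.n_noise)]
    X = ExpressionMatrix(values=values, gene_ids=gene_ids, sample_ids=sample_ids)
    return LabeledDataset(expression=X, labels=labels)


NULL_KINDS = ("normal", "uniform01", "discrete3")


def simulate_null_data(
    kind: str, m: int = 150, n: int = 150, seed: int = 0
) -> ExpressionMatrix:
    """A completely random n genes x m samples matrix with no structure.

    kind: "normal" (standard normal), "uniform01" (uniform on [0, 1]) or
    "discrete3" (uniform on {-1, 0, 1}).
    """
    rng = np.random.default_rng(seed)
    if kind == "normal":
        values = rng.standard_normal((n, m))
    elif kind == "uniform01":
        values = rng.uniform(0.0, 1.0, size=(n, m))
    elif kind == "discrete3":
        values = rng.integers(-1, 2, size=(n, m)).astype(float)
    else:
        raise UnknownKind(f"unknown null-data kind {kind!r}; choose from {NULL_KINDS}")
    gene_ids = [f"g{i + 1}" for i in range(n)]
    sample_ids = [f"s{j + 1}" for j in range(m)]
    return ExpressionMatrix(values=values, gene_ids=gene_ids, sample_ids=sample_ids)


_TOYS = {
    1: [[1.0, -1.0, 0.3], [-1.0, 1.0, -0.3], [0.3, -0.3, 1.0]],
    2: [[1.0, -1.0, 0.0], [-1.0, 1.0, 0.0], [0.0, 0.0, 1.0]],
    3: [
        [1.0, -1.0, -1.0, 0.0],
        [-1.0, 1.0, 1.0, 0.0],
        [-1.0, 1.0, 1.0, 0.0],
        [0.0, 0.0, 0.0, 1.0],
    ],
}


def toy_fixture(toy_id: int) -> CorrelationFeatures:
    """The three hand-written first-order correlation matrices.

    1: s3 weakly resembles s1 (entry 0.3); under iteration corr(s3, s1)
       climbs to +1 and corr(s3, s2) falls to -1.
    2: s3 is orthogonal to s1 and s2; the matrix is a fixed point of the
       iteration, so the independence of s3 is preserved.
    3: two unbalanced classes ({s1} and {s2, s3}) plus an s4 initially
       uncorrelated with everyone; iteration pulls corr(s4, s1) to +1.
    """
    if toy_id not in _TOYS:
        raise UnknownToy(f"toy id must be one of {sorted(_TOYS)}, got {toy_id!r}")
    values = np.array(_TOYS[toy_id], dtype=float)
    sample_ids = [f"s{i + 1}" for i in range(values.shape[0])]
    return CorrelationFeatures(values=values, order=1, sample_ids=sample_ids)


def simulate_batch_confounded(
    n_classes: int = 2,
    n_batches: int = 2,
    samples_per_class: int = 20,
    relevant_genes_per_class: int = 2,
    noise_fold: int = 10,
    sigma: float = 0.3,
    batch_shift: float = 1.0,
    seed: int = 0,
) -> tuple[LabeledDataset, dict[str, str]]:
    """Class-structured data with an additive per-batch gene-wise offset.

    Batches are interleaved within each class (so class and batch are
    crossed, not confounded with one another), and each batch b receives
    a fixed offset vector drawn N(0, batch_shift) per gene, added to all
    samples of that batch.  A gene-wise offset — rather than one constant
    shared by all genes — is what actually distorts sample correlations,
    since the Pearson coefficient ignores any constant added to a whole
    profile.  ``batch_shift = 0`` reduces exactly to the unbatched
    generator.

    Returns the labeled data set and a sample -> batch mapping.
    """
    if n_classes < 2 or n_batches < 2:
        raise InvalidSpec("need at least 2 classes and 2 batches")
    spec = SimulationSpec(
        n_classes=n_classes,
        samples_per_class=samples_per_class,
        relevant_genes_per_class=relevant_genes_per_class,
        noise_fold=noise_fold,
        sigma=sigma,
        seed=seed,
    )
    data = simulate_class_data(spec)
    rng = np.random.default_rng(seed + 1)
    offsets = rng.normal(0.0, 1.0, size=(n_batches, spec.n_genes)) * batch_shift
    batch_of: dict[str, str] = {}
    values = data.expression.values.copy()
    for j, s in enumerate(data.expression.sample_ids):
        b = j % n_batches  # interleave batches within the contiguous classes
        batch_of[s] = f"batch{b + 1}"
        values[:, j] += offsets[b]
    X = ExpressionMatrix(
        values=values,
        gene_ids=list(data.expression.gene_ids),
        sample_ids=list(data.expression.sample_ids),
    )
    return LabeledDataset(expression=X, labels=data.labels), batch_of
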