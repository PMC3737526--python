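"""Iterative Pearson correlation features (iPcc).

A gene-expression data set of *n* genes measured in *m* samples is first
summarised by the m x m matrix of pairwise Pearson correlations between
sample profiles.  Each row of that matrix is then re-interpreted as a new
feature vector for its sample, and the Pearson-correlation-of-rows map is
applied again, and again: the matrix obtained after *t* applications holds
the *t*-order correlation features.  Empirically the off-diagonal entries
converge rapidly to +1 or -1, amplifying weak sample-similarity structure
that is buried under many irrelevant genes.

The raw expression profiles are conventionally called the order-0
features; order 1 is the plain sample-correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .errors import (
    DegenerateIteration,
    TooFewGenes,
    UnknownKernel,
    ZeroVarianceRow,
    ZeroVarianceSample,
)

KERNELS = ("pearson", "spearman")


@dataclass
class ExpressionMatrix:
    """A genes x samples real-valued expression matrix with identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_genes, m_samples)
    gene_ids : sequence of str, unique, one per row
    sample_ids : sequence of str, unique, one per column
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        n, m = self.values.shape
        if len(self.gene_ids) != n or len(self.sample_ids) != m:
            raise ValueError("identifier lengths do not match matrix shape")
        if len(set(self.sample_ids)) != m:
            raise ValueError("sample_ids must be unique")
        if n < 1 or m < 2:
            raise ValueError("need at least 1 gene and 2 samples")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sample_profiles(self) -> np.ndarray:
        """Samples-as-rows view (m x n), the orientation the transform uses."""
        return self.values.T


@dataclass
class CorrelationFeatures:
    """An m x m matrix of order-*t* correlation features.

    ``values[i, j]`` is the feature of sample *i* scored by sample *j*.
    For an unadjusted transform the matrix is symmetric with unit diagonal
    and entries in [-1, 1]; batch-adjusted first-order matrices keep the
    symmetry but may leave that range (see :mod:`ipcc.batch`).
    """

    values: np.ndarray
    order: int
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        m = len(self.sample_ids)
        if self.values.shape != (m, m):
            raise ValueError("correlation matrix must be m x m")
        if self.order < 0:
            raise ValueError("order must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def validate(self, atol: float = 1e-12) -> None:
        """Assert the symmetric / unit-diagonal / bounded-range invariants."""
        v = self.values
        if not np.allclose(v, v.T, rtol=0.0, atol=atol):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0, rtol=0.0, atol=atol):
            raise ValueError("diagonal is not 1")
        if v.max() > 1.0 + atol or v.min() < -1.0 - atol:
            raise ValueError("entries outside [-1, 1]")


@dataclass
class ConvergenceTrace:
    """Per-iteration diagnostics of the iPcc map.

    ``max_abs_change[k]`` is max |C_{t+1} - C_t| for the k-th iteration
    performed; ``frac_saturated[k]`` is the fraction of off-diagonal
    entries within ``saturation_tol`` of +/-1 after that iteration.
    """

    max_abs_change: list[float] = field(default_factory=list)
    frac_saturated: list[float] = field(default_factory=list)
    saturation_tol: float = 1e-6

    def record(self, previous: np.ndarray, current: np.ndarray) -> float:
        delta = float(np.max(np.abs(current - previous)))
        off = ~np.eye(current.shape[0], dtype=bool)
        sat = float(np.mean(np.abs(np.abs(current[off]) - 1.0) < self.saturation_tol))
        self.max_abs_change.append(delta)
        self.frac_saturated.append(sat)
        return delta

    def __len__(self) -> int:
        return len(self.max_abs_change)


def _check_kernel(kernel: str) -> str:
    if kernel not in KERNELS:
        raise UnknownKernel(f"unknown correlation kernel {kernel!r}; choose from {KERNELS}")
    return kernel


def _row_correlation(rows: np.ndarray, kernel: str = "pearson") -> np.ndarray:
    """Correlation matrix of the rows of ``rows``, clipped to [-1, 1].

    Raises ZeroVarianceRow if any row is constant.
    """
    _check_kernel(kernel)
    if kernel == "spearman":
        rows = rankdata(rows, axis=1)
    sd = rows.std(axis=1)
    bad = np.flatnonzero(sd == 0.0)
    if bad.size:
        raise ZeroVarianceRow(f"constant rows at indices {bad.tolist()}")
    c = np.corrcoef(rows)
    np.clip(c, -1.0, 1.0, out=c)
    # corrcoef is symmetric up to rounding; enforce it exactly
    c = 0.5 * (c + c.T)
    return c


def sample_correlation_matrix(
    X: ExpressionMatrix,
    kernel: str = "pearson",
    on_constant: str = "error",
) -> CorrelationFeatures:
    """First-order correlation features: pairwise sample-profile correlation.

    Entry (i, j) is the Pearson (or Spearman) correlation between the
    expression profiles of samples i and j across all genes.

    Parameters
    ----------
    X : ExpressionMatrix
    kernel : {"pearson", "spearman"}
        Spearman is exploratory only; the iterative convergence behaviour
        is specific to the Pearson kernel.
    on_constant : {"error", "drop"}
        A constant profile makes the correlation undefined.  ``"error"``
        (default) raises :class:`ZeroVarianceSample`; ``"drop"`` removes
        the offending samples.

    Returns
    -------
    CorrelationFeatures with ``order=1``.
    """
    _check_kernel(kernel)
    if X.n_genes < 2:
        raise TooFewGenes("sample correlation needs at least 2 genes")
    profiles = X.sample_profiles()
    sample_ids = list(X.sample_ids)
    constant = np.flatnonzero(profiles.std(axis=1) == 0.0)
    if constant.size:
        if on_constant == "drop":
            keep = np.setdiff1d(np.arange(len(sample_ids)), constant)
            if keep.size < 2:
                raise ZeroVarianceSample(
                    "fewer than 2 samples remain after dropping constant profiles"
                )
            profiles = profiles[keep]
            sample_ids = [sample_ids[i] for i in keep]
        else:
            bad = [sample_ids[i] for i in constant]
            raise ZeroVarianceSample(
                f"constant expression profiles for samples {bad}; "
                "pass on_constant='drop' to remove them"
            )
    c = _row_correlation(profiles, kernel=kernel)
    return CorrelationFeatures(values=c, order=1, sample_ids=sample_ids)


def iterate_features(
    C: CorrelationFeatures, steps: int = 1, kernel: str = "pearson"
) -> CorrelationFeatures:
    """Apply the correlation-of-rows map ``steps`` times.

    Each application takes the current m x m feature matrix, treats its
    rows as sample feature vectors, and replaces the matrix by their
    pairwise correlations; the order increases by one per step.
    """
    _check_kernel(kernel)
    if steps < 1:
        raise ValueError("steps must be a positive integer")
    m = C.n_samples
    if m < 3:
        raise DegenerateIteration(
            "iteration needs at least 3 samples: with m = 2 every row has "
            "only two entries and the row-correlation map degenerates"
        )
    values = C.values
    for _ in range(steps):
        values = _row_correlation(values, kernel=kernel)
    return CorrelationFeatures(values=values, order=C.order + steps, sample_ids=list(C.sample_ids))


def ipcc(
    X: ExpressionMatrix,
    max_order: int = 5,
    tol: float = 1e-9,
    kernel: str = "pearson",
    on_constant: str = "error",
) -> tuple[list[CorrelationFeatures], ConvergenceTrace]:
    """Compute correlation features of orders 1..T with a convergence trace.

    Iteration stops at ``max_order`` or at the first order whose maximum
    absolute change from the previous order falls below ``tol``,
    whichever comes first.  The primary control is ``max_order``; ``tol``
    is a safety stop for matrices that reach a fixed point early.

    Returns
    -------
    (features, trace)
        ``features[t-1]`` holds the order-*t* matrix; ``trace`` has one
        entry per iteration actually performed (i.e. per order >= 2).
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be positive")
    c1 = sample_correlation_matrix(X, kernel=kernel, on_constant=on_constant)
    features = [c1]
    trace = ConvergenceTrace()
    current = c1
    for _ in range(2, max_order + 1):
        nxt = iterate_features(current, steps=1, kernel=kernel)
        delta = trace.record(current.values, nxt.values)
        features.append(nxt)
        current = nxt
        if delta < tol:
            break
    return features, trace


def iterate_matrix(values: np.ndarray, steps: int = 1, kernel: str = "pearson") -> np.ndarray:
    """Convenience: the raw correlation-of-rows map on a bare array."""
    out = np.asarray(values, dtype=float)
    for _ in range(steps):
        out = _row_correlation(out, kernel=kernel)
    return out
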