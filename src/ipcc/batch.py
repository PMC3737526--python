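"""Supervised batch-effect adjustment of first-order correlation features.

When samples come from different laboratories, between-lab signal can
dominate the sample-similarity structure.  Given known batch membership,
the first-order correlation matrix C1 is updated additively,

    C1' = C1 + lambda * B,

where B is a batch-indicator matrix (``within_value`` where two samples
share a batch, ``between_value`` otherwise; defaults -1 / +1, i.e.
penalise same-lab similarity and reward cross-lab similarity), and the
usual iteration then proceeds from C1'.  Because the row-correlation map
is invariant to adding a constant to a whole row, only the *contrast*
between within- and between-batch values matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import CorrelationFeatures, ExpressionMatrix, iterate_features, sample_correlation_matrix
from .errors import ShapeMismatch, UnlabeledSample


@dataclass
class BatchDesign:
    """Batch membership plus the adjustment parameters.

    Parameters
    ----------
    batch_of : mapping sample_id -> batch_id
    within_value, between_value : entries of the indicator matrix B for
        same-batch and different-batch sample pairs (defaults -1, +1).
    lam : non-negative weight of the adjustment (default 0.5).
    """

    batch_of: Mapping[str, str] = field(default_factory=dict)
    within_value: float = -1.0
    between_value: float = 1.0
    lam: float = 0.5

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")

    def batches_for(self, sample_ids: Sequence[str]) -> list[str]:
        missing = [s for s in sample_ids if s not in self.batch_of]
        if missing:
            raise UnlabeledSample(f"samples without a batch assignment: {missing}")
        return [str(self.batch_of[s]) for s in sample_ids]


def batch_indicator_matrix(design: BatchDesign, sample_ids: Sequence[str]) -> np.ndarray:
    """Symmetric m x m matrix B with B_ij = within_value when samples i and
    j share a batch, else between_value.  Diagonal entries are treated as
    within-batch."""
    batches = np.asarray(design.batches_for(sample_ids), dtype=object)
    same = batches[:, None] == batches[None, :]
    return np.where(same, design.within_value, design.between_value).astype(float)


def adjust_first_order(
    C1: CorrelationFeatures, B: np.ndarray, lam: float
) -> CorrelationFeatures:
    """Additive update C1' = C1 + lam * B.

    The result is symmetric but deliberately *not* re-clipped to [-1, 1]
    and its diagonal is left as computed: the subsequent row-correlation
    step needs neither, and forcing them would be an extra undocumented
    transformation.
    """
    B = np.asarray(B, dtype=float)
    if B.shape != C1.values.shape:
        raise ShapeMismatch(f"B has shape {B.shape}, expected {C1.values.shape}")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    return CorrelationFeatures(
        values=C1.values + lam * B, order=C1.order, sample_ids=list(C1.sample_ids)
    )


def ipcc_batch(
    X: ExpressionMatrix,
    design: BatchDesign,
    max_order: int = 5,
    kernel: str = "pearson",
) -> list[CorrelationFeatures]:
    """Batch-adjusted iPcc: order 1 is the adjusted correlation matrix,
    orders 2..max_order are obtained by the usual iteration on it."""
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    c1 = sample_correlation_matrix(X, kernel=kernel)
    B = batch_indicator_matrix(design, c1.sample_ids)
    adjusted = adjust_first_order(c1, B, design.lam)
    features = [adjusted]
    current = adjusted
    for _ in range(2, max_order + 1):
        current = iterate_features(current, steps=1, kernel=kernel)
        features.append(current)
    return features
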