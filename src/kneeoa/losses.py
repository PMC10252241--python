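"""Categorical cross-entropy and its gradual (partial-epoch) variant.

When an epoch is aborted after consuming only ``l`` of its ``N`` allocated
examples, the plain epoch loss (a sum divided by ``N``) under-reports the
per-example loss.  The gradual cross-entropy (GCE) rescales the summed
entropy by the consumption coefficient ``delta = N / l`` so the logged loss
reflects only the data actually seen:

    GCE = (delta / N) * sum_{i<=l} CE_i = (1 / l) * sum_{i<=l} CE_i

i.e. the mean cross-entropy over the consumed examples.  With ``l == N``
(``delta == 1``) it reduces to the standard epoch cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LossBatch",
    "PROB_FLOOR",
    "delta_coefficient",
    "cross_entropy",
    "gce",
]

# Clamp for log(p_true); keeps the loss finite on hard-zero predictions.
PROB_FLOOR = 1e-12


def _as_labels(labels: np.ndarray, num_classes: int) -> np.ndarray:
    """Canonicalize labels to int class indices; one-hot rows are converted."""
    labels = np.asarray(labels)
    if labels.ndim == 2:
        if labels.shape[1] != num_classes:
            raise ValueError("one-hot label width does not match class count")
        labels = labels.argmax(axis=1)
    labels = labels.astype(np.int64)
    if labels.size and (labels.min() < 0 or labels.max() >= num_classes):
        raise ValueError("label index out of range")
    return labels


@dataclass
class LossBatch:
    """Predicted probabilities + labels for the consumed part of an epoch.

    ``probs`` has one row per consumed example (``l`` rows of ``C``
    probabilities each); ``epoch_size`` is the epoch's full allocation ``N``.
    """

    probs: np.ndarray
    labels: np.ndarray
    epoch_size: int
    consumed: int = field(default=0)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2:
            raise ValueError("probs must be a 2-D array (examples x classes)")
        if self.consumed == 0:
            self.consumed = self.probs.shape[0]
        self.labels = _as_labels(self.labels, self.probs.shape[1])
        if self.labels.shape[0] != self.probs.shape[0]:
            raise ValueError("probs and labels disagree on example count")
        if self.probs.shape[0] != self.consumed:
            raise ValueError("number of prob/label rows must equal `consumed`")
        if not 1 <= self.consumed <= self.epoch_size:
            raise ValueError(
                f"consumed={self.consumed} outside [1, epoch_size={self.epoch_size}]"
            )
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be nonnegative")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each probability row must sum to 1 (atol 1e-6)")

    @property
    def num_classes(self) -> int:
        return self.probs.shape[1]


def delta_coefficient(epoch_size: int, consumed: int) -> float:
    """Consumption coefficient ``delta = N / l``; exact, errors outside [1, N]."""
    if consumed < 1 or consumed > epoch_size:
        raise ValueError(
            f"consumed must satisfy 1 <= l <= N, got l={consumed}, N={epoch_size}"
        )
    return epoch_size / consumed


def _per_example_ce(batch: LossBatch) -> np.ndarray:
    p_true = batch.probs[np.arange(batch.consumed), batch.labels]
    return -np.log(np.maximum(p_true, PROB_FLOOR))


def cross_entropy(batch: LossBatch) -> float:
    """Standard epoch loss ``-(1/N) sum_i log p_{i,true}``; requires l == N."""
    if batch.consumed != batch.epoch_size:
        raise ValueError("cross_entropy requires a fully consumed epoch (l == N)")
    return float(_per_example_ce(batch).sum() / batch.epoch_size)


def gce(batch: LossBatch) -> float:
    """Gradual cross-entropy: ``(delta / N) * sum over consumed examples``."""
    delta = delta_coefficient(batch.epoch_size, batch.consumed)
    return float(delta / batch.epoch_size * _per_example_ce(batch).sum())
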