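"""Confidence-thresholded pseudo-labeling losses.

The semi-supervised backbone of the framework: labeled images contribute a
plain cross-entropy on their weakly augmented view; unlabeled images get a
soft pseudo-label q from the weakly augmented view, keep it only when
max(q) strictly exceeds the threshold T, and the surviving hard labels
supervise the first strongly augmented view,

    L_s = (1/B_l) Σ_n H(y_n, p(y | weak(x_n)))
    L_u = (1/B_u) Σ_m η_m · H(q̂_m, p(y | strong(x_m))),  η_m = 1[max q_m > T].

Cross-entropy uses the natural log. Pseudo-label computation happens
outside the differentiated graph — only the strong-view branch carries
gradient.

All loss functions accept either plain arrays (returning a float) or
autodiff tensors (returning a tensor on the tape).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .tensor import Tensor


def _check_distributions(p: np.ndarray, tol: float = 1e-5):
    if p.ndim != 2:
        raise ValueError("expected a (batch, C) array of distributions")
    if np.any(p < -tol) or np.any(np.abs(p.sum(axis=1) - 1.0) > tol):
        raise ValueError("rows must be probability distributions")


@dataclasses.dataclass
class PseudoLabelBatch:
    """Soft pseudo-labels with their hard argmax classes and retention mask."""

    soft: np.ndarray  # (Bu, C)
    hard: np.ndarray  # (Bu,) int
    mask: np.ndarray  # (Bu,) {0,1}
    threshold: float

    def __post_init__(self):
        if not (len(self.soft) == len(self.hard) == len(self.mask)):
            raise ValueError("misaligned pseudo-label batch")

    @property
    def coverage(self) -> float:
        """Fraction of the unlabeled batch that passed the threshold."""
        return float(self.mask.mean()) if len(self.mask) else 0.0


def compute_pseudo_labels(weak_distributions: np.ndarray, threshold: float) -> PseudoLabelBatch:
    """Soft/hard pseudo-labels and the strict-threshold retention mask."""
    q = np.asarray(weak_distributions, dtype=np.float64)
    _check_distributions(q)
    hard = q.argmax(axis=1)  # ties: lowest index
    mask = (q.max(axis=1) > threshold).astype(np.int64)
    return PseudoLabelBatch(soft=q, hard=hard, mask=mask, threshold=float(threshold))


def supervised_loss(predicted_distributions, labels):
    """Mean natural-log cross-entropy of labeled predictions against labels."""
    is_tensor = isinstance(predicted_distributions, Tensor)
    p = predicted_distributions if is_tensor else Tensor(predicted_distributions)
    labels = np.asarray(labels, dtype=np.int64)
    _check_distributions(p.data)
    n, c = p.data.shape
    if len(labels) != n:
        raise ValueError("labels misaligned with predictions")
    if np.any(labels < 0) or np.any(labels >= c):
        raise ValueError("label outside 0..C-1")
    loss = -(p[np.arange(n), labels].log().mean())
    return loss if is_tensor else loss.item()


def unsupervised_loss(strong_view_distributions, batch: PseudoLabelBatch):
    """Masked pseudo-label cross-entropy on the first strong view, divided by Bu.

    The divisor is the full unlabeled batch size (not the number of retained
    samples), so low-confidence batches contribute proportionally little.
    """
    is_tensor = isinstance(strong_view_distributions, Tensor)
    p = strong_view_distributions if is_tensor else Tensor(strong_view_distributions)
    _check_distributions(p.data)
    bu = p.data.shape[0]
    if bu != len(batch.hard):
        raise ValueError("strong views misaligned with pseudo-label batch")
    kept = np.where(batch.mask > 0)[0]
    if bu == 0 or len(kept) == 0:
        return Tensor(0.0) if is_tensor else 0.0
    picked = p[kept, batch.hard[kept]].log()
    loss = -(picked.sum()) * (1.0 / bu)
    return loss if is_tensor else loss.item()
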