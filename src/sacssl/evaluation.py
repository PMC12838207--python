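"""Classification metrics, bootstrap model comparison, and subclass scoring.

Metrics follow the macro-averaged convention for multi-class grading
tasks: sensitivity, specificity and F1 are computed one-vs-rest per class
and averaged. Overall accuracy is the proportion of correctly classified
samples (trace of the confusion matrix over its total); the per-class
one-vs-rest accuracy average — Σ(TP+TN)/Σ(TP+TN+FP+FN) — is also reported
for transparency, since the two differ for more than two classes.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score


@dataclasses.dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (C, C), rows = true, cols = predicted

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, c: int):
        """(TP, TN, FP, FN) counts for class ``c``."""
        tp = self.counts[c, c]
        fn = self.counts[c].sum() - tp
        fp = self.counts[:, c].sum() - tp
        tn = self.total - tp - fn - fp
        return int(tp), int(tn), int(fp), int(fn)


def confusion_matrix(true_labels, predicted_labels, n_classes: int) -> ConfusionMatrix:
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if len(t) != len(p):
        raise ValueError("label vectors must be aligned")
    if len(t) and (t.min() < 0 or t.max() >= n_classes or p.min() < 0 or p.max() >= n_classes):
        raise ValueError("labels outside 0..C-1")
    counts = np.bincount(t * n_classes + p, minlength=n_classes * n_classes)
    return ConfusionMatrix(counts.reshape(n_classes, n_classes))


@dataclasses.dataclass
class MetricsReport:
    accuracy: float
    per_class_avg_accuracy: float
    sensitivity: float  # macro
    specificity: float  # macro
    f1: float  # macro
    per_class_sensitivity: np.ndarray
    per_class_specificity: np.ndarray
    per_class_f1: np.ndarray

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class_avg_accuracy": self.per_class_avg_accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
        }


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); contributing 0")
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Macro-averaged sensitivity/specificity/F1 plus the two accuracy readings."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    c = cm.n_classes
    sens = np.zeros(c)
    spec = np.zeros(c)
    f1 = np.zeros(c)
    ovr_num = ovr_den = 0.0
    for i in range(c):
        tp, tn, fp, fn = cm.one_vs_rest(i)
        sens[i] = _safe_ratio(tp, tp + fn, f"sensitivity of class {i}")
        spec[i] = _safe_ratio(tn, tn + fp, f"specificity of class {i}")
        f1[i] = _safe_ratio(2 * tp, 2 * tp + fp + fn, f"F1 of class {i}")
        ovr_num += tp + tn
        ovr_den += tp + tn + fp + fn
    return MetricsReport(
        accuracy=float(np.trace(cm.counts) / cm.total),
        per_class_avg_accuracy=float(ovr_num / ovr_den),
        sensitivity=float(sens.mean()),
        specificity=float(spec.mean()),
        f1=float(f1.mean()),
        per_class_sensitivity=sens,
        per_class_specificity=spec,
        per_class_f1=f1,
    )


def macro_f1(true_labels, predicted_labels, n_classes: int) -> float:
    return metrics(confusion_matrix(true_labels, predicted_labels, n_classes)).f1


def bootstrap_f1_diff(
    preds_a,
    preds_b,
    true_labels,
    n_classes: int | None = None,
    n_boot: int = 10000,
    level: float = 0.95,
    seed: int = 0,
):
    """Percentile bootstrap CI for macro-F1(A) − macro-F1(B) on a shared test set.

    Test items are resampled with replacement (image-level resampling); both
    models are re-scored on each replicate, so the interval reflects the
    paired difference. Returns (low, high).
    """
    a = np.asarray(preds_a, dtype=np.int64)
    b = np.asarray(preds_b, dtype=np.int64)
    t = np.asarray(true_labels, dtype=np.int64)
    if not (len(a) == len(b) == len(t)) or len(t) == 0:
        raise ValueError("prediction vectors must be aligned and non-empty")
    if n_boot < 1:
        raise ValueError("n_boot must be positive")
    c = int(n_classes) if n_classes else int(max(a.max(), b.max(), t.max())) + 1
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xB007)))
    n = len(t)
    diffs = np.empty(n_boot)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-support classes in small replicates
        for r in range(n_boot):
            idx = rng.integers(0, n, size=n)
            diffs[r] = macro_f1(t[idx], a[idx], c) - macro_f1(t[idx], b[idx], c)
    alpha = 1.0 - level
    low, high = np.quantile(diffs, [alpha / 2, 1 - alpha / 2])
    return float(low), float(high)


def subclass_recovery_score(
    assignment_labels, true_subclass_labels, class_labels=None
) -> dict:
    """Adjusted Rand index between discovered subclasses and the ground truth.

    With ``class_labels`` given, the ARI is computed within each true class
    (the discovery mechanism only ever partitions a single class) and the
    pooled value is the sample-weighted mean; otherwise one global ARI is
    returned under key ``pooled``.
    """
    a = np.asarray(assignment_labels)
    t = np.asarray(true_subclass_labels)
    if len(a) != len(t):
        raise ValueError("label vectors must be aligned")

    def _ari(x, y):
        if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
            return 0.0
        return float(adjusted_rand_score(x, y))

    if class_labels is None:
        return {"pooled": _ari(t, a)}
    cl = np.asarray(class_labels)
    out, weights = {}, []
    for c in np.unique(cl):
        sel = cl == c
        out[int(c)] = _ari(t[sel], a[sel])
        weights.append((int(c), int(sel.sum())))
    total = sum(w for _, w in weights)
    out["pooled"] = sum(out[c] * w for c, w in weights) / total if total else 0.0
    return out


def export_embeddings(results, manifest: pd.DataFrame, root) -> pd.DataFrame:
    """One row per manifest image: id, labels, prediction, unit-norm embedding."""
    probs, emb = results.forward(manifest, root)
    pred = probs.argmax(axis=1)
    true = manifest["true_label"] if "true_label" in manifest else manifest["label"]
    table = pd.DataFrame(
        {
            "id": manifest["image_path"].to_numpy(),
            "true_label": np.asarray(true, dtype=np.int64),
            "predicted_label": pred,
        }
    )
    emb_cols = pd.DataFrame(emb, columns=[f"z{j}" for j in range(emb.shape[1])])
    return pd.concat([table.reset_index(drop=True), emb_cols], axis=1)
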