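"""Subclass-aware contrastive semi-supervised learning (SACSSL).

A semi-supervised image classifier for settings — typified by colonoscopy
grading of inflammatory bowel disease — where classes look alike, each
class hides several visually distinct presentation modes, and labels are
scarce. Confidence-thresholded pseudo-labeling is combined with a
contrastive module that treats low-confidence samples as individual
instances and clusters high-confidence samples into per-class subclasses
via entropic optimal transport to momentum-updated prototypes.
"""

from .evaluation import (
    ConfusionMatrix,
    MetricsReport,
    bootstrap_f1_diff,
    confusion_matrix,
    macro_f1,
    metrics,
    subclass_recovery_score,
)
from .pseudo_labeling import (
    PseudoLabelBatch,
    compute_pseudo_labels,
    supervised_loss,
    unsupervised_loss,
)
from .subclass import (
    AssignmentMatrix,
    ConfidencePartition,
    PrototypeBank,
    SubclassAssignment,
    assign_subclasses,
    init_prototype_bank,
    instance_contrastive_loss,
    partition_confidence,
    sinkhorn_assignment,
    subclass_aware_loss,
    subclass_contrastive_loss,
    update_prototypes,
)
from .synthetic import (
    EmbeddingFixture,
    SyntheticSpec,
    generate_dataset,
    generate_embedding_fixture,
    split_by_patient,
)
from .trainer import (
    SACSSL,
    ModelBundle,
    SACSSLResults,
    TrainConfig,
    forward_heads,
    total_loss,
)

__version__ = "0.1.0"

__all__ = [
    "SACSSL",
    "SACSSLResults",
    "TrainConfig",
    "ModelBundle",
    "forward_heads",
    "total_loss",
    "SyntheticSpec",
    "EmbeddingFixture",
    "generate_dataset",
    "split_by_patient",
    "generate_embedding_fixture",
    "PseudoLabelBatch",
    "compute_pseudo_labels",
    "supervised_loss",
    "unsupervised_loss",
    "ConfidencePartition",
    "PrototypeBank",
    "AssignmentMatrix",
    "SubclassAssignment",
    "partition_confidence",
    "instance_contrastive_loss",
    "sinkhorn_assignment",
    "assign_subclasses",
    "subclass_contrastive_loss",
    "subclass_aware_loss",
    "update_prototypes",
    "init_prototype_bank",
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "metrics",
    "macro_f1",
    "bootstrap_f1_diff",
    "subclass_recovery_score",
]
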