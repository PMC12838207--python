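"""Subclass-aware contrastive module.

This is the heart of the method. The 2·Bu strongly augmented views of an
unlabeled batch are split by pseudo-label confidence:

* **uncertain** views (max q̃ ≤ T_conf) get an instance-level contrastive
  loss — each view's only positive is its augmentation partner — which
  pushes unreliable samples apart and counteracts confirmation bias;
* **confident** views (max q̃ > T_conf) are grouped by predicted class and
  assigned to that class's K unit-norm prototypes by entropic optimal
  transport with an equipartition constraint (Sinkhorn–Knopp), forming
  fine-grained subclasses. A supervised-contrastive loss then attracts an
  anchor to its augmentation partner and, weighted by the product of the
  two max pseudo-probabilities, to every other confident view in the same
  subclass.

Prototypes are non-learnable state updated once per iteration by an
exponential moving average toward the normalized center of their assigned
embeddings. Assignments and prototype updates happen outside the
differentiated graph; only the contrastive log-ratios carry gradient.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import logsumexp as np_logsumexp

from .tensor import Tensor, logsumexp

_NEG = -1e9  # additive mask excluding an index from a log-sum-exp denominator


def pairing(n_views: int) -> np.ndarray:
    """The view-partner involution i ↦ i★ on a multi-view batch of 2·Bu."""
    if n_views % 2:
        raise ValueError("multi-view batch must have even size")
    bu = n_views // 2
    return (np.arange(n_views) + bu) % n_views


@dataclasses.dataclass
class ConfidencePartition:
    """Disjoint confident / uncertain index sets over the multi-view batch."""

    confident: np.ndarray
    uncertain: np.ndarray
    t_conf: float
    n_views: int

    @property
    def confident_fraction(self) -> float:
        return len(self.confident) / self.n_views if self.n_views else 0.0


def partition_confidence(q_tilde: np.ndarray, t_conf: float) -> ConfidencePartition:
    """Split view indices by max pseudo-probability, strict at the threshold."""
    q = np.asarray(q_tilde, dtype=np.float64)
    conf = q.max(axis=1) > t_conf
    idx = np.arange(len(q))
    return ConfidencePartition(
        confident=idx[conf], uncertain=idx[~conf], t_conf=float(t_conf), n_views=len(q)
    )


# -- similarity machinery ------------------------------------------------------


def _masked_similarity(z, tau: float):
    """Pairwise cosine similarities over temperature, self-pairs masked out."""
    if tau <= 0:
        raise ValueError("temperature must be positive")
    is_tensor = isinstance(z, Tensor)
    zt = z if is_tensor else Tensor(np.asarray(z, dtype=np.float64))
    n = zt.data.shape[0]
    sim = (zt @ zt.T) * (1.0 / tau) + Tensor(_NEG * np.eye(n))
    return sim, is_tensor


def instance_contrastive_loss(z, partition: ConfidencePartition, tau: float):
    """Sum over uncertain anchors of −log softmax(z_i·z_i★/τ) over all j≠i.

    Un-normalized: the 1/(2Bu) factor is applied later when the instance and
    subclass terms are combined.
    """
    sim, is_tensor = _masked_similarity(z, tau)
    anchors = partition.uncertain
    if len(anchors) == 0:
        return Tensor(0.0) if is_tensor else 0.0
    partner = pairing(partition.n_views)
    denom = logsumexp(sim, axis=1)  # (2Bu,)
    loss = (denom[anchors] - sim[anchors, partner[anchors]]).sum()
    return loss if is_tensor else loss.item()


# -- prototypes and optimal-transport assignment -------------------------------


@dataclasses.dataclass
class PrototypeBank:
    """C×K unit-norm prototype vectors with an EMA momentum coefficient."""

    vectors: np.ndarray  # (C, K, D), unit rows
    momentum: float = 0.99

    @property
    def n_classes(self) -> int:
        return self.vectors.shape[0]

    @property
    def k(self) -> int:
        return self.vectors.shape[1]

    @property
    def dim(self) -> int:
        return self.vectors.shape[2]


def init_prototype_bank(
    C: int, K: int, D: int, seed=0, momentum: float = 0.99
) -> PrototypeBank:
    """Prototypes drawn uniformly on the D-sphere (normalized Gaussians)."""
    if K < 1 or D < 1 or C < 1:
        raise ValueError("C, K, D must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(np.random.SeedSequence((int(seed), 0x9707)))
    )
    vecs = rng.normal(size=(C, K, D))
    vecs /= np.linalg.norm(vecs, axis=2, keepdims=True)
    return PrototypeBank(vectors=vecs, momentum=float(momentum))


@dataclasses.dataclass
class AssignmentMatrix:
    """Entropic transport plan from one class's confident samples to prototypes.

    ``matrix`` is K×Nc; each column (one sample) sums to 1 and each row (one
    prototype) sums to Nc/K at convergence — the soft equipartition that
    stops every sample from collapsing onto a single prototype.
    """

    matrix: np.ndarray  # (K, Nc)
    class_index: int
    member_indices: np.ndarray  # view indices into the multi-view batch
    kappa: float
    residual: float  # worst marginal violation at exit
    n_iters_run: int

    def hard_assignments(self) -> np.ndarray:
        """Per-sample prototype index (argmax per column, lowest index wins)."""
        return self.matrix.argmax(axis=0)


def sinkhorn_assignment(
    embeddings: np.ndarray,
    prototypes: np.ndarray,
    kappa: float,
    n_iters: int = 3,
    tol: float = 1e-6,
    class_index: int = 0,
    member_indices: np.ndarray | None = None,
) -> AssignmentMatrix:
    """Solve the entropy-regularized transport from samples to prototypes.

    Maximizes ⟨M, PᵀZ⟩ + κ·H(M) subject to per-sample mass 1 and
    per-prototype mass Nc/K, by alternating row/column scalings in the log
    domain (numerically safe for arbitrarily small κ). Each iteration ends
    with the column scaling, so per-sample mass is exact on exit and the
    reported residual is the remaining row-marginal violation.
    """
    z = np.asarray(embeddings, dtype=np.float64)
    p = np.asarray(prototypes, dtype=np.float64)
    nc, k = z.shape[0], p.shape[0]
    members = (
        np.arange(nc) if member_indices is None else np.asarray(member_indices)
    )
    if nc == 0:
        return AssignmentMatrix(np.zeros((k, 0)), class_index, members, kappa, 0.0, 0)
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    s = (p @ z.T) / kappa  # (K, Nc)
    log_row_target = np.log(nc / k)
    f = np.zeros(k)
    g = np.zeros(nc)
    it = 0
    residual = np.inf
    for it in range(1, n_iters + 1):
        f = log_row_target - np_logsumexp(s + g[None, :], axis=1)
        g = -np_logsumexp(s + f[:, None], axis=0)
        m = np.exp(s + f[:, None] + g[None, :])
        residual = max(
            np.abs(m.sum(axis=0) - 1.0).max(),
            np.abs(m.sum(axis=1) - nc / k).max(),
        )
        if residual < tol:
            break
    m = np.exp(s + f[:, None] + g[None, :])
    return AssignmentMatrix(m, class_index, members, float(kappa), float(residual), it)


@dataclasses.dataclass
class SubclassAssignment:
    """Hard subclass memberships of confident views plus positive sets.

    The two views of one image are assigned independently; they may land on
    different prototypes. Positive sets exclude the anchor and its partner
    (the partner is always a positive, handled separately) and require both
    the predicted class and the prototype to agree.
    """

    n_views: int
    confident: np.ndarray  # anchor view indices
    class_of: dict  # view index -> predicted class
    proto_of: dict  # view index -> prototype index within the class
    max_prob: np.ndarray  # (2Bu,) max pseudo-probability per view
    per_class: dict  # class -> AssignmentMatrix
    groups: dict  # (class, proto) -> np.ndarray of view indices

    def positives(self, i: int, partner: np.ndarray) -> np.ndarray:
        """Cross-image positive indices Pos(i) for a confident anchor."""
        group = self.groups[(self.class_of[i], self.proto_of[i])]
        return group[(group != i) & (group != partner[i])]

    def weight(self, i: int, p: int) -> float:
        """Confidence weight of a cross-image positive pair."""
        return float(self.max_prob[i] * self.max_prob[p])


def assign_subclasses(
    z: np.ndarray,
    partition: ConfidencePartition,
    q_tilde: np.ndarray,
    bank: PrototypeBank,
    kappa: float = 0.05,
    n_iters: int = 3,
) -> SubclassAssignment:
    """Group confident views by predicted class, transport each group to its
    class's prototypes, and take per-view argmax subclass memberships."""
    z = np.asarray(z, dtype=np.float64)
    q = np.asarray(q_tilde, dtype=np.float64)
    classes = q.argmax(axis=1)
    max_prob = q.max(axis=1)
    class_of, proto_of, per_class, groups = {}, {}, {}, {}
    for c in np.unique(classes[partition.confident]):
        members = partition.confident[classes[partition.confident] == c]
        am = sinkhorn_assignment(
            z[members],
            bank.vectors[c],
            kappa,
            n_iters=n_iters,
            class_index=int(c),
            member_indices=members,
        )
        per_class[int(c)] = am
        hard = am.hard_assignments()
        for i, k in zip(members, hard):
            class_of[int(i)] = int(c)
            proto_of[int(i)] = int(k)
        for k in range(bank.k):
            sel = members[hard == k]
            if len(sel):
                groups[(int(c), int(k))] = sel
    return SubclassAssignment(
        n_views=partition.n_views,
        confident=partition.confident,
        class_of=class_of,
        proto_of=proto_of,
        max_prob=max_prob,
        per_class=per_class,
        groups=groups,
    )


def subclass_contrastive_loss(z, assignment: SubclassAssignment, tau: float):
    """Supervised-contrastive loss over confident anchors.

    Each anchor contributes its view-pair log-ratio plus confidence-weighted
    log-ratios against its cross-image subclass positives, the whole term
    divided by 1 + |Pos(i)|; anchors are then summed (the 1/(2Bu) factor is
    applied by :func:`subclass_aware_loss`).
    """
    sim, is_tensor = _masked_similarity(z, tau)
    n = assignment.n_views
    if len(assignment.confident) == 0:
        return Tensor(0.0) if is_tensor else 0.0
    partner = pairing(n)
    # coefficient matrix: scaled positive weights per anchor row
    coeff = np.zeros((n, n))
    for i in assignment.confident:
        pos = assignment.positives(int(i), partner)
        scale = 1.0 / (1.0 + len(pos))
        coeff[i, partner[i]] += scale
        for p in pos:
            coeff[i, p] += scale * assignment.weight(int(i), int(p))
    denom = logsumexp(sim, axis=1)  # (2Bu,)
    row_mass = coeff.sum(axis=1)
    loss = (denom * Tensor(row_mass)).sum() - (Tensor(coeff) * sim).sum()
    return loss if is_tensor else loss.item()


def subclass_aware_loss(l_conf, l_unc, bu: int):
    """Combine the confident and uncertain sums, averaged over the 2·Bu views."""
    if bu < 1:
        raise ValueError("Bu must be at least 1")
    return (l_conf + l_unc) * (1.0 / (2 * bu))


def update_prototypes(
    bank: PrototypeBank, z: np.ndarray, assignment: SubclassAssignment
) -> PrototypeBank:
    """EMA step toward the normalized center of each prototype's assigned views.

    p ← α·p + (1−α)·Σz/‖Σz‖, then renormalized to the unit sphere so cosine
    similarities stay well-defined. Prototypes with no assigned views this
    iteration are untouched.
    """
    z = np.asarray(z, dtype=np.float64)
    vecs = bank.vectors.copy()
    a = bank.momentum
    for (c, k), members in assignment.groups.items():
        center = z[members].sum(axis=0)
        norm = np.linalg.norm(center)
        if norm < 1e-12:
            continue
        p = a * vecs[c, k] + (1 - a) * (center / norm)
        vecs[c, k] = p / np.linalg.norm(p)
    return PrototypeBank(vectors=vecs, momentum=bank.momentum)
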