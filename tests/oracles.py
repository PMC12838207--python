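"""Independent brute-force oracles used to verify the vectorized losses.

Everything here is written as plain double loops over scalars (or exhaustive
enumeration), deliberately sharing no code with the package implementation.
"""

import itertools
import math

import numpy as np


def naive_supervised_loss(distributions, labels):
    total = 0.0
    for p, y in zip(distributions, labels):
        total += -math.log(p[y])
    return total / len(labels)


def naive_unsupervised_loss(strong_distributions, weak_distributions, threshold):
    bu = len(strong_distributions)
    total = 0.0
    for m in range(bu):
        q = weak_distributions[m]
        if max(q) > threshold:
            hard = int(np.argmax(q))
            total += -math.log(strong_distributions[m][hard])
    return total / bu


def _partner(i, n):
    return (i + n // 2) % n


def naive_instance_loss(z, uncertain, tau):
    n = len(z)
    total = 0.0
    for i in uncertain:
        denom = 0.0
        for j in range(n):
            if j != i:
                denom += math.exp(float(np.dot(z[i], z[j])) / tau)
        num = math.exp(float(np.dot(z[i], z[_partner(i, n)])) / tau)
        total += -math.log(num / denom)
    return total


def naive_subclass_loss(z, confident, class_of, proto_of, max_prob, tau):
    n = len(z)
    total = 0.0
    for i in confident:
        star = _partner(i, n)
        denom = 0.0
        for j in range(n):
            if j != i:
                denom += math.exp(float(np.dot(z[i], z[j])) / tau)
        anchor = -math.log(math.exp(float(np.dot(z[i], z[star])) / tau) / denom)
        pos = [
            j
            for j in confident
            if j != i
            and j != star
            and class_of[j] == class_of[i]
            and proto_of[j] == proto_of[i]
        ]
        for p in pos:
            w = max_prob[i] * max_prob[p]
            anchor += -w * math.log(math.exp(float(np.dot(z[i], z[p])) / tau) / denom)
        total += anchor / (1.0 + len(pos))
    return total


def ipf_transport(similarity, kappa, col_target, row_target, tol=1e-12, max_iter=100000):
    """Linear-domain iterative proportional fitting to the two marginals."""
    m = np.exp(similarity / kappa - similarity.max() / kappa)
    for _ in range(max_iter):
        m *= (row_target / m.sum(axis=1))[:, None]
        m *= col_target / m.sum(axis=0)
        if np.abs(m.sum(axis=1) - row_target).max() < tol:
            break
    return m


def brute_force_equipartition(similarity):
    """Best hard assignment with exactly Nc/K samples per prototype, by
    exhaustive enumeration over all equipartition labelings."""
    k, nc = similarity.shape
    group = nc // k
    best_val, best = -np.inf, None
    labels = [i for i in range(k) for _ in range(group)]
    for perm in set(itertools.permutations(labels)):
        val = sum(similarity[perm[s], s] for s in range(nc))
        if val > best_val:
            best_val, best = val, np.asarray(perm)
    return best, best_val
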