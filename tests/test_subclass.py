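"""Subclass-aware contrastive module: partition, transport, losses, prototypes."""

import math

import numpy as np
import pytest

import sacssl as S
from sacssl import subclass
from sacssl.tensor import Tensor

from .conftest import random_multiview_batch
from .oracles import (
    brute_force_equipartition,
    ipf_transport,
    naive_instance_loss,
    naive_subclass_loss,
)


class TestPartition:
    def test_strict_threshold(self):
        q = np.array([[0.95, 0.05], [0.90, 0.10], [0.95, 0.05], [0.90, 0.10]])
        part = S.partition_confidence(q, 0.9)
        assert list(part.confident) == [0, 2]
        assert list(part.uncertain) == [1, 3]

    def test_threshold_one_means_all_uncertain(self):
        q = np.array([[1.0, 0.0], [1.0, 0.0]])
        part = S.partition_confidence(q, 1.0)
        assert len(part.confident) == 0 and len(part.uncertain) == 2

    def test_paired_views_co_partition(self):
        rng = np.random.default_rng(0)
        _, q = random_multiview_batch(rng, bu=6, n_classes=3, dim=4)
        part = S.partition_confidence(q, 0.7)
        partner = subclass.pairing(12)
        conf = set(part.confident)
        for i in part.confident:
            assert partner[i] in conf


class TestInstanceLoss:
    def test_empty_uncertain_gives_zero(self):
        z, q = random_multiview_batch(np.random.default_rng(1), 4, 3, 8)
        part = S.partition_confidence(q, 0.0)  # everything confident
        assert S.instance_contrastive_loss(z, part, 0.1) == 0.0

    def test_identical_embeddings_closed_form(self):
        # all similarities equal -> per-anchor loss ln(2Bu-1) for any tau
        bu = 2
        z = np.tile([1.0, 0.0, 0.0], (2 * bu, 1))
        part = S.partition_confidence(np.full((2 * bu, 3), 1 / 3), 0.9)
        for tau in (0.05, 0.5, 2.0):
            got = S.instance_contrastive_loss(z, part, tau)
            assert got == pytest.approx(2 * bu * math.log(2 * bu - 1), rel=1e-9)

    def test_orthogonal_pairs_closed_form(self):
        # z_i.z_partner = 1, all cross dots 0, tau=1: per anchor -ln(e/(e+2))
        z = np.array([[1, 0], [0, 1], [1, 0], [0, 1]], dtype=float)
        part = S.partition_confidence(np.full((4, 2), 0.5), 0.9)
        expect = 4 * -math.log(math.e / (math.e + 2))
        assert S.instance_contrastive_loss(z, part, 1.0) == pytest.approx(expect)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            bu = int(rng.integers(2, 9))
            z, q = random_multiview_batch(rng, bu, 3, 6)
            part = S.partition_confidence(q, 0.6)
            got = S.instance_contrastive_loss(z, part, 0.2)
            want = naive_instance_loss(z, list(part.uncertain), 0.2)
            assert got == pytest.approx(want, abs=1e-8)

    def test_invalid_temperature(self):
        z, q = random_multiview_batch(np.random.default_rng(3), 2, 3, 4)
        with pytest.raises(ValueError):
            S.instance_contrastive_loss(z, S.partition_confidence(q, 0.5), 0.0)


class TestSinkhorn:
    def test_k1_assigns_full_mass(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(5, 3))
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        p = z[:1]
        am = S.sinkhorn_assignment(z, p, kappa=0.05, n_iters=5)
        assert np.allclose(am.matrix, np.ones((1, 5)))

    def test_constant_similarity_gives_uniform_plan(self):
        z = np.tile([1.0, 0.0], (4, 1))
        p = np.tile([0.0, 1.0], (3, 1))
        am = S.sinkhorn_assignment(z, p, kappa=0.05, n_iters=50)
        assert np.allclose(am.matrix, np.full((3, 4), 1 / 3), atol=1e-8)

    def test_marginals_feasible_across_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            nc, k, d = int(rng.integers(1, 12)), int(rng.integers(1, 5)), 6
            z = rng.normal(size=(nc, d))
            z /= np.linalg.norm(z, axis=1, keepdims=True)
            p = rng.normal(size=(k, d))
            p /= np.linalg.norm(p, axis=1, keepdims=True)
            am = S.sinkhorn_assignment(z, p, kappa=0.05, n_iters=100000)
            m = am.matrix
            assert np.all(m >= 0)
            assert np.abs(m.sum(axis=0) - 1.0).max() < 1e-4
            assert np.abs(m.sum(axis=1) - nc / k).max() < 1e-4

    def test_matches_ipf_oracle_mid_kappa(self):
        rng = np.random.default_rng(6)
        z = rng.normal(size=(6, 4))
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        p = rng.normal(size=(2, 4))
        p /= np.linalg.norm(p, axis=1, keepdims=True)
        am = S.sinkhorn_assignment(z, p, kappa=0.3, n_iters=50000)
        want = ipf_transport((p @ z.T), 0.3, np.ones(6), np.full(2, 3.0))
        assert np.allclose(am.matrix, want, atol=1e-6)

    def test_small_kappa_matches_identity_permutation(self):
        # diagonal-favoring similarities, Nc=K=2: plan approaches the identity
        z = np.array([[1.0, 0.0], [0.0, 1.0]])
        p = np.array([[1.0, 0.0], [0.0, 1.0]])
        am = S.sinkhorn_assignment(z, p, kappa=0.01, n_iters=100)
        assert np.allclose(am.matrix, np.eye(2), atol=1e-6)

    def test_tiny_kappa_never_overflows(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=(6, 5))
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        p = rng.normal(size=(3, 5))
        p /= np.linalg.norm(p, axis=1, keepdims=True)
        am = S.sinkhorn_assignment(z, p, kappa=1e-4, n_iters=200)
        assert np.isfinite(am.matrix).all()

    @pytest.mark.parametrize("trial", range(10))
    def test_small_kappa_recovers_optimal_equipartition(self, trial):
        rng = np.random.default_rng(100 + trial)
        nc, k = 6, 3
        z = rng.normal(size=(nc, 5))
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        p = rng.normal(size=(k, 5))
        p /= np.linalg.norm(p, axis=1, keepdims=True)
        am = S.sinkhorn_assignment(z, p, kappa=0.001, n_iters=20000)
        want, _ = brute_force_equipartition(p @ z.T)
        assert np.array_equal(am.hard_assignments(), want)

    def test_empty_class_gives_empty_matrix(self):
        am = S.sinkhorn_assignment(np.zeros((0, 4)), np.eye(4)[:2], 0.05)
        assert am.matrix.shape == (2, 0)


class TestAssignSubclasses:
    def test_single_sample_reduces_to_nearest_prototype(self):
        rng = np.random.default_rng(8)
        bank = S.init_prototype_bank(2, 3, 4, seed=0)
        z = np.zeros((2, 4))
        z[:, :] = bank.vectors[1, 2]  # both views sit on prototype (1,2)
        q = np.array([[0.01, 0.99], [0.01, 0.99]])
        part = S.partition_confidence(q, 0.9)
        asg = S.assign_subclasses(z, part, q, bank, kappa=0.05, n_iters=10)
        assert asg.class_of[0] == 1 and asg.proto_of[0] == 2

    def test_matches_nearest_mean_on_separated_fixture(self):
        fx = S.generate_embedding_fixture(2, 3, 15, concentration=40, D=16, seed=3)
        bank = S.PrototypeBank(
            vectors=fx.component_means.reshape(2, 3, 16).copy(), momentum=0.99
        )
        n = len(fx.vectors)
        assert n % 2 == 0
        q = np.eye(2)[fx.class_labels] * 0.98 + 0.01
        part = S.partition_confidence(q, 0.9)
        asg = S.assign_subclasses(fx.vectors, part, q, bank, kappa=0.05, n_iters=200)
        got = np.array([asg.proto_of[i] for i in range(n)])
        nearest = np.array(
            [
                (fx.vectors[i] @ bank.vectors[fx.class_labels[i]].T).argmax()
                for i in range(n)
            ]
        )
        # components are balanced, so equipartition transport should agree
        # with plain nearest-mean at least as often as not
        assert (got == fx.subclass_labels).mean() >= (
            nearest == fx.subclass_labels
        ).mean() - 1e-12


class TestSubclassLoss:
    def test_empty_confident_gives_zero(self):
        z, q = random_multiview_batch(np.random.default_rng(9), 3, 3, 6)
        part = S.partition_confidence(q, 1.0)
        bank = S.init_prototype_bank(3, 2, 6, seed=0)
        asg = S.assign_subclasses(z, part, q, bank)
        assert S.subclass_contrastive_loss(z, asg, 0.1) == 0.0

    def test_no_positives_reduces_to_instance_term(self):
        # two confident views of one image, different classes impossible:
        # single image -> Pos(i) empty -> pure view-pair term
        rng = np.random.default_rng(10)
        z, _ = random_multiview_batch(rng, 1, 2, 5)
        q = np.array([[0.99, 0.01], [0.99, 0.01]])
        part = S.partition_confidence(q, 0.9)
        bank = S.init_prototype_bank(2, 2, 5, seed=1)
        asg = S.assign_subclasses(z, part, q, bank)
        got = S.subclass_contrastive_loss(z, asg, 0.3)
        all_unc = S.partition_confidence(q, 1.0)
        want = S.instance_contrastive_loss(z, all_unc, 0.3)
        assert got == pytest.approx(want, abs=1e-10)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            bu = int(rng.integers(2, 9))
            z, q = random_multiview_batch(rng, bu, 3, 6)
            part = S.partition_confidence(q, 0.5)
            bank = S.init_prototype_bank(3, 2, 6, seed=int(rng.integers(100)))
            asg = S.assign_subclasses(z, part, q, bank, kappa=0.1, n_iters=100)
            got = S.subclass_contrastive_loss(z, asg, 0.2)
            want = naive_subclass_loss(
                z, list(part.confident), asg.class_of, asg.proto_of,
                q.max(axis=1), 0.2,
            )
            assert got == pytest.approx(want, abs=1e-6)

    def test_k_equals_one_positives_are_all_same_class(self):
        """With K=1 the subclass is the class: Pos(i) holds every other
        confident same-class view."""
        rng = np.random.default_rng(12)
        z, q = random_multiview_batch(rng, 5, 2, 6)
        part = S.partition_confidence(q, 0.5)
        bank = S.init_prototype_bank(2, 1, 6, seed=2)
        asg = S.assign_subclasses(z, part, q, bank)
        partner = subclass.pairing(10)
        classes = q.argmax(axis=1)
        for i in part.confident:
            pos = set(asg.positives(int(i), partner))
            want = {
                int(j)
                for j in part.confident
                if j != i and j != partner[i] and classes[j] == classes[i]
            }
            assert pos == want


class TestPrototypes:
    def test_init_norms_and_determinism(self):
        a = S.init_prototype_bank(3, 4, 16, seed=5)
        b = S.init_prototype_bank(3, 4, 16, seed=5)
        assert np.allclose(np.linalg.norm(a.vectors, axis=2), 1.0, atol=1e-6)
        assert np.array_equal(a.vectors, b.vectors)

    def test_random_prototypes_near_orthogonal_in_high_dim(self):
        bank = S.init_prototype_bank(10, 100, 128, seed=6)
        flat = bank.vectors.reshape(-1, 128)
        gram = flat @ flat.T
        off = gram[~np.eye(len(flat), dtype=bool)]
        assert abs(off.mean()) < 0.01

    def _asg(self, z, q, bank):
        part = S.partition_confidence(q, 0.5)
        return S.assign_subclasses(z, part, q, bank)

    def test_momentum_one_keeps_bank(self):
        rng = np.random.default_rng(13)
        z, q = random_multiview_batch(rng, 3, 2, 5)
        bank = S.init_prototype_bank(2, 2, 5, seed=7, momentum=1.0)
        out = S.update_prototypes(bank, z, self._asg(z, q, bank))
        assert np.allclose(out.vectors, bank.vectors)

    def test_momentum_zero_jumps_to_center(self):
        bank = S.init_prototype_bank(1, 1, 3, seed=8, momentum=0.0)
        z = np.array([[0.0, 1.0, 0.0], [0.0, 1.0, 0.0]])
        q = np.array([[1.0], [1.0]])
        part = S.partition_confidence(q, 0.5)
        asg = S.assign_subclasses(z, part, q, bank)
        out = S.update_prototypes(bank, z, asg)
        assert np.allclose(out.vectors[0, 0], [0.0, 1.0, 0.0], atol=1e-12)

    def test_hand_formula_with_momentum(self):
        bank = S.init_prototype_bank(1, 1, 4, seed=9, momentum=0.99)
        rng = np.random.default_rng(14)
        z = rng.normal(size=(2, 4))
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        q = np.ones((2, 1))
        part = S.partition_confidence(q, 0.5)
        asg = S.assign_subclasses(z, part, q, bank)
        out = S.update_prototypes(bank, z, asg)
        center = z.sum(axis=0) / np.linalg.norm(z.sum(axis=0))
        want = 0.99 * bank.vectors[0, 0] + 0.01 * center
        want /= np.linalg.norm(want)
        assert np.allclose(out.vectors[0, 0], want, atol=1e-6)
        assert np.allclose(np.linalg.norm(out.vectors, axis=2), 1.0, atol=1e-6)

    def test_unassigned_prototypes_untouched(self):
        bank = S.init_prototype_bank(2, 2, 5, seed=10)
        rng = np.random.default_rng(15)
        z, _ = random_multiview_batch(rng, 2, 2, 5)
        q = np.array([[0.99, 0.01]] * 4)  # class 0 only
        part = S.partition_confidence(q, 0.9)
        asg = S.assign_subclasses(z, part, q, bank)
        out = S.update_prototypes(bank, z, asg)
        assert np.array_equal(out.vectors[1], bank.vectors[1])


class TestSubclassAwareLoss:
    def test_arithmetic(self):
        assert S.subclass_aware_loss(2.0, 4.0, 3) == pytest.approx(1.0)
        assert S.subclass_aware_loss(0.0, 0.0, 5) == 0.0

    def test_degenerate_threshold_reduces_to_instance_only(self):
        rng = np.random.default_rng(16)
        bu = 4
        z, q = random_multiview_batch(rng, bu, 3, 8)
        part = S.partition_confidence(q, 1.0)
        l_unc = S.instance_contrastive_loss(z, part, 0.1)
        bank = S.init_prototype_bank(3, 2, 8, seed=11)
        asg = S.assign_subclasses(z, part, q, bank)
        l_conf = S.subclass_contrastive_loss(z, asg, 0.1)
        assert l_conf == 0.0
        assert S.subclass_aware_loss(l_conf, l_unc, bu) == pytest.approx(
            l_unc / (2 * bu)
        )


def test_losses_finite_at_low_temperature():
    """Log-sum-exp formulation stays finite for tau down to 0.01."""
    rng = np.random.default_rng(17)
    z, q = random_multiview_batch(rng, 6, 3, 8)
    part = S.partition_confidence(q, 0.5)
    bank = S.init_prototype_bank(3, 2, 8, seed=12)
    asg = S.assign_subclasses(z, part, q, bank)
    for tau in (0.01, 0.05):
        assert np.isfinite(S.instance_contrastive_loss(z, part, tau))
        assert np.isfinite(S.subclass_contrastive_loss(z, asg, tau))


def test_gradients_flow_through_contrastive_losses():
    rng = np.random.default_rng(18)
    z_np, q = random_multiview_batch(rng, 3, 2, 5)
    z = Tensor(z_np, requires_grad=True)
    part = S.partition_confidence(q, 0.5)
    bank = S.init_prototype_bank(2, 2, 5, seed=13)
    asg = S.assign_subclasses(z_np, part, q, bank)
    loss = S.subclass_contrastive_loss(z, asg, 0.2) + S.instance_contrastive_loss(
        z, part, 0.2
    )
    loss.backward()
    assert z.grad is not None and np.isfinite(z.grad).all()
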