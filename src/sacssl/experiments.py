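"""Reproducible desk-scale experiments built from the library pieces.

These functions define the study conditions used throughout the package's
own validation: a C=3, k_true=3 synthetic dataset at 32×32 with a 20%
labeled fraction and patient-level splits, trained with the CPU-sized
configuration (``TrainConfig.desk``). Problem sizes are chosen so a full
paired comparison runs in minutes on one core.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, subclass
from .synthetic import SyntheticSpec, generate_dataset, generate_embedding_fixture, split_by_patient
from .trainer import SACSSL, TrainConfig


def make_study_dataset(out_dir, seed: int = 7) -> pd.DataFrame:
    """Generate the default study dataset with a 20/80 labeled split."""
    spec = SyntheticSpec(seed=seed)
    manifest = generate_dataset(spec, out_dir)
    manifest = split_by_patient(manifest, labeled_fraction=0.2, test_fraction=0.2, seed=seed)
    manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return manifest


def make_evaluation_pool(out_dir, seed: int, images_per_subclass: int = 40) -> pd.DataFrame:
    """An independently generated held-out pool (fresh patients, all test).

    Drawn from the same image distribution as the study dataset but with
    its own seed, it enlarges the evaluation set beyond the study split so
    paired comparisons are not quantized by a small test count.
    """
    spec = SyntheticSpec(seed=seed, images_per_subclass=images_per_subclass)
    manifest = generate_dataset(spec, out_dir)
    manifest = manifest.assign(split="test", true_label=manifest["label"])
    manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return manifest


def paired_gain_experiment(data_dir, seeds, eval_manifest=None, eval_dir=None) -> pd.DataFrame:
    """Full semi-supervised training vs the labeled-only baseline, per seed.

    Both arms of each pair share the dataset and the seed (weight init,
    shuffles and augmentation streams all derive from it), so the only
    difference is the objective. Evaluation uses the dataset's test split
    plus, when given, an independent evaluation pool. Returns one row per
    seed with test accuracies and macro-F1 of both arms.
    """
    rows = []
    for seed in seeds:
        cfg = TrainConfig.desk(seed=int(seed))
        model = SACSSL.from_manifest(Path(data_dir) / "manifest.csv", cfg)
        res_full = model.fit()
        res_base = model.fit_supervised()

        def _score(res):
            rep = res.evaluate(model.manifest, data_dir)
            if eval_manifest is None:
                return rep.accuracy, rep.f1
            rep2 = res.evaluate(eval_manifest, eval_dir)
            n1 = (model.manifest["split"] == "test").sum()
            n2 = len(eval_manifest)
            acc = (rep.accuracy * n1 + rep2.accuracy * n2) / (n1 + n2)
            f1 = (rep.f1 * n1 + rep2.f1 * n2) / (n1 + n2)
            return acc, f1

        acc_f, f1_f = _score(res_full)
        acc_b, f1_b = _score(res_base)
        rows.append(
            {
                "seed": int(seed),
                "acc_sacssl": acc_f,
                "acc_baseline": acc_b,
                "f1_sacssl": f1_f,
                "f1_baseline": f1_b,
            }
        )
    return pd.DataFrame(rows)


def paired_gain_study(work_dir, base_seed: int, n_pairs: int = 7) -> pd.DataFrame:
    """The full paired comparison: one fresh dataset and evaluation pool per
    pair, so the estimate averages over dataset draws, patient splits, and
    training randomness jointly."""
    work_dir = Path(work_dir)
    tables = []
    for i in range(n_pairs):
        pair_seed = int(base_seed) + i
        data = work_dir / f"pair_{i}"
        make_study_dataset(data, seed=pair_seed)
        eval_dir = work_dir / f"pair_{i}_eval"
        eval_manifest = make_evaluation_pool(eval_dir, seed=pair_seed + 5000)
        tables.append(
            paired_gain_experiment(
                data, [pair_seed + 1000], eval_manifest=eval_manifest, eval_dir=eval_dir
            )
        )
    return pd.concat(tables, ignore_index=True)


def subclass_recovery_experiment(
    seed: int = 0,
    n_classes: int = 2,
    k: int = 3,
    n_per_component: int = 40,
    concentration: float = 40.0,
    dim: int = 16,
    n_rounds: int = 50,
    n_permutations: int = 1000,
):
    """Unsupervised subclass discovery on a well-separated embedding fixture.

    Runs the online prototype machinery — equipartition transport assignment
    followed by an EMA prototype update — for ``n_rounds`` full-batch
    rounds from a random prototype init, then scores the final hard
    assignments against the ground-truth subclasses by within-class ARI.
    The permutation null shuffles true subclass labels within each class.
    """
    fx = generate_embedding_fixture(n_classes, k, n_per_component, concentration, dim, seed)
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xA21)))
    bank = subclass.init_prototype_bank(n_classes, k, dim, seed=rng, momentum=0.9)
    n = len(fx.vectors)
    q = np.full((n, n_classes), 0.01 / max(n_classes - 1, 1))
    q[np.arange(n), fx.class_labels] = 0.99
    part = subclass.partition_confidence(q, 0.9)
    asg = None
    for _ in range(n_rounds):
        asg = subclass.assign_subclasses(fx.vectors, part, q, bank, kappa=0.05, n_iters=100)
        bank = subclass.update_prototypes(bank, fx.vectors, asg)
    discovered = np.array([asg.proto_of[i] for i in range(n)])
    score = evaluation.subclass_recovery_score(
        discovered, fx.subclass_labels, class_labels=fx.class_labels
    )
    null = []
    for _ in range(n_permutations):
        permuted = fx.subclass_labels.copy()
        for c in range(n_classes):
            sel = np.where(fx.class_labels == c)[0]
            permuted[sel] = permuted[rng.permutation(sel)]
        null.append(
            evaluation.subclass_recovery_score(
                discovered, permuted, class_labels=fx.class_labels
            )["pooled"]
        )
    return {
        "ari": score["pooled"],
        "null_95th": float(np.quantile(null, 0.95)),
        "n": n,
    }


def bootstrap_coverage_experiment(
    seed: int = 0,
    n_reps: int = 200,
    n_items: int = 300,
    n_boot: int = 400,
    p_correct_a: float = 0.8,
    p_correct_b: float = 0.7,
    n_classes: int = 3,
):
    """Monte-Carlo coverage of the 95% bootstrap CI for a known F1 gap.

    Predictions follow a symmetric-error model: each model predicts the
    true class with its own probability and otherwise errs uniformly. Under
    that symmetry per-class precision equals recall equals the correctness
    probability, so the population macro-F1 gap is exactly
    ``p_correct_a − p_correct_b``.
    """
    true_gap = p_correct_a - p_correct_b
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xC0F)))
    hits = 0
    for rep in range(n_reps):
        t = rng.integers(0, n_classes, n_items)

        def _predict(p_correct):
            correct = rng.random(n_items) < p_correct
            errs = (t + rng.integers(1, n_classes, n_items)) % n_classes
            return np.where(correct, t, errs)

        a, b = _predict(p_correct_a), _predict(p_correct_b)
        low, high = evaluation.bootstrap_f1_diff(
            a, b, t, n_classes=n_classes, n_boot=n_boot,
            seed=int(rng.integers(2**31 - 1)),
        )
        hits += int(low <= true_gap <= high)
    return {"coverage": hits / n_reps, "n": n_reps}
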