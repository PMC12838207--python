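"""End-to-end training: the :class:`SACSSL` model and its results object.

The model couples a pluggable encoder (a 4-block conv net by default, or a
tiny vision transformer) with a prediction head and a projection head, and
optimizes

    L_total = L_s + λ1·L_u + λ2·L_sac

where L_s / L_u are the labeled and pseudo-labeled cross-entropies and
L_sac is the subclass-aware contrastive term built from the two strong
views of every unlabeled image. Prototypes are momentum state, updated
after each optimizer step from the embeddings that iteration's losses saw.

Usage follows the model/results convention of statistical modelling
libraries::

    model = SACSSL.from_manifest("data/manifest.csv", config)
    res = model.fit()
    print(res.summary())
    report = res.evaluate(split="test")

Every source of randomness — weight init, shuffling, augmentation streams,
prototype init — derives from the single ``config.seed`` through named
substreams, so a run is exactly reproducible.
"""

from __future__ import annotations

import dataclasses
import io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import augment, pseudo_labeling, subclass, synthetic
from .nn import AdamW, Module, PredictionHead, ProjectionHead, SmallConvNet, TinyViT
from .tensor import Tensor, l2_normalize, no_grad

_STREAMS = {
    "init": 11,
    "labeled_shuffle": 12,
    "unlabeled_shuffle": 13,
    "weak_labeled": 14,
    "unlabeled_views": 15,
    "prototypes": 16,
}


def _substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STREAMS[name])))


@dataclasses.dataclass
class TrainConfig:
    """Hyperparameters of a training run.

    Defaults are the full-scale operating point of the method: pseudo-label
    threshold T=0.8, contrastive-partition threshold T_conf=0.9, loss
    weights λ1=1 and λ2=2, K=3 prototypes per class, embedding dimension
    D=128, transport smoothness κ=0.05, prototype momentum α=0.99, batch
    sizes 40 labeled / 80 unlabeled, 150 epochs with the learning rate
    decaying linearly 1e-3 → 1e-6 under decoupled weight decay 5e-4. The
    temperature τ=0.1 is the usual contrastive default. ``desk()`` returns
    a configuration sized for CPU-scale synthetic experiments.
    """

    n_classes: int = 3
    T: float = 0.8
    t_conf: float = 0.9
    tau: float = 0.1
    kappa: float = 0.05
    alpha: float = 0.99
    lambda1: float = 1.0
    lambda2: float = 2.0
    K: int = 3
    D: int = 128
    bl: int = 40
    bu: int = 80
    epochs: int = 150
    lr: float = 1e-3
    lr_final: float = 1e-6
    weight_decay: float = 5e-4
    sinkhorn_iters: int = 3
    encoder: str = "small-conv"
    proj_hidden: int = 128
    use_lu: bool = True
    use_unc: bool = True
    use_conf: bool = True
    # Epochs over which lambda2 ramps linearly from 0 to its configured
    # value. A cold-started encoder makes every view uncertain, and full
    # instance-level repulsion from step one prevents pseudo-label
    # confidence from ever developing; the ramp lets the pseudo-labeling
    # branch bootstrap first, standing in for the pretrained initialization
    # a full-scale run starts from. 0 disables the ramp.
    lambda2_warmup_epochs: int = 0
    strong_n_ops: int = 2
    strong_magnitude: int = 9
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.T < 1) or not (0 < self.t_conf <= 1):
            raise ValueError("thresholds must lie in (0, 1]")
        if self.tau <= 0 or self.kappa <= 0:
            raise ValueError("tau and kappa must be positive")
        if not (0 <= self.alpha <= 1):
            raise ValueError("alpha must lie in [0, 1]")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be non-negative")
        if self.bl < 1 or self.bu < 1 or self.epochs < 1:
            raise ValueError("batch sizes and epochs must be positive")
        if self.encoder not in ("small-conv", "small-vit"):
            raise ValueError("encoder preset must be 'small-conv' or 'small-vit'")

    @classmethod
    def desk(cls, **overrides) -> "TrainConfig":
        """CPU-scale preset: small batches, 30 epochs, conv encoder."""
        base = dict(
            bl=8, bu=16, epochs=30, D=64, proj_hidden=64, lambda2_warmup_epochs=10
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class ModelBundle(Module):
    """Encoder + prediction head + projection head."""

    def __init__(self, config: TrainConfig, image_size: int, rng: np.random.Generator):
        if config.encoder == "small-conv":
            self.encoder = SmallConvNet(rng)
        else:
            patch = 8 if image_size % 8 == 0 else 4
            self.encoder = TinyViT(rng, image_size=image_size, patch=patch)
        self.pred_head = PredictionHead(self.encoder.out_dim, config.n_classes, rng)
        self.proj_head = ProjectionHead(self.encoder.out_dim, config.proj_hidden, config.D, rng)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def forward_heads(bundle: ModelBundle, images):
    """Class distributions and ℓ2-normalized embeddings for an image batch.

    ``images`` is (N, 3, H, W); returns tensors on the current tape (wrap in
    :func:`sacssl.tensor.no_grad` for inference).
    """
    x = images if isinstance(images, Tensor) else Tensor(np.asarray(images))
    feats = bundle.encoder(x)
    probs = bundle.pred_head(feats)
    emb = l2_normalize(bundle.proj_head(feats), axis=-1)
    return probs, emb


def total_loss(ls, lu, l_sac, lambda1: float, lambda2: float):
    """Combined objective L_s + λ1·L_u + λ2·L_sac."""
    return ls + lambda1 * lu + lambda2 * l_sac


class _BatchCycler:
    """Endless shuffled index batches; reshuffles from its stream on exhaustion."""

    def __init__(self, indices: np.ndarray, batch_size: int, rng: np.random.Generator):
        self.indices = np.asarray(indices)
        self.batch_size = min(batch_size, len(self.indices))
        self.rng = rng
        self._order = None
        self._pos = 0

    def next(self) -> np.ndarray:
        if self._order is None or self._pos + self.batch_size > len(self._order):
            self._order = self.rng.permutation(self.indices)
            self._pos = 0
        out = self._order[self._pos : self._pos + self.batch_size]
        self._pos += self.batch_size
        return out


def _nchw(batch_hwc: list | np.ndarray) -> np.ndarray:
    arr = np.stack(batch_hwc) if isinstance(batch_hwc, list) else batch_hwc
    return np.ascontiguousarray(arr.transpose(0, 3, 1, 2))


class SACSSL:
    """Subclass-aware contrastive semi-supervised classifier.

    Built from a dataset manifest (image paths, labels with −1 for
    unlabeled, patient ids, split column) plus a :class:`TrainConfig`.
    ``fit()`` runs the full semi-supervised objective; ``fit_supervised()``
    runs an independent plain supervised loop on the labeled split only
    (the comparison baseline).
    """

    def __init__(self, manifest: pd.DataFrame, root, config: TrainConfig):
        self.config = config
        self.root = Path(root)
        self.manifest = manifest.reset_index(drop=True)
        lab = self.manifest[self.manifest["split"] == "train_labeled"]
        unl = self.manifest[self.manifest["split"] == "train_unlabeled"]
        if len(lab) == 0:
            raise ValueError("train_labeled split is empty")
        if (lab["label"] < 0).any():
            raise ValueError("labeled rows must carry labels")
        train = pd.concat([lab, unl]).reset_index(drop=True)
        self._train_manifest = train
        self.images = synthetic.load_images(train, self.root)  # (N, H, W, 3)
        self.labels = train["label"].to_numpy()
        self.labeled_idx = np.where(train["split"].to_numpy() == "train_labeled")[0]
        self.unlabeled_idx = np.where(train["split"].to_numpy() == "train_unlabeled")[0]
        self.image_size = self.images.shape[1]

    @classmethod
    def from_manifest(cls, manifest_path, config: TrainConfig) -> "SACSSL":
        path = Path(manifest_path)
        return cls(pd.read_csv(path), path.parent, config)

    # -- training loops -------------------------------------------------------

    def _build(self):
        cfg = self.config
        bundle = ModelBundle(cfg, self.image_size, _substream(cfg.seed, "init"))
        opt = AdamW(bundle.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
        return bundle, opt

    def _lr_at(self, step: int, total_steps: int) -> float:
        cfg = self.config
        frac = step / max(total_steps - 1, 1)
        return cfg.lr + (cfg.lr_final - cfg.lr) * frac

    def fit(self, verbose: bool = False) -> "SACSSLResults":
        """Train with the combined semi-supervised objective."""
        cfg = self.config
        unlabeled_on = (cfg.use_lu or cfg.use_unc or cfg.use_conf) and len(
            self.unlabeled_idx
        ) > 0
        bundle, opt = self._build()
        bank = subclass.init_prototype_bank(
            cfg.n_classes, cfg.K, cfg.D, _substream(cfg.seed, "prototypes"), cfg.alpha
        )
        lab_cycler = _BatchCycler(
            self.labeled_idx, cfg.bl, _substream(cfg.seed, "labeled_shuffle")
        )
        unl_cycler = _BatchCycler(
            self.unlabeled_idx, cfg.bu, _substream(cfg.seed, "unlabeled_shuffle")
        )
        rng_weak = _substream(cfg.seed, "weak_labeled")
        rng_views = _substream(cfg.seed, "unlabeled_views")
        policy = augment.AugmentationPolicy(
            kind="strong", n_ops=cfg.strong_n_ops, magnitude=cfg.strong_magnitude
        )
        if unlabeled_on:
            iters_per_epoch = max(len(self.unlabeled_idx) // unl_cycler.batch_size, 1)
        else:
            iters_per_epoch = max(len(self.labeled_idx) // lab_cycler.batch_size, 1)
        total_steps = cfg.epochs * iters_per_epoch
        log: list[dict] = []
        step = 0
        for epoch in range(cfg.epochs):
            for _ in range(iters_per_epoch):
                opt.lr = self._lr_at(step, total_steps)
                rec = {"epoch": epoch, "step": step, "lr": opt.lr}
                lab_batch = lab_cycler.next()
                xw_l = [
                    augment.weak_augment(self.images[i], rng_weak) for i in lab_batch
                ]
                y_l = self.labels[lab_batch]
                if unlabeled_on:
                    unl_batch = unl_cycler.next()
                    bu = len(unl_batch)
                    weak_u, s1, s2 = augment.make_views(
                        [self.images[i] for i in unl_batch], rng_views, policy
                    )
                    with no_grad():
                        probs_wu, _ = forward_heads(bundle, _nchw(weak_u))
                    plb = pseudo_labeling.compute_pseudo_labels(probs_wu.data, cfg.T)
                    x = Tensor(_nchw(xw_l + s1 + s2))
                    probs, emb = forward_heads(bundle, x)
                    nl = len(lab_batch)
                    ls = pseudo_labeling.supervised_loss(probs[:nl], y_l)
                    lu = (
                        pseudo_labeling.unsupervised_loss(probs[nl : nl + bu], plb)
                        if cfg.use_lu
                        else Tensor(0.0)
                    )
                    z = emb[nl:]
                    q_tilde = np.vstack([plb.soft, plb.soft])
                    part = subclass.partition_confidence(q_tilde, cfg.t_conf)
                    l_unc = (
                        subclass.instance_contrastive_loss(z, part, cfg.tau)
                        if cfg.use_unc
                        else Tensor(0.0)
                    )
                    if cfg.use_conf:
                        asg = subclass.assign_subclasses(
                            z.data, part, q_tilde, bank, cfg.kappa, cfg.sinkhorn_iters
                        )
                        l_conf = subclass.subclass_contrastive_loss(z, asg, cfg.tau)
                    else:
                        asg, l_conf = None, Tensor(0.0)
                    l_sac = subclass.subclass_aware_loss(l_conf, l_unc, bu)
                    if cfg.lambda2_warmup_epochs > 0:
                        ramp = min(epoch / cfg.lambda2_warmup_epochs, 1.0)
                    else:
                        ramp = 1.0
                    lt = total_loss(ls, lu, l_sac, cfg.lambda1, cfg.lambda2 * ramp)
                    rec.update(
                        ls=ls.item(),
                        lu=lu.item(),
                        l_unc=l_unc.item(),
                        l_conf=l_conf.item(),
                        l_sac=l_sac.item(),
                        l_total=lt.item(),
                        lambda2_eff=cfg.lambda2 * ramp,
                        coverage=plb.coverage,
                        confident_fraction=part.confident_fraction,
                    )
                else:
                    probs, _ = forward_heads(bundle, Tensor(_nchw(xw_l)))
                    ls = pseudo_labeling.supervised_loss(probs, y_l)
                    lt = ls
                    rec.update(
                        ls=ls.item(), lu=0.0, l_unc=0.0, l_conf=0.0, l_sac=0.0,
                        l_total=lt.item(), coverage=0.0, confident_fraction=0.0,
                    )
                if not np.isfinite(rec["l_total"]):
                    raise FloatingPointError(
                        f"non-finite loss at step {step}: {json.dumps(rec)}"
                    )
                opt.zero_grad()
                lt.backward()
                opt.step()
                if unlabeled_on and cfg.use_conf and asg is not None:
                    new_bank = subclass.update_prototypes(bank, z.data, asg)
                    rec["prototype_drift"] = float(
                        np.linalg.norm(new_bank.vectors - bank.vectors)
                    )
                    bank = new_bank
                log.append(rec)
                step += 1
            if verbose:
                print(f"epoch {epoch}: L_total={log[-1]['l_total']:.4f}")
        return SACSSLResults(bundle, bank, self.config, log, self.image_size)

    def fit_supervised(self, verbose: bool = False) -> "SACSSLResults":
        """Plain supervised cross-entropy loop on the labeled split only."""
        cfg = self.config
        bundle, opt = self._build()
        lab_cycler = _BatchCycler(
            self.labeled_idx, cfg.bl, _substream(cfg.seed, "labeled_shuffle")
        )
        rng_weak = _substream(cfg.seed, "weak_labeled")
        iters_per_epoch = max(len(self.labeled_idx) // lab_cycler.batch_size, 1)
        total_steps = cfg.epochs * iters_per_epoch
        log: list[dict] = []
        step = 0
        for epoch in range(cfg.epochs):
            for _ in range(iters_per_epoch):
                opt.lr = self._lr_at(step, total_steps)
                batch = lab_cycler.next()
                xw = [augment.weak_augment(self.images[i], rng_weak) for i in batch]
                probs, _ = forward_heads(bundle, Tensor(_nchw(xw)))
                ls = pseudo_labeling.supervised_loss(probs, self.labels[batch])
                if not np.isfinite(ls.item()):
                    raise FloatingPointError(f"non-finite loss at step {step}")
                opt.zero_grad()
                ls.backward()
                opt.step()
                log.append(
                    {
                        "epoch": epoch, "step": step, "lr": opt.lr, "ls": ls.item(),
                        "lu": 0.0, "l_unc": 0.0, "l_conf": 0.0, "l_sac": 0.0,
                        "l_total": ls.item(), "coverage": 0.0, "confident_fraction": 0.0,
                    }
                )
                step += 1
            if verbose:
                print(f"epoch {epoch}: L_s={log[-1]['ls']:.4f}")
        bank = subclass.init_prototype_bank(
            cfg.n_classes, cfg.K, cfg.D, _substream(cfg.seed, "prototypes"), cfg.alpha
        )
        return SACSSLResults(bundle, bank, self.config, log, self.image_size)


class SACSSLResults:
    """Fitted model state: weights, prototype bank, per-iteration log."""

    def __init__(self, bundle, bank, config, log, image_size):
        self.bundle = bundle
        self.prototypes = bank
        self.config = config
        self._log = log
        self.image_size = image_size

    @property
    def train_log(self) -> pd.DataFrame:
        return pd.DataFrame(self._log)

    # -- inference ------------------------------------------------------------

    def forward(self, manifest: pd.DataFrame, root, batch_size: int = 256):
        """Probabilities and unit-norm embeddings for manifest images (no grad)."""
        images = synthetic.load_images(manifest, root)
        probs_out, emb_out = [], []
        with no_grad():
            for a in range(0, len(images), batch_size):
                p, e = forward_heads(self.bundle, _nchw(images[a : a + batch_size]))
                probs_out.append(p.data)
                emb_out.append(e.data)
        if not probs_out:
            return np.zeros((0, self.config.n_classes)), np.zeros((0, self.config.D))
        return np.vstack(probs_out), np.vstack(emb_out)

    def predict(self, manifest: pd.DataFrame, root):
        probs, _ = self.forward(manifest, root)
        return probs.argmax(axis=1), probs

    def evaluate(self, manifest: pd.DataFrame, root, split: str | None = "test"):
        """MetricsReport on the given manifest rows (default: the test split)."""
        from . import evaluation

        rows = manifest if split is None else manifest[manifest["split"] == split]
        pred, _ = self.predict(rows, root)
        true_col = "true_label" if "true_label" in rows else "label"
        truth = rows[true_col].to_numpy()
        cm = evaluation.confusion_matrix(truth, pred, self.config.n_classes)
        return evaluation.metrics(cm)

    def export_embeddings(self, manifest: pd.DataFrame, root) -> pd.DataFrame:
        from . import evaluation

        return evaluation.export_embeddings(self, manifest, root)

    # -- reporting ------------------------------------------------------------

    def summary(self) -> str:
        cfg = self.config
        tail = self._log[-1] if self._log else {}
        buf = io.StringIO()
        buf.write("SACSSL training results\n")
        buf.write("=" * 60 + "\n")
        buf.write(f"encoder preset      : {cfg.encoder}\n")
        buf.write(f"parameters          : {self.bundle.n_parameters()}\n")
        buf.write(f"classes / prototypes: C={cfg.n_classes}, K={cfg.K}, D={cfg.D}\n")
        buf.write(
            f"thresholds          : T={cfg.T}, T_conf={cfg.t_conf}, tau={cfg.tau}, "
            f"kappa={cfg.kappa}, alpha={cfg.alpha}\n"
        )
        buf.write(f"loss weights        : lambda1={cfg.lambda1}, lambda2={cfg.lambda2}\n")
        buf.write(
            f"schedule            : {cfg.epochs} epochs, lr {cfg.lr} -> {cfg.lr_final}, "
            f"wd {cfg.weight_decay}, Bl={cfg.bl}, Bu={cfg.bu}\n"
        )
        if tail:
            buf.write("-" * 60 + "\n")
            buf.write(
                "final iteration     : "
                f"L_s={tail['ls']:.4f}  L_u={tail['lu']:.4f}  "
                f"L_sac={tail['l_sac']:.4f}  L_total={tail['l_total']:.4f}\n"
            )
            buf.write(
                f"pseudo-label coverage={tail['coverage']:.2f}  "
                f"confident fraction={tail['confident_fraction']:.2f}\n"
            )
        return buf.getvalue()

    # -- persistence ----------------------------------------------------------

    def save(self, path):
        """Single-archive checkpoint: weights, prototypes, config, log."""
        path = Path(path)
        arrays = {f"param_{i}": a for i, a in enumerate(self.bundle.state_arrays())}
        arrays["prototypes"] = self.prototypes.vectors
        np.savez(
            path,
            config=json.dumps(self.config.to_dict()),
            log=json.dumps(self._log),
            image_size=self.image_size,
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "SACSSLResults":
        with np.load(path, allow_pickle=False) as data:
            cfg = TrainConfig(**json.loads(str(data["config"])))
            log = json.loads(str(data["log"]))
            image_size = int(data["image_size"])
            bundle = ModelBundle(cfg, image_size, _substream(cfg.seed, "init"))
            n_params = len(bundle.parameters())
            bundle.load_state_arrays([data[f"param_{i}"] for i in range(n_params)])
            bank = subclass.PrototypeBank(
                vectors=np.asarray(data["prototypes"]), momentum=cfg.alpha
            )
        return cls(bundle, bank, cfg, log, image_size)
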