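"""Synthetic endoscopy-like datasets with known class and subclass structure.

Real colonoscopy grading tasks pair subtle between-class differences with
strong within-class heterogeneity: a single disease class contains several
visually distinct presentation modes. The generator emulates exactly that
geometry. Each class is a texture family with its own color tint; each of
its ``k_true`` latent subclasses is a deterministic geometric variant
(orientation / scale / blob count) of the family motif, and individual
images add small positional jitter plus pixel noise. Images therefore
cluster around per-subclass pixel centroids that are tighter than the class
centroid, which is the property the subclass-aware contrastive machinery is
meant to exploit.

Patients are first-class citizens: every image belongs to a patient, every
patient belongs to a single class, and dataset splits are performed at the
patient level so no patient leaks across train/test or labeled/unlabeled
boundaries.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

MANIFEST_COLUMNS = ["image_path", "label", "subclass", "patient_id", "split"]


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a generated dataset.

    noise_sd is the per-pixel Gaussian noise standard deviation on the
    [0, 1] intensity scale; class_proportions, when given, reweights the
    number of images per class (default balanced).
    """

    n_classes: int = 3
    k_true: int = 3
    images_per_subclass: int = 40
    image_size: int = 32
    noise_sd: float = 0.08
    class_proportions: tuple | None = None
    n_patients: int = 24
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 1 or self.k_true < 1 or self.images_per_subclass < 1:
            raise ValueError("counts must be positive")
        if self.image_size < 8:
            raise ValueError("image_size must be at least 8")
        if not (0 <= self.noise_sd <= 1):
            raise ValueError("noise_sd must lie in [0, 1]")
        if self.n_patients < self.n_classes:
            raise ValueError("need at least one patient per class")
        if self.class_proportions is not None:
            p = np.asarray(self.class_proportions, dtype=float)
            if len(p) != self.n_classes:
                raise ValueError("class_proportions length must equal n_classes")
            if np.any(p <= 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("class_proportions must be positive and sum to 1")


# one shared mucosa-like tint for every class: inter-class differences must
# come from texture, not color, mirroring the subtlety of the real task
_TINT = np.array([0.78, 0.55, 0.5])


def _motif(c: int, s: int, k_true: int, size: int, rng: np.random.Generator) -> np.ndarray:
    """Grayscale base pattern for (class, subclass) with per-image jitter.

    The class picks the texture family; the subclass picks a geometric
    variant of it (orientation, blob count, cell scale), so within-class
    variability is large and structured while between-class differences
    stay textural.
    """
    yy, xx = np.mgrid[0:size, 0:size] / size
    family = c % 3
    angle = (s / max(k_true, 1)) * (np.pi / 2) + 0.08 * rng.normal()
    u = np.cos(angle) * xx + np.sin(angle) * yy
    v = -np.sin(angle) * xx + np.cos(angle) * yy
    if family == 0:  # oriented sinusoidal grating
        freq = 4 + 2 * (c // 3)
        phase = 0.6 * rng.normal()
        g = 0.5 + 0.5 * np.sin(2 * np.pi * freq * u + phase)
    elif family == 1:  # lattice of soft blobs, count grows with subclass
        n_blobs = s + 2
        g = np.zeros((size, size))
        for b in range(n_blobs):
            cx = (b + 0.5) / n_blobs + 0.03 * rng.normal()
            cy = 0.5 + 0.3 * np.sin(angle + b) + 0.03 * rng.normal()
            g += np.exp(-(((u - cx) ** 2 + (v - cy) ** 2) / (2 * 0.06**2)))
        g = np.clip(g, 0, 1)
    else:  # checkerboard, cell size set by subclass
        cells = 2 * (s + 2)
        g = ((np.floor(u * cells) + np.floor(v * cells)) % 2).astype(float)
    return g


def render_image(
    c: int, s: int, k_true: int, size: int, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """One RGB image in [0,1], HWC float, for class ``c`` subclass ``s``."""
    g = _motif(c, s, k_true, size, rng)
    amplitude = 0.45 + 0.15 * rng.random()  # per-image illumination variation
    img = 0.2 + amplitude * g[:, :, None] * _TINT[None, None, :]
    img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def _class_counts(spec: SyntheticSpec) -> np.ndarray:
    total_default = spec.n_classes * spec.k_true * spec.images_per_subclass
    if spec.class_proportions is None:
        return np.full(spec.n_classes, spec.k_true * spec.images_per_subclass, dtype=int)
    p = np.asarray(spec.class_proportions, dtype=float)
    counts = np.maximum(np.rint(p * total_default).astype(int), spec.k_true)
    return counts


def generate_dataset(spec: SyntheticSpec, out_dir) -> pd.DataFrame:
    """Write PNG images plus ``manifest.csv`` under ``out_dir``; return the manifest.

    Deterministic for a fixed spec (including seed). All rows start in split
    ``train``; apply :func:`split_by_patient` afterwards.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence((int(spec.seed), 0xDA7A)))

    counts = _class_counts(spec)
    patients_per_class = max(spec.n_patients // spec.n_classes, 1)
    rows = []
    idx = 0
    for c in range(spec.n_classes):
        pids = [f"P{c}{j:03d}" for j in range(patients_per_class)]
        for j in range(counts[c]):
            s = j % spec.k_true
            img = render_image(c, s, spec.k_true, spec.image_size, spec.noise_sd, rng)
            rel = f"images/img_{idx:05d}.png"
            Image.fromarray((img * 255).round().astype(np.uint8)).save(out_dir / rel)
            rows.append(
                {
                    "image_path": rel,
                    "label": c,
                    "subclass": s,
                    "patient_id": pids[j % patients_per_class],
                    "split": "train",
                }
            )
            idx += 1
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def split_by_patient(
    manifest: pd.DataFrame,
    labeled_fraction: float = 0.2,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Patient-level split into train_labeled / train_unlabeled / test.

    Fractions are by image count, achieved greedily over a seeded patient
    shuffle within each class (so every class appears in every split).
    Unlabeled rows get ``label`` −1; the ground truth is preserved in a
    ``true_label`` column for evaluation only — training code must not read
    it.
    """
    for name, f in (("labeled_fraction", labeled_fraction), ("test_fraction", test_fraction)):
        if not (0.0 < f < 1.0):
            raise ValueError(f"{name} must lie strictly inside (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x5417)))

    out = manifest.copy()
    out["true_label"] = out["label"]
    counts = out.groupby("patient_id").size()
    pid_class = out.groupby("patient_id")["label"].first()

    def _greedy(pids: list, target: float) -> int:
        """Prefix length whose cumulative image count is nearest the target."""
        taken = 0
        for i, pid in enumerate(pids):
            if abs(taken + counts[pid] - target) >= abs(taken - target):
                return i
            taken += counts[pid]
        return len(pids)

    assign: dict[str, str] = {}
    for c in sorted(pid_class.unique()):
        pids = sorted(pid_class.index[pid_class == c])
        rng.shuffle(pids)
        total = int(counts[pids].sum())
        cut = _greedy(pids, test_fraction * total)
        cut = min(max(cut, 1), len(pids) - 1)  # ≥1 test and ≥1 train patient
        test_pids, train_pids = pids[:cut], pids[cut:]
        for pid in test_pids:
            assign[pid] = "test"
        train_total = int(counts[train_pids].sum())
        cut = max(_greedy(train_pids, labeled_fraction * train_total), 1)
        for i, pid in enumerate(train_pids):
            assign[pid] = "train_labeled" if i < cut else "train_unlabeled"

    out["split"] = out["patient_id"].map(assign)
    out.loc[out["split"] == "train_unlabeled", "label"] = -1
    return out


@dataclasses.dataclass
class EmbeddingFixture:
    """Unit vectors clustered around C·k_true component mean directions."""

    vectors: np.ndarray  # (N, D), unit rows
    class_labels: np.ndarray  # (N,)
    subclass_labels: np.ndarray  # (N,)
    component_means: np.ndarray  # (C*k_true, D), unit rows
    concentration: float


def generate_embedding_fixture(
    C: int,
    k_true: int,
    n_per_component: int,
    concentration: float,
    D: int,
    seed: int = 0,
) -> EmbeddingFixture:
    """Directional mixture on the sphere: sample ≈ normalize(κ·μ + ε).

    Larger ``concentration`` gives tighter components; in the limit every
    point equals its component mean. Component means are drawn uniformly on
    the sphere and resampled until pairwise separated, so components are
    distinguishable whenever D is not tiny.
    """
    if D < 2:
        raise ValueError("D must be at least 2")
    if C < 1 or k_true < 1 or n_per_component < 1 or concentration <= 0:
        raise ValueError("invalid fixture parameters")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xF1C5)))
    n_comp = C * k_true
    for _ in range(200):
        means = rng.normal(size=(n_comp, D))
        means /= np.linalg.norm(means, axis=1, keepdims=True)
        gram = means @ means.T
        np.fill_diagonal(gram, -1.0)
        if gram.max() < 0.7:
            break
    labels_c = np.repeat(np.arange(C), k_true * n_per_component)
    labels_s = np.tile(np.repeat(np.arange(k_true), n_per_component), C)
    comp_idx = np.repeat(np.arange(n_comp), n_per_component)
    noise = rng.normal(size=(n_comp * n_per_component, D))
    vecs = concentration * means[comp_idx] + noise
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    return EmbeddingFixture(
        vectors=vecs,
        class_labels=labels_c,
        subclass_labels=labels_s,
        component_means=means,
        concentration=float(concentration),
    )


def load_images(manifest: pd.DataFrame, root) -> np.ndarray:
    """Load manifest rows as a float array (N, H, W, 3) in [0, 1]."""
    root = Path(root)
    imgs = [
        np.asarray(Image.open(root / rel).convert("RGB"), dtype=np.float64) / 255.0
        for rel in manifest["image_path"]
    ]
    return np.stack(imgs) if imgs else np.zeros((0, 0, 0, 3))
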