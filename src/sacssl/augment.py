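"""Weak and strong stochastic augmentation views.

The weak policy is crop-with-padding plus horizontal flip. The strong
policy samples ``n_ops`` operations from a 9-operation catalogue
(rotate, translate, shear, solarize, posterize, contrast, brightness,
sharpness, equalize) with magnitudes on a 0–10 scale, followed by cutout —
the standard strong-augmentation recipe in confidence-thresholded
semi-supervised pipelines. Geometric operations use reflection padding and
pixel operations act per channel, so outputs stay inside [0, 1].

All randomness flows through an explicit ``numpy.random.Generator``; a
fixed generator state yields a fixed output.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from PIL import Image, ImageEnhance, ImageOps

STRONG_OPS = (
    "rotate",
    "translate_x",
    "translate_y",
    "shear_x",
    "shear_y",
    "solarize",
    "posterize",
    "contrast",
    "brightness",
    "sharpness",
    "equalize",
)
# catalogue actually sampled from (9 ops; the translate/shear axis variants
# count as one op each with a random axis)
_SAMPLED_OPS = (
    "rotate",
    "translate",
    "shear",
    "solarize",
    "posterize",
    "contrast",
    "brightness",
    "sharpness",
    "equalize",
)


@dataclasses.dataclass(frozen=True)
class AugmentationPolicy:
    kind: str = "strong"  # "weak" | "strong"
    n_ops: int = 2
    magnitude: int = 9
    cutout: bool = True
    crop_padding: int = 4

    def __post_init__(self):
        if self.kind not in ("weak", "strong"):
            raise ValueError("kind must be 'weak' or 'strong'")
        if not (0 <= self.magnitude <= 10):
            raise ValueError("magnitude on the 0-10 scale")


def _to_pil(img: np.ndarray) -> Image.Image:
    return Image.fromarray((np.clip(img, 0, 1) * 255).round().astype(np.uint8))


def _from_pil(im: Image.Image) -> np.ndarray:
    return np.asarray(im, dtype=np.float64) / 255.0


def weak_augment(
    img: np.ndarray, rng: np.random.Generator, padding: int = 4, flip: bool = True
) -> np.ndarray:
    """Reflection-padded random crop back to original size, then random h-flip."""
    h, w = img.shape[:2]
    if padding > 0:
        padded = np.pad(
            img, ((padding, padding), (padding, padding), (0, 0)), mode="reflect"
        )
        oy = int(rng.integers(0, 2 * padding + 1))
        ox = int(rng.integers(0, 2 * padding + 1))
        out = padded[oy : oy + h, ox : ox + w]
    else:
        out = img
    if flip and rng.random() < 0.5:
        out = out[:, ::-1]
    return np.ascontiguousarray(out)


def _affine(im: Image.Image, coeffs) -> Image.Image:
    # reflection padding: pre-expand, transform, crop center
    w, h = im.size
    big = ImageOps.expand(im, border=(w // 2, h // 2))
    a, b, c, d, e, f = coeffs
    big = big.transform(
        big.size, Image.AFFINE, (a, b, c + (a - 1) * w / 2 + b * h / 2,
                                 d, e, f + d * w / 2 + (e - 1) * h / 2),
        resample=Image.BILINEAR,
    )
    return big.crop((w // 2, h // 2, w // 2 + w, h // 2 + h))


def _apply_strong_op(im: Image.Image, op: str, level: float, rng) -> Image.Image:
    """Apply one catalogue op at ``level`` in [0,1]; sign of geometric ops random."""
    sign = 1 if rng.random() < 0.5 else -1
    if op == "rotate":
        return _affine_rotate(im, sign * 30 * level)
    if op == "translate":
        shift = sign * 0.3 * level * im.size[0]
        if rng.random() < 0.5:
            return _affine(im, (1, 0, shift, 0, 1, 0))
        return _affine(im, (1, 0, 0, 0, 1, shift))
    if op == "shear":
        s = sign * 0.3 * level
        if rng.random() < 0.5:
            return _affine(im, (1, s, 0, 0, 1, 0))
        return _affine(im, (1, 0, 0, s, 1, 0))
    if op == "solarize":
        return ImageOps.solarize(im, threshold=int(255 * (1 - level)))
    if op == "posterize":
        bits = max(8 - int(4 * level), 4)
        return ImageOps.posterize(im, bits)
    if op == "contrast":
        return ImageEnhance.Contrast(im).enhance(1 + sign * 0.9 * level)
    if op == "brightness":
        return ImageEnhance.Brightness(im).enhance(1 + sign * 0.9 * level)
    if op == "sharpness":
        return ImageEnhance.Sharpness(im).enhance(1 + sign * 0.9 * level)
    if op == "equalize":
        return ImageOps.equalize(im)
    raise ValueError(f"unknown op {op!r}")


def _affine_rotate(im: Image.Image, deg: float) -> Image.Image:
    w, h = im.size
    big = ImageOps.expand(im, border=(w // 2, h // 2))
    big = big.rotate(deg, resample=Image.BILINEAR, center=(w, h))
    return big.crop((w // 2, h // 2, w // 2 + w, h // 2 + h))


def cutout(img: np.ndarray, rng: np.random.Generator, frac: float = 0.5) -> np.ndarray:
    """Zero-information gray square of side frac·min(H,W) at a random center."""
    h, w = img.shape[:2]
    side = int(frac * min(h, w))
    if side == 0:
        return img
    cy = int(rng.integers(0, h))
    cx = int(rng.integers(0, w))
    y0, y1 = max(cy - side // 2, 0), min(cy + side // 2, h)
    x0, x1 = max(cx - side // 2, 0), min(cx + side // 2, w)
    out = img.copy()
    out[y0:y1, x0:x1] = 0.5
    return out


def strong_augment(
    img: np.ndarray,
    rng: np.random.Generator,
    policy: AugmentationPolicy | None = None,
) -> np.ndarray:
    """Random-op strong augmentation followed by cutout; output clipped to [0,1]."""
    policy = policy or AugmentationPolicy()
    im = _to_pil(img)
    for _ in range(policy.n_ops):
        op = _SAMPLED_OPS[int(rng.integers(0, len(_SAMPLED_OPS)))]
        level = float(rng.integers(1, policy.magnitude + 1)) / 10.0
        im = _apply_strong_op(im, op, level, rng)
    out = _from_pil(im)
    if policy.cutout:
        out = cutout(out, rng)
    return np.clip(out, 0.0, 1.0)


def make_views(
    images,
    rng: np.random.Generator,
    strong_policy: AugmentationPolicy | None = None,
    crop_padding: int = 4,
    weak_flip: bool = True,
):
    """Weak view + two strong views per image, index-aligned with the input.

    Index m of each returned list derives from ``images[m]``; this pairing is
    what the multi-view batch and its view-partner involution rely on.
    """
    weak, s1, s2 = [], [], []
    for img in images:
        weak.append(weak_augment(img, rng, padding=crop_padding, flip=weak_flip))
        s1.append(strong_augment(img, rng, strong_policy))
        s2.append(strong_augment(img, rng, strong_policy))
    return weak, s1, s2
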