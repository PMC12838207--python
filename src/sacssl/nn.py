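"""Neural building blocks on top of the autodiff core.

Two encoder presets are provided: a 4-block strided conv net (default) and a
tiny vision transformer. Both map NCHW image batches to a flat feature
vector; the prediction head emits class probabilities and the projection
head emits an embedding for contrastive learning.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concatenate, conv2d, log_softmax, softmax


class Module:
    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_arrays(self):
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays):
        for p, a in zip(self.parameters(), arrays, strict=True):
            p.data = np.asarray(a, dtype=np.float64).copy()

    def __call__(self, x):
        return self.forward(x)


def _he(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, n_in, n_out, rng):
        self.weight = Tensor(_he(rng, (n_in, n_out), n_in), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x):
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, cin, cout, k, stride, padding, rng):
        fan_in = cin * k * k
        self.weight = Tensor(_he(rng, (cout, cin, k, k), fan_in), requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)
        self.stride, self.padding = stride, padding

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class LayerNorm(Module):
    def __init__(self, dim, eps=1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class SmallConvNet(Module):
    """Four stride-2 conv blocks with ReLU, then global average pooling."""

    def __init__(self, rng, channels=(16, 32, 64, 64)):
        cin = 3
        self.blocks = []
        for cout in channels:
            self.blocks.append(Conv2d(cin, cout, 3, stride=2, padding=1, rng=rng))
            cin = cout
        self.out_dim = channels[-1]

    def forward(self, x):
        for conv in self.blocks:
            x = conv(x).relu()
        return x.mean(axis=(2, 3))  # (N, C)


class _AttentionBlock(Module):
    def __init__(self, dim, rng):
        self.norm1 = LayerNorm(dim)
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(dim, 2 * dim, rng)
        self.fc2 = Linear(2 * dim, dim, rng)
        self.dim = dim

    def forward(self, x):  # x: (N, T, dim), single head
        d = self.dim
        h = self.norm1(x)
        qkv = self.qkv(h)
        q, k, v = (qkv[:, :, i * d : (i + 1) * d] for i in range(3))
        attn = softmax(q @ k.transpose(0, 2, 1) * (1.0 / np.sqrt(d)), axis=-1)
        x = x + self.proj(attn @ v)
        h = self.norm2(x)
        return x + self.fc2(self.fc1(h).relu())


class TinyViT(Module):
    """Patch-embedding transformer with two single-head blocks; mean pooling."""

    def __init__(self, rng, image_size=32, patch=8, dim=48, depth=2):
        self.patch = patch
        n_tokens = (image_size // patch) ** 2
        self.embed = Linear(3 * patch * patch, dim, rng)
        self.pos = Tensor(0.02 * rng.normal(size=(1, n_tokens, dim)), requires_grad=True)
        self.blocks = [_AttentionBlock(dim, rng) for _ in range(depth)]
        self.norm = LayerNorm(dim)
        self.out_dim = dim

    def forward(self, x):  # (N, 3, H, W)
        n, c, h, w = x.shape
        p = self.patch
        t = x.reshape(n, c, h // p, p, w // p, p)
        t = t.transpose(0, 2, 4, 1, 3, 5).reshape(n, (h // p) * (w // p), c * p * p)
        t = self.embed(t) + self.pos
        for blk in self.blocks:
            t = blk(t)
        return self.norm(t).mean(axis=1)


class PredictionHead(Module):
    def __init__(self, n_in, n_classes, rng):
        self.fc = Linear(n_in, n_classes, rng)

    def log_probs(self, feats):
        return log_softmax(self.fc(feats), axis=-1)

    def forward(self, feats):
        return self.log_probs(feats).exp()


class ProjectionHead(Module):
    """Two-layer MLP projector; output is ℓ2-normalized by the caller."""

    def __init__(self, n_in, n_hidden, n_out, rng):
        self.fc1 = Linear(n_in, n_hidden, rng)
        self.fc2 = Linear(n_hidden, n_out, rng)

    def forward(self, feats):
        return self.fc2(self.fc1(feats).relu())


class AdamW:
    """Adam with decoupled weight decay and externally scheduled learning rate."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=5e-4):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (
                (m / b1t) / (np.sqrt(v / b2t) + self.eps) + self.weight_decay * p.data
            )

    def zero_grad(self):
        for p in self.params:
            p.grad = None
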