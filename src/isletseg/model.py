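"""AA-Net: an encoder–attention–decoder network for islet segmentation.

The architecture has three parts:

* a *twin-block* encoder — a shortcut-free (SF) double-conv block at each
  end, with four ResNet blocks in the middle, each followed by 2x2 max
  pooling, so the bottleneck is 1/16 of the input resolution;
* an affinity-aware attention bottleneck (AAM) that computes pairwise
  pixel-feature affinities over the whole bottleneck map, row-softmax
  normalises them, and aggregates value features with those weights, so
  each position is informed by every other position;
* a U-Net-style decoder: four 2x2 transposed-convolution upsampling
  stages with skip connections from the pre-pool encoder features.

The attention arithmetic is exposed as three pure NumPy functions
(:func:`affinity`, :func:`normalize_affinity`, :func:`weighted_feature`)
so it can be checked against brute-force per-pixel loops independently of
the network plumbing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, concat, softmax_rows
from .layers import BatchNorm2d, Conv2d, ConvTranspose2d, MaxPool2d, Module

__all__ = [
    "affinity",
    "normalize_affinity",
    "weighted_feature",
    "AANetSpec",
    "AffinityAttention",
    "SFBlock",
    "ResNetBlock",
    "Encoder",
    "AANet",
    "count_parameters",
]


# ---------------------------------------------------------------------------
# pure attention arithmetic
# ---------------------------------------------------------------------------

def affinity(q: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Pairwise pixel-feature affinity ``W = Q^T K``.

    ``q`` and ``k`` are (C', N) projected feature matrices whose columns
    are pixels; ``W[i, j]`` is the dot product of pixel i's query feature
    with pixel j's key feature.
    """
    q = np.asarray(q)
    k = np.asarray(k)
    if q.shape != k.shape:
        raise ValueError(f"Q and K must share shape, got {q.shape} vs {k.shape}")
    return q.T @ k


def normalize_affinity(w_raw: np.ndarray) -> np.ndarray:
    """Row-wise softmax of the raw affinity matrix (max-shifted)."""
    w_raw = np.asarray(w_raw, dtype=float)
    z = w_raw - w_raw.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_feature(a: np.ndarray, v_prime: np.ndarray) -> np.ndarray:
    """Attention-weighted aggregation ``H'[c, i] = sum_j A[i, j] V'[c, j]``.

    Output pixel i is a convex combination of all value-feature columns,
    weighted by row i of the normalised affinity matrix.
    """
    a = np.asarray(a)
    v_prime = np.asarray(v_prime)
    if a.shape[0] != a.shape[1] or a.shape[1] != v_prime.shape[1]:
        raise ValueError(
            f"incompatible shapes: A {a.shape}, V' {v_prime.shape}")
    return v_prime @ a.T


# ---------------------------------------------------------------------------
# network specification
# ---------------------------------------------------------------------------

@dataclass
class AANetSpec:
    """Hyper-parameters of the network.

    ``channel_schedule`` gives the output width of each of the four
    pooled ResNet stages; the default doubles from ``base_channels``.
    ``c_prime_ratio`` is the channel-reduction divisor for the attention
    projections (C' = max(1, C // ratio)).  ``use_attention=False``
    replaces the attention bottleneck with the identity, the ablated twin
    used to measure what the attention contributes.
    """

    base_channels: int = 64
    channel_schedule: tuple = field(default=None)
    c_prime_ratio: int = 8
    use_skip_connections: bool = True
    use_attention: bool = True
    in_channels: int = 1
    out_channels: int = 1

    def __post_init__(self):
        if self.channel_schedule is None:
            b = self.base_channels
            self.channel_schedule = (b, 2 * b, 4 * b, 8 * b)
        self.channel_schedule = tuple(int(c) for c in self.channel_schedule)
        if len(self.channel_schedule) != 4:
            raise ValueError("channel_schedule must have four stages")

    def to_dict(self) -> dict:
        return {
            "base_channels": self.base_channels,
            "channel_schedule": list(self.channel_schedule),
            "c_prime_ratio": self.c_prime_ratio,
            "use_skip_connections": self.use_skip_connections,
            "use_attention": self.use_attention,
            "in_channels": self.in_channels,
            "out_channels": self.out_channels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AANetSpec":
        d = dict(d)
        if d.get("channel_schedule") is not None:
            d["channel_schedule"] = tuple(d["channel_schedule"])
        return cls(**d)


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

class SFBlock(Module):
    """Shortcut-free block: (3x3 conv -> batch norm -> ReLU) twice.

    The reduced form of the ResNet block with the additive shortcut
    removed; used at both ends of the encoder to curb feature redundancy.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng)
        self.bn2 = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn1(self.conv1(x)).relu()
        return self.bn2(self.conv2(y)).relu()


class ResNetBlock(Module):
    """SF block plus an additive identity shortcut.

    The shortcut is the identity when channel counts match, else a 1x1
    projection.  The sum is taken after the second activation, so with
    identical convolutional weights ``resnet(x) - sf(x)`` equals exactly
    the shortcut path's output.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.body = SFBlock(in_ch, out_ch, rng)
        self.proj = Conv2d(in_ch, out_ch, 1, rng) if in_ch != out_ch else None

    def forward(self, x: Tensor) -> Tensor:
        sc = self.proj(x) if self.proj is not None else x
        return self.body(x) + sc


class AffinityAttention(Module):
    """Non-local attention over the bottleneck feature map.

    Query/key/value features come from three 1x1 convolutions reducing
    C channels to C'; the N x N affinity (N = H*W) is row-softmaxed and
    used to aggregate values; the result is concatenated with the input
    and fused back to C channels by a final 1x1 convolution.
    """

    #: refuse to build an N x N affinity above this many pixels
    MAX_PIXELS = 4096

    def __init__(self, channels: int, c_prime_ratio: int, rng: np.random.Generator):
        super().__init__()
        self.channels = channels
        self.c_prime = max(1, channels // c_prime_ratio)
        self.query = Conv2d(channels, self.c_prime, 1, rng)
        self.key = Conv2d(channels, self.c_prime, 1, rng)
        self.value = Conv2d(channels, self.c_prime, 1, rng)
        self.fuse = Conv2d(channels + self.c_prime, channels, 1, rng)

    def forward(self, h: Tensor) -> Tensor:
        B, C, Hd, Wd = h.data.shape
        n = Hd * Wd
        if n > self.MAX_PIXELS:
            raise ValueError(
                f"affinity matrix would be {n}x{n}; the attention module is "
                "meant for the encoder bottleneck (e.g. 8x8 for 128-pixel "
                "patches after four poolings), not full-resolution maps")
        q = self.query(h).reshape(B, self.c_prime, n)
        k = self.key(h).reshape(B, self.c_prime, n)
        v = self.value(h).reshape(B, self.c_prime, n)
        w_raw = q.transpose(0, 2, 1).matmul(k)          # (B, N, N)
        a = softmax_rows(w_raw)
        h_prime = v.matmul(a.transpose(0, 2, 1))        # (B, C', N)
        h_prime = h_prime.reshape(B, self.c_prime, Hd, Wd)
        return self.fuse(concat([h, h_prime], axis=1))


# ---------------------------------------------------------------------------
# encoder / decoder / full network
# ---------------------------------------------------------------------------

class Encoder(Module):
    """SF -> 4 x (ResNet -> 2x2 max-pool) -> SF; output is input/16."""

    def __init__(self, spec: AANetSpec, rng: np.random.Generator):
        super().__init__()
        c = spec.channel_schedule
        self.sf_in = SFBlock(spec.in_channels, c[0], rng)
        prev = c[0]
        self.res_blocks = []
        for ch in c:
            self.res_blocks.append(ResNetBlock(prev, ch, rng))
            prev = ch
        self.pool = MaxPool2d()
        self.sf_out = SFBlock(c[3], c[3], rng)

    def forward(self, x: Tensor):
        """Return (bottleneck, skips); skips are the pre-pool stage outputs."""
        B, C, H, W = x.data.shape
        if H % 16 or W % 16:
            raise ValueError(f"spatial dims must be divisible by 16, got {H}x{W}")
        y = self.sf_in(x)
        skips = []
        for block in self.res_blocks:
            y = block(y)
            skips.append(y)
            y = self.pool(y)
        return self.sf_out(y), skips


class _DecoderStage(Module):
    def __init__(self, in_ch: int, skip_ch: int, use_skip: bool,
                 rng: np.random.Generator):
        super().__init__()
        self.use_skip = use_skip
        self.up = ConvTranspose2d(in_ch, skip_ch, rng)
        body_in = 2 * skip_ch if use_skip else skip_ch
        self.body = SFBlock(body_in, skip_ch, rng)

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        y = self.up(x)
        if self.use_skip:
            y = concat([y, skip], axis=1)
        return self.body(y)


class AANet(Module):
    """The full encoder–attention–decoder segmentation network."""

    def __init__(self, spec: AANetSpec, rng: np.random.Generator | int | None = None):
        super().__init__()
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.spec = spec
        c = spec.channel_schedule
        self.encoder = Encoder(spec, rng)
        self.dec_stages = [
            _DecoderStage(c[3], c[3], spec.use_skip_connections, rng),
            _DecoderStage(c[3], c[2], spec.use_skip_connections, rng),
            _DecoderStage(c[2], c[1], spec.use_skip_connections, rng),
            _DecoderStage(c[1], c[0], spec.use_skip_connections, rng),
        ]
        self.head = Conv2d(c[0], spec.out_channels, 1, rng)
        # built last so the ablated twin (use_attention=False) shares
        # identical encoder/decoder initial weights — paired comparisons
        self.attention = (AffinityAttention(c[3], spec.c_prime_ratio, rng)
                          if spec.use_attention else None)

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        y, skips = self.encoder(x)
        if self.attention is not None:
            y = self.attention(y)
        for stage, skip in zip(self.dec_stages, reversed(skips)):
            y = stage(y, skip)
        return self.head(y).sigmoid()

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        """Inference-mode probabilities for a (B, H, W) patch batch."""
        was_training = self.training
        self.eval()
        x = np.asarray(patches, dtype=np.float32)[:, None, :, :]
        out = self.forward(Tensor(x)).data[:, 0]
        if was_training:
            self.train()
        return out.astype(np.float64)


def count_parameters(model: Module) -> int:
    return int(sum(p.data.size for p in model.parameters()))
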