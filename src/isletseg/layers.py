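"""Neural-network layers on top of the autograd engine.

Layout convention is NCHW (batch, channel, row, col) throughout.
Convolutions use im2col with slice-based col2im so that both passes are
dense matrix products, which is what makes CPU training of the small
network tractable.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, _make

__all__ = [
    "Module",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "MaxPool2d",
]

_DT = np.float32


class Module:
    """Base class: parameter discovery, train/eval mode, state (de)serialisation."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Tensor]:
        params = []
        for m in self.modules():
            for name in getattr(m, "_param_names", ()):
                params.append(getattr(m, name))
        return params

    def weight_parameters(self) -> list[Tensor]:
        """Convolution kernels only — the set the L2 penalty acts on."""
        params = []
        for m in self.modules():
            if isinstance(m, (Conv2d, ConvTranspose2d)):
                params.append(m.weight)
        return params

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def state_dict(self) -> dict:
        state = {}
        for i, m in enumerate(self.modules()):
            for name in getattr(m, "_param_names", ()):
                state[f"{i}.{name}"] = getattr(m, name).data
            for name in getattr(m, "_buffer_names", ()):
                state[f"{i}.{name}"] = getattr(m, name)
        return state

    def load_state_dict(self, state: dict):
        for i, m in enumerate(self.modules()):
            for name in getattr(m, "_param_names", ()):
                getattr(m, name).data = np.asarray(state[f"{i}.{name}"], dtype=_DT)
            for name in getattr(m, "_buffer_names", ()):
                setattr(m, name, np.asarray(state[f"{i}.{name}"]))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(_DT)


class Conv2d(Module):
    """2-D convolution with 'same' zero padding for odd kernels."""

    _param_names = ("weight", "bias")

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.pad = kernel // 2
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(_he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=_DT), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        k, p = self.kernel, self.pad
        w, b = self.weight, self.bias
        xd = x.data
        if p:
            xd = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p)))
        B, C, Hp, Wp = xd.shape
        Ho, Wo = Hp - k + 1, Wp - k + 1
        cols = _im2col(xd, k)                       # (B*Ho*Wo, C*k*k)
        wf = w.data.reshape(self.out_ch, -1)
        y = cols @ wf.T + b.data
        y = y.reshape(B, Ho, Wo, self.out_ch).transpose(0, 3, 1, 2)
        out = _make((x, w, b), np.ascontiguousarray(y))

        def bwd(g):
            gf = g.transpose(0, 2, 3, 1).reshape(-1, self.out_ch)  # (B*Ho*Wo, O)
            if b.requires_grad:
                b._accum(gf.sum(axis=0))
            if w.requires_grad:
                w._accum((gf.T @ cols).reshape(w.data.shape))
            if x.requires_grad:
                gcols = gf @ wf                                     # (B*Ho*Wo, C*k*k)
                gx = _col2im(gcols, (B, C, Hp, Wp), k)
                if p:
                    gx = gx[:, :, p:-p, p:-p]
                x._accum(gx)

        out._backward = bwd
        return out


def _im2col(xp: np.ndarray, k: int) -> np.ndarray:
    B, C, Hp, Wp = xp.shape
    Ho, Wo = Hp - k + 1, Wp - k + 1
    s = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp, (B, C, k, k, Ho, Wo), (s[0], s[1], s[2], s[3], s[2], s[3]))
    return win.transpose(0, 4, 5, 1, 2, 3).reshape(B * Ho * Wo, C * k * k)


def _col2im(gcols: np.ndarray, shape: tuple, k: int) -> np.ndarray:
    B, C, Hp, Wp = shape
    Ho, Wo = Hp - k + 1, Wp - k + 1
    g6 = gcols.reshape(B, Ho, Wo, C, k, k).transpose(0, 3, 4, 5, 1, 2)
    gx = np.zeros(shape, dtype=gcols.dtype)
    for i in range(k):
        for j in range(k):
            gx[:, :, i:i + Ho, j:j + Wo] += g6[:, :, i, j]
    return gx


class ConvTranspose2d(Module):
    """2x2 stride-2 transposed convolution (the decoder upsampler)."""

    _param_names = ("weight", "bias")

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.weight = Tensor(_he_init(rng, (in_ch, out_ch, 2, 2), in_ch),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=_DT), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        w, b = self.weight, self.bias
        B, C, H, W = x.data.shape
        # non-overlapping stride-2 kernel: each input pixel paints a 2x2 block
        t = np.einsum("bchw,cokl->bohkwl", x.data, w.data, optimize=True)
        y = t.reshape(B, self.out_ch, 2 * H, 2 * W) + b.data[None, :, None, None]
        out = _make((x, w, b), y)

        def bwd(g):
            g6 = g.reshape(B, self.out_ch, H, 2, W, 2)
            if b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                w._accum(np.einsum("bchw,bohkwl->cokl", x.data, g6, optimize=True))
            if x.requires_grad:
                x._accum(np.einsum("bohkwl,cokl->bchw", g6, w.data, optimize=True))

        out._backward = bwd
        return out


class BatchNorm2d(Module):
    _param_names = ("gamma", "beta")
    _buffer_names = ("running_mean", "running_var")

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones(n_ch, dtype=_DT), requires_grad=True)
        self.beta = Tensor(np.zeros(n_ch, dtype=_DT), requires_grad=True)
        self.running_mean = np.zeros(n_ch, dtype=_DT)
        self.running_var = np.ones(n_ch, dtype=_DT)

    def forward(self, x: Tensor) -> Tensor:
        g, b = self.gamma, self.beta
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(_DT)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(_DT)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mean[None, :, None, None]) * inv[None, :, None, None]
        y = g.data[None, :, None, None] * xhat + b.data[None, :, None, None]
        out = _make((x, g, b), y.astype(x.data.dtype))
        training = self.training

        def bwd(gr):
            if b.requires_grad:
                b._accum(gr.sum(axis=(0, 2, 3)))
            if g.requires_grad:
                g._accum((gr * xhat).sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gxh = gr * g.data[None, :, None, None]
                if training:
                    n = gr.shape[0] * gr.shape[2] * gr.shape[3]
                    t1 = gxh.sum(axis=(0, 2, 3))[None, :, None, None]
                    t2 = (gxh * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
                    gx = (inv[None, :, None, None] / n) * (n * gxh - t1 - xhat * t2)
                else:
                    gx = gxh * inv[None, :, None, None]
                x._accum(gx.astype(x.data.dtype))

        out._backward = bwd
        return out


class MaxPool2d(Module):
    """2x2 max pooling, stride 2."""

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.data.shape
        r = x.data.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(B, C, H // 2, W // 2, 4)
        idx = r.argmax(axis=-1)
        y = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        out = _make((x,), np.ascontiguousarray(y))

        def bwd(g):
            if x.requires_grad:
                g4 = np.zeros(r.shape, dtype=g.dtype)
                np.put_along_axis(g4, idx[..., None], g[..., None], axis=-1)
                gx = g4.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
                x._accum(np.ascontiguousarray(gx.reshape(B, C, H, W)))

        out._backward = bwd
        return out
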