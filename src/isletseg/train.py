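"""Weighted-BCE training with L2 regularisation and F-score model selection.

The loss is ``L = L_w + L_r`` where

* ``L_w = Σ_i [ α · (−t_i log p_i) + (1−α) · (−(1−t_i) log(1−p_i)) ]``
  with ``α = |t−| / (|t+| + |t−|)`` the background fraction of the
  pixels the loss is computed over, so the scarce islet class is
  up-weighted exactly by the imbalance;
* ``L_r = weight_decay · Σ w²`` over the convolution kernels, an
  explicit additive penalty rather than an optimizer-side decay so the
  total loss is literally the sum of the two terms.

Model selection: after every epoch the validation patches are scored
with the F-score at the binarisation threshold and the best-scoring
parameters are kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autograd import Tensor
from .config import RunConfig
from .layers import Module
from .metrics import confusion_counts, fscore, ppv, sensitivity
from .model import AANet, AANetSpec

__all__ = ["LossTerms", "TrainState", "class_weight_alpha", "weighted_bce",
           "l2_penalty", "total_loss", "Adam", "train_model",
           "save_checkpoint", "load_checkpoint", "predict_stack"]

_EPS = 1e-7


@dataclass
class LossTerms:
    L_w: float
    L_r: float
    L: float
    alpha: float


@dataclass
class TrainState:
    epoch: int = 0
    best_fscore: float = -np.inf
    best_epoch: int = -1
    best_checkpoint: dict | None = None
    history: list = field(default_factory=list)  # (epoch, L, val F-score)
    rng_seed: int = 0

    def history_frame(self):
        import pandas as pd
        return pd.DataFrame(self.history, columns=["epoch", "loss", "val_fscore"])


def class_weight_alpha(targets) -> float:
    """Imbalance weight α = (#background) / (#total pixels)."""
    t = np.asarray(targets)
    if t.size == 0:
        raise ValueError("cannot compute class weight of an empty target set")
    n_fg = float(np.count_nonzero(t))
    return (t.size - n_fg) / t.size


def weighted_bce(p, t, alpha: float):
    """Class-weighted binary cross-entropy, summed over pixels.

    Islet pixels (t=1) contribute ``−α·log p``; background pixels
    contribute ``−(1−α)·log(1−p)``.  Probabilities are clamped to
    ``[1e-7, 1−1e-7]``.  Accepts either NumPy arrays (returns a float)
    or autograd :class:`Tensor` inputs (returns a Tensor on the tape).
    """
    if isinstance(p, Tensor):
        t = t if isinstance(t, Tensor) else Tensor(np.asarray(t, dtype=p.data.dtype))
        pc = p.clip(_EPS, 1.0 - _EPS)
        pos = t * pc.log()
        neg = (1.0 - t) * (1.0 - pc).log()
        return -(alpha * pos.sum() + (1.0 - alpha) * neg.sum())
    p = np.clip(np.asarray(p, dtype=float), _EPS, 1.0 - _EPS)
    t = np.asarray(t, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    pos = -np.sum(t * np.log(p))
    neg = -np.sum((1.0 - t) * np.log(1.0 - p))
    return float(alpha * pos + (1.0 - alpha) * neg)


def l2_penalty(model: Module, weight_decay: float) -> float:
    """L_r = weight_decay · Σ w² over convolution kernels."""
    return float(weight_decay *
                 sum(float(np.sum(w.data.astype(np.float64) ** 2))
                     for w in model.weight_parameters()))


def total_loss(l_w: float, model: Module, weight_decay: float,
               alpha: float) -> LossTerms:
    """Assemble L = L_w + L_r."""
    l_r = l2_penalty(model, weight_decay)
    return LossTerms(L_w=float(l_w), L_r=l_r, L=float(l_w) + l_r, alpha=alpha)


class Adam:
    """Adam with the conventional defaults (β1=0.9, β2=0.999, ε=1e-8)."""

    def __init__(self, params: list, lr: float = 1e-5,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def _validation_fscore(model: AANet, images: np.ndarray, masks: np.ndarray,
                       threshold: float, batch: int = 16) -> float:
    """F-score over all validation pixels pooled together."""
    preds = []
    for i in range(0, len(images), batch):
        preds.append(model.predict_proba(images[i:i + batch]))
    pred_mask = np.concatenate(preds) >= threshold
    c = confusion_counts(pred_mask, masks.astype(bool))
    return fscore(sensitivity(c), ppv(c))


def train_model(train_patches, val_patches, config: RunConfig,
                spec: AANetSpec | None = None,
                checkpoint_path=None, per_batch_alpha: bool = True,
                verbose: bool = False):
    """Train an AA-Net on (image, mask) patch pairs.

    ``train_patches`` and ``val_patches`` are ``(images, masks)`` tuples
    of arrays shaped (n, H, W).  Inputs are standardised with the
    training set's mean and standard deviation (stored in the
    checkpoint).  Returns ``(model, TrainState)``; when
    ``checkpoint_path`` is given the best checkpoint is also written to
    disk.
    """
    train_imgs, train_masks = (np.asarray(a) for a in train_patches)
    val_imgs, val_masks = (np.asarray(a) for a in val_patches)
    if len(train_imgs) == 0 or len(val_imgs) == 0:
        raise ValueError("training and validation sets must be non-empty")
    spec = spec or AANetSpec()
    rng = np.random.default_rng(config.seed)
    model = AANet(spec, rng)

    mu = float(train_imgs.mean())
    sd = float(train_imgs.std()) or 1.0
    x_train = ((train_imgs - mu) / sd).astype(np.float32)
    x_val = ((val_imgs - mu) / sd).astype(np.float32)
    y_train = train_masks.astype(np.float32)

    global_alpha = class_weight_alpha(train_masks)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    state = TrainState(rng_seed=config.seed)
    norm = {"mean": mu, "std": sd}

    n = len(x_train)
    for epoch in range(1, config.max_epochs + 1):
        model.train()
        order = rng.permutation(n)
        epoch_lw = 0.0
        alpha = global_alpha
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = Tensor(x_train[idx][:, None])
            yb = y_train[idx][:, None]
            if per_batch_alpha:
                alpha = class_weight_alpha(yb)
            probs = model(xb)
            loss = weighted_bce(probs, Tensor(yb), alpha)
            opt.zero_grad()
            loss.backward()
            # explicit L_r gradient: d(wd·Σw²)/dw = 2·wd·w
            for w in model.weight_parameters():
                if w.grad is not None:
                    w.grad += (2.0 * config.weight_decay * w.data).astype(w.grad.dtype)
            opt.step()
            epoch_lw += float(loss.data)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss.data}")
        terms = total_loss(epoch_lw, model, config.weight_decay, alpha)
        val_f = _validation_fscore(model, x_val, val_masks,
                                   config.binarize_threshold)
        state.epoch = epoch
        state.history.append((epoch, terms.L, val_f))
        if val_f > state.best_fscore:
            state.best_fscore = val_f
            state.best_epoch = epoch
            state.best_checkpoint = {k: v.copy()
                                     for k, v in model.state_dict().items()}
        if verbose:
            print(f"epoch {epoch:4d}  L={terms.L:12.2f}  val F={val_f:.4f}")

    if state.best_checkpoint is not None:
        model.load_state_dict(state.best_checkpoint)
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, model, spec, norm, state)
    model.eval()
    model._norm = norm
    return model, state


def save_checkpoint(path, model: AANet, spec: AANetSpec, norm: dict,
                    state: TrainState | None = None) -> None:
    """Write parameters as .npz plus a JSON sidecar with the spec."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    sidecar = {"spec": spec.to_dict(), "normalization": norm}
    if state is not None:
        sidecar["best_fscore"] = float(state.best_fscore)
        sidecar["best_epoch"] = int(state.best_epoch)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path) -> AANet:
    """Rebuild a model (and its input normalisation) from a checkpoint."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec = AANetSpec.from_dict(sidecar["spec"])
    model = AANet(spec, np.random.default_rng(0))
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state_dict(dict(data))
    model.eval()
    model._norm = sidecar["normalization"]
    return model


def predict_stack(model: AANet, stack_voxels: np.ndarray,
                  patch_size: int = 128, batch: int = 16) -> np.ndarray:
    """Probability maps for every slice of a stack, by tile-and-stitch."""
    from .preprocess import stitch_predictions, tile_test_patches

    norm = getattr(model, "_norm", {"mean": 0.0, "std": 1.0})
    out = np.empty(stack_voxels.shape, dtype=np.float64)
    for z in range(stack_voxels.shape[0]):
        tiles = tile_test_patches(np.asarray(stack_voxels[z], dtype=np.float64),
                                  patch_size)
        x = (np.stack(tiles.patches) - norm["mean"]) / norm["std"]
        probs = []
        for i in range(0, len(x), batch):
            probs.append(model.predict_proba(x[i:i + batch]))
        prob_patches = list(np.concatenate(probs))
        out[z] = stitch_predictions(
            type(tiles)(prob_patches, tiles.origins, tiles.source_shape,
                        tiles.padded_shape))
    return out
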