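"""A small trainable convolutional network, implemented on numpy.

This is the desk-scale backbone behind every classification task in the
package: a stack of 3x3 convolution + ReLU + 2x2 max-pool blocks, global
average pooling, and a linear softmax head (~10^4-10^5 parameters depending
on the width schedule). It trains in seconds-to-minutes on one CPU core,
is bit-reproducible given a seed, and exposes exactly the internals the
explainability module needs: the penultimate (pooled-feature) embedding and
the final convolutional response with its class-score gradient.

The architecture is deliberately minimal; wider or deeper backbones can be
registered by constructing :class:`SmallCNN` with a different ``channels``
schedule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["SmallCNN", "TrainHistory"]


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N, H*W, C*9) patch matrix for a 3x3 same conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # N, C, H, W, 3, 3
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * 9)


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, _, h, wid = x.shape
    cols = _im2col(x)  # N, HW, Cin*9
    out = cols @ w.T + b  # N, HW, Cout
    return out.transpose(0, 2, 1).reshape(n, w.shape[0], h, wid), cols


def _conv_backward(
    dout: np.ndarray, cols: np.ndarray, w: np.ndarray, in_channels: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of a same-padded 3x3 conv.

    ``dx`` is computed as a correlation of ``dout`` with the 180-degree
    rotated, channel-transposed kernel — itself a same-padded 3x3 conv, which
    keeps the backward pass as fast as the forward one.
    """
    n, cout, h, wid = dout.shape
    dflat = dout.reshape(n, cout, h * wid).transpose(0, 2, 1)  # N, HW, Cout
    dw = np.einsum("npo,npi->oi", dflat, cols)
    db = dflat.sum(axis=(0, 1))
    wk = w.reshape(cout, in_channels, 3, 3)
    wflip = wk[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(in_channels, cout * 9)
    dcols = _im2col(dout)  # N, HW, Cout*9
    dx = (dcols @ wflip.T).transpose(0, 2, 1).reshape(n, in_channels, h, wid)
    return dx, dw, db


def _pool_forward(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _pool_backward(dout: np.ndarray, idx: np.ndarray, in_shape: tuple) -> np.ndarray:
    n, c, h, w = in_shape
    dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return dx.reshape(n, c, h, w)


@dataclass
class TrainHistory:
    """Per-epoch learning curves (loss and accuracy, train and validation)."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)


class SmallCNN:
    """Conv(3x3)+ReLU+MaxPool blocks -> global average pool -> softmax head.

    Parameters
    ----------
    input_side:
        Side length of the square grayscale input; must be divisible by
        ``2 ** len(channels)``.
    n_classes:
        Number of output classes.
    channels:
        Width of each convolutional block.
    seed:
        Seed for He-style weight initialisation; two networks built with the
        same seed are identical.
    """

    def __init__(
        self,
        input_side: int,
        n_classes: int,
        channels: tuple[int, ...] = (8, 16, 32),
        seed: int = 0,
    ) -> None:
        if input_side % (2 ** len(channels)) != 0:
            raise ValueError(
                f"input_side {input_side} not divisible by 2^{len(channels)}"
            )
        self.input_side = int(input_side)
        self.n_classes = int(n_classes)
        self.channels = tuple(int(c) for c in channels)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        self.conv_w: list[np.ndarray] = []
        self.conv_b: list[np.ndarray] = []
        cin = 1
        for cout in self.channels:
            fan_in = cin * 9
            self.conv_w.append(
                rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, fan_in))
            )
            self.conv_b.append(np.zeros(cout))
            cin = cout
        self.head_w = rng.normal(0.0, np.sqrt(1.0 / cin), size=(n_classes, cin))
        self.head_b = np.zeros(n_classes)
        self._adam_state: list[tuple[np.ndarray, np.ndarray]] | None = None
        self._adam_t = 0

    # -- forward ---------------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[-2:] != (self.input_side, self.input_side):
            raise ValueError(
                f"expected {self.input_side}x{self.input_side} inputs, got {x.shape[-2:]}"
            )
        return x

    def _forward(self, x: np.ndarray, cache: bool = False):
        caches = []
        a = x
        for w, b in zip(self.conv_w, self.conv_b):
            z, cols = _conv_forward(a, w, b)
            r = np.maximum(z, 0.0)
            p, idx = _pool_forward(r)
            if cache:
                caches.append((a.shape, cols, z, r.shape, idx))
            a = p
        feats = a.mean(axis=(2, 3))  # global average pool
        logits = feats @ self.head_w.T + self.head_b
        return (a, feats, logits, caches) if cache else (a, feats, logits)

    def feature_map(self, x: np.ndarray) -> np.ndarray:
        """Final convolutional response after the last pool, (N, C, h, w)."""
        a, _, _ = self._forward(self._check_input(x))
        return a

    def embed(self, x: np.ndarray) -> np.ndarray:
        """Penultimate-layer embedding: the globally pooled feature vector."""
        _, feats, _ = self._forward(self._check_input(x))
        return feats

    def logits(self, x: np.ndarray) -> np.ndarray:
        _, _, logits = self._forward(self._check_input(x))
        return logits

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        z = self.logits(x)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def class_map_gradient(self, target_class: int) -> np.ndarray:
        """d(logit of ``target_class``) / d(feature map), per channel.

        With a global-average-pool head the gradient is spatially constant:
        ``head_w[target, c] / (h * w)`` for channel ``c``. Returned as the
        per-channel constant (the ``1/(h*w)`` factor cancels in Grad-CAM's
        normalisation and is omitted).
        """
        return self.head_w[target_class].copy()

    # -- training --------------------------------------------------------

    def _params(self) -> list[np.ndarray]:
        return [*self.conv_w, *self.conv_b, self.head_w, self.head_b]

    def _loss_and_grads(self, x, y_idx, sample_weight):
        n = x.shape[0]
        a, feats, logits, caches = self._forward(x, cache=True)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs = e / e.sum(axis=1, keepdims=True)
        wsum = sample_weight.sum()
        loss = float(
            -(sample_weight * np.log(probs[np.arange(n), y_idx] + 1e-12)).sum() / wsum
        )
        dlogits = probs.copy()
        dlogits[np.arange(n), y_idx] -= 1.0
        dlogits *= (sample_weight / wsum)[:, None]
        d_head_w = dlogits.T @ feats
        d_head_b = dlogits.sum(axis=0)
        dfeats = dlogits @ self.head_w
        h = a.shape[2]
        da = np.broadcast_to(
            (dfeats / (h * h))[:, :, None, None], a.shape
        ).copy()
        d_conv_w = [None] * len(self.conv_w)
        d_conv_b = [None] * len(self.conv_b)
        for li in range(len(self.conv_w) - 1, -1, -1):
            in_shape, cols, z_pre, r_shape, idx = caches[li]
            dr = _pool_backward(da, idx, r_shape)
            dz = dr * (z_pre > 0)
            da, d_conv_w[li], d_conv_b[li] = _conv_backward(
                dz, cols, self.conv_w[li], in_shape[1]
            )
        grads = [*d_conv_w, *d_conv_b, d_head_w, d_head_b]
        acc = float((probs.argmax(axis=1) == y_idx).mean())
        return loss, acc, grads

    def _adam_step(self, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        params = self._params()
        if self._adam_state is None:
            self._adam_state = [(np.zeros_like(p), np.zeros_like(p)) for p in params]
        self._adam_t += 1
        t = self._adam_t
        for p, g, (m, v) in zip(params, grads, self._adam_state):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        x_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        epochs: int = 30,
        batch_size: int = 32,
        learning_rate: float = 3e-3,
        class_weights: np.ndarray | None = None,
        seed: int = 0,
    ) -> TrainHistory:
        """Train with Adam on weighted softmax cross-entropy.

        ``y`` holds integer class indices. ``class_weights`` (one weight per
        class) rescales each sample's loss contribution; pass inverse class
        frequencies to counter imbalance. Shuffling and initialisation are
        driven only by explicit seeds, so runs are reproducible.
        """
        x = self._check_input(x)
        y = np.asarray(y, dtype=int)
        if class_weights is None:
            class_weights = np.ones(self.n_classes)
        class_weights = np.asarray(class_weights, dtype=float)
        rng = np.random.default_rng(seed)
        history = TrainHistory()
        n = x.shape[0]
        for _ in range(epochs):
            order = rng.permutation(n)
            losses, accs, counts = [], [], []
            for start in range(0, n, batch_size):
                sel = order[start : start + batch_size]
                sw = class_weights[y[sel]]
                loss, acc, grads = self._loss_and_grads(x[sel], y[sel], sw)
                self._adam_step(grads, learning_rate)
                losses.append(loss * len(sel))
                accs.append(acc * len(sel))
                counts.append(len(sel))
            history.train_loss.append(float(np.sum(losses) / n))
            history.train_accuracy.append(float(np.sum(accs) / n))
            if x_val is not None and len(x_val):
                probs = self.predict_proba(x_val)
                yv = np.asarray(y_val, dtype=int)
                vloss = float(
                    -np.log(probs[np.arange(len(yv)), yv] + 1e-12).mean()
                )
                history.val_loss.append(vloss)
                history.val_accuracy.append(float((probs.argmax(axis=1) == yv).mean()))
        return history

    # -- persistence -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"conv_w{i}": w for i, w in enumerate(self.conv_w)}
        arrays |= {f"conv_b{i}": b for i, b in enumerate(self.conv_b)}
        arrays |= {"head_w": self.head_w, "head_b": self.head_b}
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {
            "input_side": self.input_side,
            "n_classes": self.n_classes,
            "channels": list(self.channels),
            "seed": self.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "SmallCNN":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(
            meta["input_side"], meta["n_classes"], tuple(meta["channels"]), meta["seed"]
        )
        data = np.load(path.with_suffix(".npz"))
        model.conv_w = [data[f"conv_w{i}"] for i in range(len(model.channels))]
        model.conv_b = [data[f"conv_b{i}"] for i in range(len(model.channels))]
        model.head_w = data["head_w"]
        model.head_b = data["head_b"]
        return model

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self._params()))
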