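"""Minimal convolutional network with manual backprop.

A compact, dependency-free CNN sized for desk-scale experiments: a stack
of stride-2 conv/ReLU blocks ("backbone"), one final conv/ReLU block
feeding global average pooling and a linear classifier ("head"). The two
parameter groups can be driven at different learning rates, which is what
the frozen-backbone fine-tuning schedule requires, and the post-ReLU
activation of the last convolution (plus the gradient of any class logit
with respect to it) is exposed for Grad-CAM.

All arithmetic is float64 numpy; with a fixed seed, training is bit
reproducible on a single thread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SmallConvNet"]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, int, int]:
    """(N,C,H,W) -> (N, out_h*out_w, C*k*k) patch matrix."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out_h = (h + 2 * pad - k) // stride + 1
    out_w = (w + 2 * pad - k) // stride + 1
    s0, s1, s2, s3 = xp.strides
    shape = (n, c, out_h, out_w, k, k)
    strides = (s0, s1, s2 * stride, s3 * stride, s2, s3)
    windows = np.lib.stride_tricks.as_strided(xp, shape=shape, strides=strides)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, out_h * out_w, c * k * k)
    return np.ascontiguousarray(cols), out_h, out_w


def _col2im(dcols: np.ndarray, x_shape: tuple, k: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w = x_shape
    out_h = (h + 2 * pad - k) // stride + 1
    out_w = (w + 2 * pad - k) // stride + 1
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    d6 = dcols.reshape(n, out_h, out_w, c, k, k)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + out_h * stride : stride, j : j + out_w * stride : stride] += (
                d6[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            )
    return dxp[:, :, pad : pad + h, pad : pad + w]


class _Conv:
    """3x3 same-padded convolution (configurable stride) with He init."""

    def __init__(self, cin: int, cout: int, stride: int, rng: np.random.Generator, k: int = 3):
        self.k, self.stride, self.pad = k, stride, k // 2
        self.W = rng.normal(0.0, np.sqrt(2.0 / (cin * k * k)), size=(cout, cin, k, k))
        self.b = np.zeros(cout)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, oh, ow = _im2col(x, self.k, self.stride, self.pad)
        wmat = self.W.reshape(self.W.shape[0], -1)
        y = cols @ wmat.T + self.b
        self._cache = (x.shape, cols, oh, ow)
        return y.transpose(0, 2, 1).reshape(x.shape[0], -1, oh, ow)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, cols, oh, ow = self._cache
        dyf = dy.reshape(dy.shape[0], dy.shape[1], -1).transpose(0, 2, 1)
        wmat = self.W.reshape(self.W.shape[0], -1)
        self.dW = np.einsum("npo,npk->ok", dyf, cols).reshape(self.W.shape)
        self.db = dyf.sum(axis=(0, 1))
        dcols = dyf @ wmat
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad)

    def params(self):
        return [("W", self), ("b", self)]


@dataclass
class _Momentum:
    buffers: dict = field(default_factory=dict)

    def step(self, layers, lr: float, momentum: float) -> None:
        if lr == 0.0:
            return
        for layer in layers:
            for name in ("W", "b"):
                p = getattr(layer, name)
                g = getattr(layer, "d" + name)
                key = (id(layer), name)
                v = self.buffers.get(key)
                v = momentum * v + g if v is not None else g.copy()
                self.buffers[key] = v
                setattr(layer, name, p - lr * v)


class _Linear:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(1.0 / cin), size=(cout, cin))
        self.b = np.zeros(cout)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = dy.T @ self._x
        self.db = dy.sum(axis=0)
        return dy @ self.W


class SmallConvNet:
    """Stride-2 conv/ReLU stack + GAP + linear softmax classifier.

    ``channels[:-1]`` convolutions form the *backbone* parameter group,
    the last convolution plus the linear classifier form the *head*.
    """

    def __init__(
        self,
        channels: tuple[int, ...] = (8, 16, 32, 32),
        n_classes: int = 2,
        in_channels: int = 3,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.channels = tuple(channels)
        self.n_classes = n_classes
        self.convs: list[_Conv] = []
        cin = in_channels
        for i, cout in enumerate(channels):
            stride = 2 if i < len(channels) - 1 else 1
            self.convs.append(_Conv(cin, cout, stride, rng))
            cin = cout
        self.fc = _Linear(cin, n_classes, rng)
        self._relu_masks: list[np.ndarray] = []
        self.last_conv_activation: np.ndarray | None = None
        self._opt = _Momentum()

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, 3, H, W) float -> logits (N, n_classes)."""
        self._relu_masks = []
        h = x
        for conv in self.convs:
            h = conv.forward(h)
            mask = h > 0
            self._relu_masks.append(mask)
            h = h * mask
        self.last_conv_activation = h
        self._gap_size = h.shape[2] * h.shape[3]
        pooled = h.mean(axis=(2, 3))
        return self.fc.forward(pooled)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        """Backprop from logit grads; returns grad wrt last-conv activation."""
        dpooled = self.fc.backward(dlogits)
        a = self.last_conv_activation
        dh = dpooled[:, :, None, None] * np.ones_like(a) / self._gap_size
        dact = dh.copy()
        for conv, mask in zip(reversed(self.convs), reversed(self._relu_masks)):
            dh = conv.backward(dh * mask)
        return dact

    # -- training utilities -------------------------------------------------
    @staticmethod
    def softmax(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
        """Mean softmax cross-entropy and its logit gradient (backprop run)."""
        logits = self.forward(x)
        p = self.softmax(logits)
        n = x.shape[0]
        loss = -float(np.log(np.maximum(p[np.arange(n), y], 1e-300)).mean())
        dlogits = p.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        self.backward(dlogits)
        return loss, dlogits

    def sgd_step(self, lr_backbone: float, lr_head: float, momentum: float) -> None:
        self._opt.step(self.convs[:-1], lr_backbone, momentum)
        self._opt.step([self.convs[-1], self.fc], lr_head, momentum)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.softmax(self.forward(x))

    # -- Grad-CAM hook ------------------------------------------------------
    def class_activation_gradient(self, x: np.ndarray, target_class: int) -> tuple[np.ndarray, np.ndarray]:
        """Activation of the last conv (post-ReLU) and d(logit_target)/d(activation)."""
        logits = self.forward(x)
        dlogits = np.zeros_like(logits)
        dlogits[:, target_class] = 1.0
        dact = self.backward(dlogits)
        return self.last_conv_activation, dact

    # -- persistence --------------------------------------------------------
    def state_dict(self) -> dict:
        state = {"channels": list(self.channels), "n_classes": self.n_classes}
        for i, conv in enumerate(self.convs):
            state[f"conv{i}_W"] = conv.W
            state[f"conv{i}_b"] = conv.b
        state["fc_W"] = self.fc.W
        state["fc_b"] = self.fc.b
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, conv in enumerate(self.convs):
            conv.W = np.asarray(state[f"conv{i}_W"])
            conv.b = np.asarray(state[f"conv{i}_b"])
        self.fc.W = np.asarray(state["fc_W"])
        self.fc.b = np.asarray(state["fc_b"])

    @property
    def n_parameters(self) -> int:
        total = sum(c.W.size + c.b.size for c in self.convs)
        return total + self.fc.W.size + self.fc.b.size
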