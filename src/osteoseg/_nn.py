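"""Minimal numpy CNN toolkit used by the slice-wise U-Net.

Layers are implemented with explicit forward/backward passes on ``(N, C, H,
W)`` float32 arrays; 3x3 convolutions use an unrolled 9-offset accumulation
(equivalent to im2col but without materialising the column matrix), which is
fast enough at the slice resolutions this package trains at.  Weights use He
initialisation, biases start at zero.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "UNet2D", "SGDMomentum", "Adam", "soft_dice_loss", "bce_loss"]


class Conv2d:
    """Same-padded 2D convolution, kernel 3x3 or 1x1, with ReLU optional."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        fan_in = c_in * kernel * kernel
        self.W = (rng.standard_normal((c_out, c_in, kernel, kernel)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.kernel = kernel
        self._x = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, c, h, w = x.shape
        co = self.W.shape[0]
        if self.kernel == 1:
            out = np.einsum("nchw,oc->nohw", x, self.W[:, :, 0, 0], optimize=True)
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
            out = np.zeros((n, co, h, w), dtype=x.dtype)
            for i in range(3):
                for j in range(3):
                    patch = xp[:, :, i : i + h, j : j + w]
                    out += np.einsum("nchw,oc->nohw", patch, self.W[:, :, i, j], optimize=True)
        return out + self.b[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        n, c, h, w = x.shape
        self.db = dout.sum(axis=(0, 2, 3))
        self.dW = np.zeros_like(self.W)
        if self.kernel == 1:
            self.dW[:, :, 0, 0] = np.einsum("nohw,nchw->oc", dout, x, optimize=True)
            dx = np.einsum("nohw,oc->nchw", dout, self.W[:, :, 0, 0], optimize=True)
            return dx
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        dxp = np.zeros_like(xp)
        for i in range(3):
            for j in range(3):
                patch = xp[:, :, i : i + h, j : j + w]
                self.dW[:, :, i, j] = np.einsum("nohw,nchw->oc", dout, patch, optimize=True)
                dxp[:, :, i : i + h, j : j + w] += np.einsum(
                    "nohw,oc->nchw", dout, self.W[:, :, i, j], optimize=True
                )
        return dxp[:, :, 1 : 1 + h, 1 : 1 + w]


def _relu_forward(x):
    mask = x > 0
    return x * mask, mask


def _maxpool2(x):
    n, c, h, w = x.shape
    # windows as a trailing axis of 4; argmax routes each gradient to one input
    xw = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = xw.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    mask = np.zeros(flat.shape, dtype=bool)
    np.put_along_axis(mask, idx[..., None], True, axis=-1)
    return out, mask


def _maxpool2_backward(dout, mask):
    n, c, h2, w2, _ = mask.shape
    d = mask * dout[..., None]
    return d.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2 * 2, w2 * 2)


def _upsample2(x):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _upsample2_backward(dout):
    n, c, h, w = dout.shape
    return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class UNet2D:
    """Encoder-decoder with skip connections and a logistic output head.

    ``depth`` encoder levels with ``base_filters * 2**level`` channels, two
    3x3 conv+ReLU per level, 2x2 max-pool between levels, nearest-neighbour
    upsampling with skip concatenation on the way back, and a final 1x1
    convolution squashed through a sigmoid to one foreground-probability
    channel per pixel.
    """

    def __init__(self, depth: int = 4, base_filters: int = 32, in_channels: int = 1, seed: int = 0):
        if depth < 2 or base_filters < 4:
            raise ValueError("need depth >= 2 and base_filters >= 4")
        self.depth = depth
        self.base_filters = base_filters
        self.in_channels = in_channels
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.enc = []
        c_prev = in_channels
        for level in range(depth):
            c = base_filters * 2**level
            self.enc.append((Conv2d(c_prev, c, 3, rng), Conv2d(c, c, 3, rng)))
            c_prev = c
        self.dec = []
        for level in range(depth - 2, -1, -1):
            c_skip = base_filters * 2**level
            c_up = base_filters * 2 ** (level + 1)
            self.dec.append((Conv2d(c_up + c_skip, c_skip, 3, rng), Conv2d(c_skip, c_skip, 3, rng)))
        self.head = Conv2d(base_filters, 1, 1, rng)

    # -- parameter plumbing -------------------------------------------------
    def layers(self):
        out = []
        for a, b in self.enc:
            out += [a, b]
        for a, b in self.dec:
            out += [a, b]
        out.append(self.head)
        return out

    def params(self):
        return [p for layer in self.layers() for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers() for g in layer.grads()]

    def required_multiple(self) -> int:
        return 2 ** (self.depth - 1)

    def check_input(self, h: int, w: int) -> None:
        mult = self.required_multiple()
        if h % mult or w % mult:
            raise ValueError(
                f"input size {h}x{w} not divisible by 2^(depth-1)={mult}; "
                f"pad to {mult * ((h + mult - 1) // mult)}x{mult * ((w + mult - 1) // mult)}"
            )

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, remember: bool = False) -> np.ndarray:
        """Probabilities in [0,1] for a batch ``(N, C, H, W)``."""
        x = np.asarray(x, dtype=self.head.W.dtype)
        self.check_input(x.shape[2], x.shape[3])
        cache = {"relu": [], "pool": [], "skips": []}
        h = x
        for level, (c1, c2) in enumerate(self.enc):
            h, m1 = _relu_forward(c1.forward(h))
            h, m2 = _relu_forward(c2.forward(h))
            cache["relu"].append((m1, m2))
            if level < self.depth - 1:
                cache["skips"].append(h)
                h, pmask = _maxpool2(h)
                cache["pool"].append(pmask)
        for i, (c1, c2) in enumerate(self.dec):
            skip = cache["skips"][-(i + 1)]
            h = np.concatenate([_upsample2(h), skip], axis=1)
            h, m1 = _relu_forward(c1.forward(h))
            h, m2 = _relu_forward(c2.forward(h))
            cache["relu"].append((m1, m2))
        logits = self.head.forward(h)
        with np.errstate(over="ignore"):
            probs = np.where(
                logits >= 0,
                1.0 / (1.0 + np.exp(-np.abs(logits))),
                np.exp(-np.abs(logits)) / (1.0 + np.exp(-np.abs(logits))),
            )
        if remember:
            cache["probs"] = probs
            self._cache = cache
        return probs

    def backward(self, dprobs: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the output probabilities."""
        cache = self._cache
        probs = cache["probs"]
        dlogits = (dprobs * probs * (1.0 - probs)).astype(probs.dtype)
        h = self.head.backward(dlogits)
        relu = list(cache["relu"])
        dskips = []
        for i, (c1, c2) in enumerate(reversed(self.dec)):
            m1, m2 = relu.pop()
            h = c1.backward(c2.backward(h * m2) * m1)
            c_up = self.base_filters * 2 ** (i + 1)
            dup, dskip = h[:, :c_up], h[:, c_up:]
            dskips.append(dskip)
            h = _upsample2_backward(dup)
        for level in range(self.depth - 1, -1, -1):
            c1, c2 = self.enc[level]
            if level < self.depth - 1:
                h = _maxpool2_backward(h, cache["pool"][level])
                h = h + dskips[level]  # dskips[i] collected at decoder level i
            m1, m2 = relu.pop()
            h = c1.backward(c2.backward(h * m2) * m1)

    # -- persistence --------------------------------------------------------
    def state_dict(self) -> dict:
        state = {
            "depth": self.depth,
            "base_filters": self.base_filters,
            "in_channels": self.in_channels,
            "seed": self.seed,
        }
        for i, layer in enumerate(self.layers()):
            state[f"W{i}"] = layer.W
            state[f"b{i}"] = layer.b
        return state

    @classmethod
    def from_state(cls, state: dict) -> "UNet2D":
        net = cls(
            depth=int(state["depth"]),
            base_filters=int(state["base_filters"]),
            in_channels=int(state["in_channels"]),
            seed=int(state["seed"]),
        )
        for i, layer in enumerate(net.layers()):
            layer.W = np.asarray(state[f"W{i}"], dtype=np.float32)
            layer.b = np.asarray(state[f"b{i}"], dtype=np.float32)
        return net


class SGDMomentum:
    """Classical momentum: v <- mu v - lr g; w <- w + v."""

    def __init__(self, params, lr: float = 1e-2, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads):
        for p, g, v in zip(self.params, grads, self.v):
            v *= self.momentum
            v -= self.lr * g
            p += v


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def soft_dice_loss(probs: np.ndarray, targets: np.ndarray, eps: float = 1.0):
    """Per-sample soft Dice loss (1 - Dice) and its gradient w.r.t. probs.

    The smoothing term ``eps`` keeps empty-target slices well-defined and
    pushes predictions on them toward empty.
    """
    n = probs.shape[0]
    p = probs.reshape(n, -1)
    t = targets.reshape(n, -1).astype(p.dtype)
    inter = (p * t).sum(axis=1)
    sums = p.sum(axis=1) + t.sum(axis=1)
    dice = (2 * inter + eps) / (sums + eps)
    loss = float(np.mean(1.0 - dice))
    # d(1-dice)/dp = -(2 t (sums+eps) - (2 inter + eps)) / (sums+eps)^2, /n for the mean
    denom = (sums + eps) ** 2
    dp = -(2 * t * (sums + eps)[:, None] - (2 * inter + eps)[:, None]) / denom[:, None] / n
    return loss, dp.reshape(probs.shape).astype(probs.dtype)


def bce_loss(probs: np.ndarray, targets: np.ndarray, eps: float = 1e-7):
    """Mean binary cross-entropy and its gradient w.r.t. probs."""
    p = np.clip(probs, eps, 1 - eps)
    t = targets.astype(np.float32)
    loss = float(np.mean(-(t * np.log(p) + (1 - t) * np.log(1 - p))))
    dp = ((p - t) / (p * (1 - p))) / p.size
    return loss, dp.astype(p.dtype)
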