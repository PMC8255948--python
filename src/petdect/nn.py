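"""Minimal CNN engine for single-image autoencoders.

A compact, dependency-free stack of 2D convolution (stride 1 or 2, zero 'same'
padding), bilinear resizing, ReLU and the Adam optimizer, with hand-written
backward passes.  It exists to train the small residual encoder-decoder
(RED-CNN) and U-Net autoencoders on one 2D image; it is deliberately not a
general deep-learning framework.

Images are ``(C, H, W)`` float arrays.  All computation is deterministic for
a fixed seed.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Conv2D:
    """2D convolution with zero 'same' padding and stride 1 or 2."""

    def __init__(self, c_in: int, c_out: int, ksize: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        if ksize % 2 == 0:
            raise ValueError("ksize must be odd")
        self.c_in, self.c_out, self.ksize, self.stride = c_in, c_out, ksize, stride
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * ksize * ksize
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(c_out, c_in, ksize, ksize)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self._xp = None  # padded input cached for backward

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def params(self):
        return [self.W, self.b]

    def _windows(self, xp: np.ndarray):
        k, s = self.ksize, self.stride
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        return win[:, ::s, ::s]

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.ksize // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p)))
        self._xp = xp
        self._in_shape = x.shape
        win = self._windows(xp)
        out = np.tensordot(self.W, win, axes=([1, 2, 3], [0, 3, 4]))
        return out + self.b[:, None, None]

    def backward(self, dout: np.ndarray):
        """Returns dx; accumulates dW, db on the layer."""
        k, s, p = self.ksize, self.stride, self.ksize // 2
        xp = self._xp
        win = self._windows(xp)
        self.db = dout.sum(axis=(1, 2))
        self.dW = np.tensordot(dout, win, axes=([1, 2], [1, 2]))
        contrib = np.tensordot(self.W, dout, axes=([0], [0]))  # (C, k, k, Ho, Wo)
        dxp = np.zeros_like(xp)
        ho, wo = dout.shape[1:]
        for a in range(k):
            for b in range(k):
                dxp[:, a:a + s * ho:s, b:b + s * wo:s] += contrib[:, a, b]
        _, h, w = self._in_shape
        return dxp[:, p:p + h, p:p + w]

    def grads(self):
        return [self.dW, self.db]


class BilinearResize:
    """Separable bilinear resize to a fixed target size; exact adjoint backward."""

    def __init__(self, in_size: tuple[int, int], out_size: tuple[int, int]):
        self.S_r = self._interp_matrix(in_size[0], out_size[0])
        self.S_c = self._interp_matrix(in_size[1], out_size[1])

    @staticmethod
    def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
        S = np.zeros((n_out, n_in), dtype=DTYPE)
        pos = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
        pos = np.clip(pos, 0.0, n_in - 1.0)
        lo = np.floor(pos).astype(int)
        hi = np.minimum(lo + 1, n_in - 1)
        frac = pos - lo
        S[np.arange(n_out), lo] += 1.0 - frac
        S[np.arange(n_out), hi] += frac
        return S

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.einsum("ij,cjk,lk->cil", self.S_r, x, self.S_c, optimize=True)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.einsum("ji,cjk,kl->cil", self.S_r, dout, self.S_c, optimize=True)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_backward(dout: np.ndarray, activated: np.ndarray) -> np.ndarray:
    return dout * (activated > 0)


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updates in place)."""

    def __init__(self, params: list, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class REDCNN:
    """Residual encoder-decoder CNN: 5x5 convolutions, ReLU, additive skips.

    Five encoding convolutions followed by five decoding ("deconvolution")
    layers at full resolution, with residual shortcuts (e4 -> d1, e2 -> d3,
    input -> output).  The penultimate layer is the last hidden decoder
    activation (``width`` channels).
    """

    feature_layer_default = "d4"

    def __init__(self, width: int = 60, seed: int = 0):
        rng = np.random.default_rng(seed)
        w = width
        self.width = w
        self.convs = {
            "c1": Conv2D(1, w, 5, rng=rng), "c2": Conv2D(w, w, 5, rng=rng),
            "c3": Conv2D(w, w, 5, rng=rng), "c4": Conv2D(w, w, 5, rng=rng),
            "c5": Conv2D(w, w, 5, rng=rng),
            "d1": Conv2D(w, w, 5, rng=rng), "d2": Conv2D(w, w, 5, rng=rng),
            "d3": Conv2D(w, w, 5, rng=rng), "d4": Conv2D(w, w, 5, rng=rng),
            "d5": Conv2D(w, 1, 5, rng=rng),
        }

    @property
    def n_params(self) -> int:
        return sum(c.n_params for c in self.convs.values())

    def layer_names(self):
        return ("e1", "e2", "e3", "e4", "e5", "d1", "d2", "d3", "d4")

    def forward(self, x: np.ndarray) -> dict:
        c = self.convs
        acts = {"x": x}
        acts["e1"] = relu(c["c1"].forward(x))
        acts["e2"] = relu(c["c2"].forward(acts["e1"]))
        acts["e3"] = relu(c["c3"].forward(acts["e2"]))
        acts["e4"] = relu(c["c4"].forward(acts["e3"]))
        acts["e5"] = relu(c["c5"].forward(acts["e4"]))
        acts["d1"] = relu(c["d1"].forward(acts["e5"]) + acts["e4"])
        acts["d2"] = relu(c["d2"].forward(acts["d1"]))
        acts["d3"] = relu(c["d3"].forward(acts["d2"]) + acts["e2"])
        acts["d4"] = relu(c["d4"].forward(acts["d3"]))
        acts["out"] = c["d5"].forward(acts["d4"]) + x
        return acts

    def backward(self, dout: np.ndarray, acts: dict) -> None:
        c = self.convs
        dd4 = c["d5"].backward(dout)
        dd3 = c["d4"].backward(relu_backward(dd4, acts["d4"]))
        g3 = relu_backward(dd3, acts["d3"])
        dd2 = c["d3"].backward(g3)
        dd1 = c["d2"].backward(relu_backward(dd2, acts["d2"]))
        g1 = relu_backward(dd1, acts["d1"])
        de5 = c["d1"].backward(g1)
        de4 = c["c5"].backward(relu_backward(de5, acts["e5"])) + g1
        de3 = c["c4"].backward(relu_backward(de4, acts["e4"]))
        de2 = c["c3"].backward(relu_backward(de3, acts["e3"])) + g3
        de1 = c["c2"].backward(relu_backward(de2, acts["e2"]))
        c["c1"].backward(relu_backward(de1, acts["e1"]))

    def params(self):
        return [p for name in sorted(self.convs) for p in self.convs[name].params()]

    def grads(self):
        return [g for name in sorted(self.convs) for g in self.convs[name].grads()]


class UNet:
    """U-Net autoencoder: 3x3 convolutions, stride-2 downsampling, bilinear
    upsampling, additive left-to-right residual connections, and a 12-channel
    penultimate layer at input resolution.

    ``channels`` fixes one width per scale; its length sets the number of
    scales (len(channels) - 1 stride-2 downsamplings).
    """

    feature_layer_default = "p"

    def __init__(self, image_shape: tuple[int, int],
                 channels: tuple = (32, 64, 96, 112),
                 penultimate_channels: int = 12, seed: int = 0):
        if len(channels) < 2:
            raise ValueError("UNet needs at least two scales")
        rng = np.random.default_rng(seed)
        self.channels = tuple(channels)
        self.n_scales = len(channels)
        self.penultimate_channels = penultimate_channels
        sizes = [tuple(image_shape)]
        for _ in range(self.n_scales - 1):
            h, w = sizes[-1]
            sizes.append(((h + 1) // 2, (w + 1) // 2))
        self.sizes = tuple(sizes)
        self.convs = {"enc1": Conv2D(1, channels[0], 3, rng=rng)}
        for s in range(1, self.n_scales):
            self.convs[f"enc{s + 1}"] = Conv2D(channels[s - 1], channels[s], 3,
                                               stride=2, rng=rng)
        for s in range(self.n_scales - 1, 0, -1):
            self.convs[f"dec{s}"] = Conv2D(channels[s], channels[s - 1], 3,
                                           rng=rng)
        self.convs["pen"] = Conv2D(channels[0], penultimate_channels, 3, rng=rng)
        self.convs["out"] = Conv2D(penultimate_channels, 1, 3, rng=rng)
        self.ups = {s: BilinearResize(sizes[s], sizes[s - 1])
                    for s in range(1, self.n_scales)}

    @property
    def n_params(self) -> int:
        return sum(c.n_params for c in self.convs.values())

    def layer_names(self):
        return ("e1", "d1", "p")

    def forward(self, x: np.ndarray) -> dict:
        c = self.convs
        acts = {"x": x}
        acts["e1"] = relu(c["enc1"].forward(x))
        for s in range(2, self.n_scales + 1):
            acts[f"e{s}"] = relu(c[f"enc{s}"].forward(acts[f"e{s - 1}"]))
        prev = acts[f"e{self.n_scales}"]
        for s in range(self.n_scales - 1, 0, -1):
            up = self.ups[s].forward(prev)
            acts[f"d{s}"] = relu(c[f"dec{s}"].forward(up) + acts[f"e{s}"])
            prev = acts[f"d{s}"]
        acts["p"] = relu(c["pen"].forward(acts["d1"]))
        acts["out"] = c["out"].forward(acts["p"])
        return acts

    def backward(self, dout: np.ndarray, acts: dict) -> None:
        c = self.convs
        dp = c["out"].backward(dout)
        dd = c["pen"].backward(relu_backward(dp, acts["p"]))
        skip_grads = {}
        for s in range(1, self.n_scales):
            g = relu_backward(dd, acts[f"d{s}"])
            skip_grads[s] = g
            dd = self.ups[s].backward(c[f"dec{s}"].backward(g))
        de = dd  # gradient at the bottleneck encoder activation
        for s in range(self.n_scales, 1, -1):
            de = c[f"enc{s}"].backward(relu_backward(de, acts[f"e{s}"]))
            de = de + skip_grads[s - 1]
        c["enc1"].backward(relu_backward(de, acts["e1"]))

    def params(self):
        return [p for name in sorted(self.convs) for p in self.convs[name].params()]

    def grads(self):
        return [g for name in sorted(self.convs) for g in self.convs[name].grads()]
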