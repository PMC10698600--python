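"""Minimal NumPy neural-network core for the 2D U-Net segmenter.

Implements exactly what the segmentation stage needs — 3x3/1x1
convolutions via im2col, ReLU, 2x2 max-pooling, nearest-neighbour
upsampling, channel concatenation, Adam, and a soft-Dice + binary
cross-entropy loss — with hand-written reverse-mode gradients.  The
gradients are validated against central finite differences in the test
suite.

Arrays are ``(N, C, H, W)`` float64.  Spatial sizes must be divisible by
``2**depth`` so the encoder/decoder paths mirror exactly.
"""

from __future__ import annotations

import numpy as np


class Conv2D:
    """Same-padded convolution (kernel 3 or 1), He-initialised."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        fan_in = c_in * kernel * kernel
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel, kernel))
        self.b = np.zeros(c_out)
        self.kernel = kernel
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._x_shape = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.kernel
        self._x_shape = x.shape
        if k == 1:
            cols = x.transpose(0, 2, 3, 1).reshape(-1, c)
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
            windows = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
            cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(-1, c * 9)
        self._cols = cols
        out = cols @ self.W.reshape(self.W.shape[0], -1).T + self.b
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c_out, h, w = dout.shape
        k = self.kernel
        c_in = self._x_shape[1]
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, c_out)
        self.dW += (dflat.T @ self._cols).reshape(self.W.shape)
        self.db += dflat.sum(axis=0)
        dcols = dflat @ self.W.reshape(c_out, -1)
        if k == 1:
            return dcols.reshape(n, h, w, c_in).transpose(0, 3, 1, 2)
        dcols = dcols.reshape(n, h, w, c_in, 3, 3)
        dxp = np.zeros((n, c_in, h + 2, w + 2))
        for di in range(3):
            for dj in range(3):
                dxp[:, :, di : di + h, dj : dj + w] += dcols[:, :, :, :, di, dj].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, 1:-1, 1:-1]


class LeakyReLU:
    """Leaky rectifier (slope 0.1).  The small foreground fraction of lung
    slices can push every plain-ReLU unit inactive in the first updates,
    collapsing the network to a constant; the leak keeps gradients alive."""

    slope = 0.1

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


class MaxPool2:
    """2x2 max pooling, stride 2; ties resolved to the first maximum."""

    def forward(self, x):
        n, c, h, w = x.shape
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = blocks.reshape(n, c, h // 2, w // 2, 4)
        self._argmax = flat.argmax(axis=-1)
        self._in_shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dout):
        n, c, h, w = self._in_shape
        dflat = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dflat, self._argmax[..., None], dout[..., None], axis=-1)
        blocks = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return blocks.reshape(n, c, h, w)


class Upsample2:
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout):
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class ConvBlock:
    """conv3x3 -> ReLU -> conv3x3 -> ReLU."""

    def __init__(self, c_in, c_out, rng):
        self.conv1 = Conv2D(c_in, c_out, 3, rng)
        self.relu1 = LeakyReLU()
        self.conv2 = Conv2D(c_out, c_out, 3, rng)
        self.relu2 = LeakyReLU()

    def params(self):
        return self.conv1.params() + self.conv2.params()

    def forward(self, x):
        return self.relu2.forward(self.conv2.forward(self.relu1.forward(self.conv1.forward(x))))

    def backward(self, dout):
        return self.conv1.backward(
            self.relu1.backward(self.conv2.backward(self.relu2.backward(dout)))
        )


class UNet2D:
    """Symmetric encoder-decoder with skip connections and a 1-channel
    logit head.

    ``depth`` resolution levels below the input level; ``base_channels``
    channels at the top, doubling per level.
    """

    def __init__(self, depth: int = 3, base_channels: int = 8, in_channels: int = 1, seed: int = 0):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.enc = []
        c_in = in_channels
        for i in range(depth):
            c_out = base_channels * 2**i
            self.enc.append(ConvBlock(c_in, c_out, rng))
            c_in = c_out
        self.pools = [MaxPool2() for _ in range(depth)]
        self.bottleneck = ConvBlock(c_in, base_channels * 2**depth, rng)
        self.ups = []
        self.up_convs = []  # halve channels after upsampling
        self.dec = []
        c = base_channels * 2**depth
        for i in reversed(range(depth)):
            c_skip = base_channels * 2**i
            self.ups.append(Upsample2())
            self.up_convs.append(Conv2D(c, c_skip, 1, rng))
            self.dec.append(ConvBlock(2 * c_skip, c_skip, rng))
            c = c_skip
        self.head = Conv2D(c, 1, 1, rng)

    def params(self):
        out = []
        for block in self.enc:
            out += block.params()
        out += self.bottleneck.params()
        for up_conv, block in zip(self.up_convs, self.dec):
            out += up_conv.params()
            out += block.params()
        out += self.head.params()
        return out

    def zero_grad(self):
        for _, g in self.params():
            g[...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Input (N, C, H, W) -> logits (N, 1, H, W)."""
        h, w = x.shape[2:]
        div = 2**self.depth
        if h % div or w % div:
            raise ValueError(f"spatial size {h}x{w} not divisible by 2^depth = {div}")
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_channels = []
        for up, up_conv, block, skip in zip(self.ups, self.up_convs, self.dec, reversed(skips)):
            x = up_conv.forward(up.forward(x))
            self._skip_channels.append(skip.shape[1])
            x = block.forward(np.concatenate([skip, x], axis=1))
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.head.backward(dlogits)
        dskips = []
        for up, up_conv, block, c_skip in zip(
            reversed(self.ups),
            reversed(self.up_convs),
            reversed(self.dec),
            reversed(self._skip_channels),
        ):
            dcat = block.backward(dx)
            dskips.append(dcat[:, :c_skip])
            dx = up.backward(up_conv.backward(dcat[:, c_skip:]))
        dx = self.bottleneck.backward(dx)
        for block, pool, dskip in zip(reversed(self.enc), reversed(self.pools), reversed(dskips)):
            dx = block.backward(pool.backward(dx) + dskip)
        return dx


def sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def dice_bce_loss(logits: np.ndarray, targets: np.ndarray, eps: float = 1.0):
    """Soft-Dice + binary cross-entropy over a batch; returns (loss, dL/dlogits).

    The Dice term counters the strong foreground/background imbalance of
    lung slices; BCE keeps per-pixel gradients informative.  Both terms are
    computed over the whole batch.
    """
    p = sigmoid(logits)
    n_pix = logits.size
    # BCE with logits, numerically stable
    bce = np.mean(np.maximum(logits, 0) - logits * targets + np.log1p(np.exp(-np.abs(logits))))
    dl_bce = (p - targets) / n_pix

    inter = float((p * targets).sum())
    sums = float(p.sum() + targets.sum())
    dice = (2.0 * inter + eps) / (sums + eps)
    # d(1-dice)/dp, then chain through the sigmoid
    ddice_dp = (2.0 * targets * (sums + eps) - (2.0 * inter + eps)) / (sums + eps) ** 2
    dl_dice = -ddice_dp * p * (1.0 - p)

    return bce + (1.0 - dice), dl_bce + dl_dice


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
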