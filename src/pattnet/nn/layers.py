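"""Minimal 3D convolutional network engine with reverse-mode gradients.

Tensors are NumPy arrays of shape (batch, channels, d1, d2, d3).  Each layer
implements ``forward(x, training)`` and ``backward(grad_out)``; composite
modules chain them.  Circular ("periodic same") convolution — the natural
boundary condition for crystallographic maps, which are periodic by
construction — is evaluated in Fourier space: a circular cross-correlation is
a per-frequency product with the conjugate kernel spectrum, and both the
input- and weight-gradients are again circular (de)correlations.  Zero-padded
"same" convolution reuses the same machinery on a zero-embedded grid.

Gradient correctness for every layer is pinned down by central-difference
checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "Tanh",
    "MaxPool3d",
    "UpsampleNearest3d",
    "SqueezeExcite3d",
    "ResidualBlock3d",
    "he_normal",
]


class Parameter:
    """A trainable array with its gradient accumulator."""

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.asarray(data, dtype=float)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def he_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    """He (Kaiming) normal initialization: N(0, sqrt(2/fan_in))."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Module:
    """Base class: parameter collection plus forward/backward protocol."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in self.__dict__.values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training)

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name->array view of parameters (and buffers) for checkpoints."""
        out = {}
        for i, p in enumerate(self.parameters()):
            out[f"p{i}"] = p.data
        for j, (name, buf) in enumerate(self.buffers()):
            out[f"b{j}_{name}"] = buf
        return out

    def buffers(self) -> list[tuple[str, np.ndarray]]:
        bufs: list[tuple[str, np.ndarray]] = []
        for value in self.__dict__.values():
            if isinstance(value, Module):
                bufs.extend(value.buffers())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        bufs.extend(item.buffers())
        return bufs

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data[...] = state[f"p{i}"]
        for j, (name, buf) in enumerate(self.buffers()):
            buf[...] = state[f"b{j}_{name}"]


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------


def _embed_kernel(w: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Place a (Co, Ci, k, k, k) kernel on the full grid at wrapped offsets.

    Offset m in [-k//2, k//2] of the kernel lands at index m mod n, so the
    embedded kernel's spectrum multiplies like a centered correlation.
    """
    co, ci, k = w.shape[0], w.shape[1], w.shape[2]
    p = k // 2
    emb = np.zeros((co, ci) + shape, dtype=float)
    idx = [np.mod(np.arange(-p, p + 1), n) for n in shape]
    emb[:, :, idx[0][:, None, None], idx[1][None, :, None], idx[2][None, None, :]] = w
    return emb


class Conv3d(Module):
    """3D cross-correlation with 'same' output size.

    ``padding='circular'`` wraps periodically (used in the Encoding and
    Learning Features phases); ``padding='zeros'`` embeds the input in a
    zero border (Decoding phase).  Stride is 1; kernels are odd-sized.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 padding: str = "circular", rng: np.random.Generator | None = None):
        if kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd")
        if padding not in ("circular", "zeros"):
            raise ValueError(f"unknown padding {padding!r}")
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        fan_in = in_channels * k**3
        self.weight = Parameter(
            he_normal(rng, (out_channels, in_channels, k, k, k), fan_in), "weight"
        )
        self.bias = Parameter(np.zeros(out_channels), "bias")
        self.kernel_size = k
        self.padding = padding
        self._cache = None

    def _pad(self, x: np.ndarray) -> np.ndarray:
        p = self.kernel_size // 2
        if self.padding == "circular":
            return x
        return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))

    def _crop(self, y: np.ndarray) -> np.ndarray:
        if self.padding == "circular":
            return y
        p = self.kernel_size // 2
        return y[:, :, p:-p, p:-p, p:-p]

    def forward(self, x, training=False):
        xp = self._pad(x)
        shape = xp.shape[2:]
        Xf = np.fft.fftn(xp, axes=(2, 3, 4))
        Wf = np.fft.fftn(_embed_kernel(self.weight.data, shape), axes=(2, 3, 4))
        Yf = np.einsum("bixyz,oixyz->boxyz", Xf, np.conj(Wf))
        y = self._crop(np.fft.ifftn(Yf, axes=(2, 3, 4)).real)
        y += self.bias.data[None, :, None, None, None]
        if training:
            self._cache = (Xf, Wf, x.shape, shape)
        return y

    def backward(self, grad):
        Xf, Wf, x_shape, shape = self._cache
        p = self.kernel_size // 2
        if self.padding == "zeros":
            g = np.zeros(grad.shape[:2] + shape, dtype=float)
            g[:, :, p:-p, p:-p, p:-p] = grad
        else:
            g = grad
        Gf = np.fft.fftn(g, axes=(2, 3, 4))
        # input gradient: circular convolution of grad with the kernel
        dXf = np.einsum("boxyz,oixyz->bixyz", Gf, Wf)
        dxp = np.fft.ifftn(dXf, axes=(2, 3, 4)).real
        if self.padding == "zeros":
            dx = dxp[:, :, p:-p, p:-p, p:-p]
        else:
            dx = dxp
        # weight gradient: correlation of input with grad, read at kernel offsets
        dWf = np.einsum("bixyz,boxyz->oixyz", Xf, np.conj(Gf))
        dwe = np.fft.ifftn(dWf, axes=(2, 3, 4)).real
        idx = [np.mod(np.arange(-p, p + 1), n) for n in shape]
        self.weight.grad += dwe[
            :, :, idx[0][:, None, None], idx[1][None, :, None], idx[2][None, None, :]
        ]
        self.bias.grad += grad.sum(axis=(0, 2, 3, 4))
        return dx


# ---------------------------------------------------------------------------
# normalization and activations
# ---------------------------------------------------------------------------


class BatchNorm3d(Module):
    """Per-channel batch normalization with affine terms and running stats."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels), "gamma")
        self.beta = Parameter(np.zeros(channels), "beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def buffers(self):
        return [("running_mean", self.running_mean), ("running_var", self.running_var)]

    def forward(self, x, training=False):
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean *= 1.0 - self.momentum
            self.running_mean += self.momentum * mean
            self.running_var *= 1.0 - self.momentum
            self.running_var += self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * inv_std[None, :, None, None, None]
        if training:
            self._cache = (xhat, inv_std, x.shape)
        return self.gamma.data[None, :, None, None, None] * xhat + \
            self.beta.data[None, :, None, None, None]

    def backward(self, grad):
        xhat, inv_std, shape = self._cache
        axes = (0, 2, 3, 4)
        m = shape[0] * shape[2] * shape[3] * shape[4]
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self.gamma.data[None, :, None, None, None]
        gsum = g.sum(axis=axes, keepdims=True)
        gxsum = (g * xhat).sum(axis=axes, keepdims=True)
        return inv_std[None, :, None, None, None] * (g - gsum / m - xhat * gxsum / m)


class ReLU(Module):
    def forward(self, x, training=False):
        mask = x > 0
        if training:
            self._mask = mask
        return x * mask

    def backward(self, grad):
        return grad * self._mask


class Tanh(Module):
    def forward(self, x, training=False):
        y = np.tanh(x)
        if training:
            self._y = y
        return y

    def backward(self, grad):
        return grad * (1.0 - self._y**2)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


class MaxPool3d(Module):
    """2x2x2 max pooling with stride 2 (axes must be even)."""

    def forward(self, x, training=False):
        b, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError("max pooling requires even spatial dimensions")
        blocks = (
            x.reshape(b, c, d // 2, 2, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 2, 4, 6, 3, 5, 7)
            .reshape(b, c, d // 2, h // 2, w // 2, 8)
        )
        idx = blocks.argmax(axis=-1)
        y = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (idx, x.shape)
        return y

    def backward(self, grad):
        idx, (b, c, d, h, w) = self._cache
        blocks = np.zeros((b, c, d // 2, h // 2, w // 2, 8))
        np.put_along_axis(blocks, idx[..., None], grad[..., None], axis=-1)
        return (
            blocks.reshape(b, c, d // 2, h // 2, w // 2, 2, 2, 2)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(b, c, d, h, w)
        )


class UpsampleNearest3d(Module):
    """Naive (nearest-neighbor) x2 upsampling."""

    def forward(self, x, training=False):
        self._in_shape = x.shape
        return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(self, grad):
        b, c, d, h, w = self._in_shape
        return (
            grad.reshape(b, c, d, 2, h, 2, w, 2).sum(axis=(3, 5, 7))
        )


# ---------------------------------------------------------------------------
# squeeze-and-excitation and residual blocks
# ---------------------------------------------------------------------------


class SqueezeExcite3d(Module):
    """Channel reweighting from globally pooled statistics.

    Global average pool -> FC bottleneck (width / reduction) -> ReLU -> FC
    back to full width -> sigmoid gate multiplying each channel.
    """

    def __init__(self, channels: int, reduction: int = 2,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        hidden = max(1, channels // reduction)
        self.w1 = Parameter(he_normal(rng, (hidden, channels), channels), "se_w1")
        self.b1 = Parameter(np.zeros(hidden), "se_b1")
        self.w2 = Parameter(he_normal(rng, (channels, hidden), hidden), "se_w2")
        self.b2 = Parameter(np.zeros(channels), "se_b2")
        self._cache = None

    def forward(self, x, training=False):
        z = x.mean(axis=(2, 3, 4))  # (B, C)
        h = z @ self.w1.data.T + self.b1.data
        a = np.maximum(h, 0.0)
        u = a @ self.w2.data.T + self.b2.data
        s = 1.0 / (1.0 + np.exp(-u))  # (B, C)
        y = x * s[:, :, None, None, None]
        if training:
            self._cache = (x, z, h, a, s)
        return y

    def backward(self, grad):
        x, z, h, a, s = self._cache
        nspat = x.shape[2] * x.shape[3] * x.shape[4]
        ds = (grad * x).sum(axis=(2, 3, 4))  # (B, C)
        du = ds * s * (1.0 - s)
        self.w2.grad += du.T @ a
        self.b2.grad += du.sum(axis=0)
        da = du @ self.w2.data
        dh = da * (h > 0)
        self.w1.grad += dh.T @ z
        self.b1.grad += dh.sum(axis=0)
        dz = dh @ self.w1.data  # (B, C)
        dx = grad * s[:, :, None, None, None]
        dx += dz[:, :, None, None, None] / nspat
        return dx


class ResidualBlock3d(Module):
    """conv-BN-ReLU-conv-BN [-SE] + skip, then ReLU; periodic padding."""

    def __init__(self, channels: int, kernel_size: int = 7, use_se: bool = True,
                 se_reduction: int = 2, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv3d(channels, channels, kernel_size, "circular", rng)
        self.bn1 = BatchNorm3d(channels)
        self.relu1 = ReLU()
        self.conv2 = Conv3d(channels, channels, kernel_size, "circular", rng)
        self.bn2 = BatchNorm3d(channels)
        self.se = SqueezeExcite3d(channels, se_reduction, rng) if use_se else None
        self.relu_out = ReLU()

    def forward(self, x, training=False):
        y = self.bn1.forward(self.conv1.forward(x, training), training)
        y = self.relu1.forward(y, training)
        y = self.bn2.forward(self.conv2.forward(y, training), training)
        if self.se is not None:
            y = self.se.forward(y, training)
        return self.relu_out.forward(y + x, training)

    def backward(self, grad):
        g = self.relu_out.backward(grad)
        skip = g
        if self.se is not None:
            g = self.se.backward(g)
        g = self.bn2.backward(g)
        g = self.conv2.backward(g)
        g = self.relu1.backward(g)
        g = self.bn1.backward(g)
        g = self.conv1.backward(g)
        return g + skip
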