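"""Minimal NumPy neural-network layers with exact parameter accounting.

Only what symmetric image autoencoders need: dense layers, 3×3 same-padding
convolutions (forward and transposed), 2×2 max pooling and nearest-neighbor
up-sampling, ReLU/sigmoid activations, binary-cross-entropy and MSE losses,
and Adam. Everything is deliberately small and deterministic: a fixed PCG64
seed yields bit-identical training runs in single-threaded use, and every
layer knows its trainable-parameter count *structurally* — from its shapes,
before any weights are allocated — so architectures with tens of millions
of parameters can be audited without touching memory.

Data layout is channels-last: batches are (N, H, W, C) for convolutional
layers and (N, features) for dense layers. Weights are allocated lazily by
``initialize``; counts and summaries never require allocation.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Flatten",
    "Reshape",
    "Dense",
    "Conv2D",
    "ConvTranspose2D",
    "MaxPool2D",
    "UpSampling2D",
    "Adam",
    "bce_loss",
    "mse_loss",
]

_EPS = 1e-7


def _apply_activation(z: np.ndarray, activation: str) -> np.ndarray:
    if activation == "relu":
        return np.maximum(z, 0.0)
    if activation == "sigmoid":
        # clip the pre-activation to keep exp() finite
        return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))
    if activation == "linear":
        return z
    raise ValueError(f"unknown activation {activation!r}")


def _activation_grad(y: np.ndarray, activation: str) -> np.ndarray:
    """d(activation)/d(pre-activation), expressed through the output y."""
    if activation == "relu":
        return (y > 0.0).astype(y.dtype)
    if activation == "sigmoid":
        return y * (1.0 - y)
    if activation == "linear":
        return np.ones_like(y)
    raise ValueError(f"unknown activation {activation!r}")


class Layer:
    """Base layer: shape propagation, lazy weights, forward/backward."""

    activation: str = ""

    def __init__(self, name: str):
        self.name = name
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    # -- structural interface (no allocation needed) --
    def output_shape(self, input_shape: tuple[int, ...]) -> tuple[int, ...]:
        raise NotImplementedError

    @property
    def param_count(self) -> int:
        return 0

    @property
    def type_name(self) -> str:
        return type(self).__name__

    # -- runtime interface --
    def initialize(self, rng: np.random.Generator) -> None:  # noqa: ARG002
        pass

    def forward(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Flatten(Layer):
    def __init__(self, name: str = "flatten"):
        super().__init__(name)
        self._shape: tuple[int, ...] | None = None

    def output_shape(self, input_shape):
        return (int(np.prod(input_shape)),)

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, target: tuple[int, ...], name: str = "reshape"):
        super().__init__(name)
        self.target = tuple(target)

    def output_shape(self, input_shape):  # noqa: ARG002
        return self.target

    def forward(self, x):
        return x.reshape((x.shape[0],) + self.target)

    def backward(self, grad):
        return grad.reshape(grad.shape[0], -1)


class Dense(Layer):
    """Fully connected layer with bias: params = n_in * n_out + n_out."""

    def __init__(self, n_in: int, n_out: int, activation: str = "relu", name: str = "dense"):
        super().__init__(name)
        self.n_in = int(n_in)
        self.n_out = int(n_out)
        self.activation = activation
        self.w: np.ndarray | None = None
        self.b: np.ndarray | None = None

    def output_shape(self, input_shape):
        if input_shape != (self.n_in,):
            raise ValueError(f"{self.name}: expected input ({self.n_in},), got {input_shape}")
        return (self.n_out,)

    @property
    def param_count(self) -> int:
        return self.n_in * self.n_out + self.n_out

    def initialize(self, rng):
        # uniform scaled by fan-in
        limit = 1.0 / np.sqrt(self.n_in)
        self.w = rng.uniform(-limit, limit, size=(self.n_in, self.n_out))
        self.b = np.zeros(self.n_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x):
        self._x = x
        self._y = _apply_activation(x @ self.w + self.b, self.activation)
        return self._y

    def backward(self, grad):
        dz = grad * _activation_grad(self._y, self.activation)
        self.grads[0][...] = self._x.T @ dz
        self.grads[1][...] = dz.sum(axis=0)
        return dz @ self.w.T


class Conv2D(Layer):
    """3×3 convolution, stride 1, same (zero) padding, with bias.

    params = k² * c_in * c_out + c_out. Implemented with an im2col/GEMM
    scheme; the kernel is applied as a correlation.
    """

    _flip_kernel = False

    def __init__(
        self, c_in: int, c_out: int, k: int = 3, activation: str = "relu", name: str = "conv"
    ):
        super().__init__(name)
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.c_in = int(c_in)
        self.c_out = int(c_out)
        self.k = int(k)
        self.activation = activation
        self.w: np.ndarray | None = None
        self.b: np.ndarray | None = None

    def output_shape(self, input_shape):
        h, w, c = input_shape
        if c != self.c_in:
            raise ValueError(f"{self.name}: expected {self.c_in} channels, got {c}")
        return (h, w, self.c_out)

    @property
    def param_count(self) -> int:
        return self.k * self.k * self.c_in * self.c_out + self.c_out

    def initialize(self, rng):
        fan_in = self.k * self.k * self.c_in
        limit = 1.0 / np.sqrt(fan_in)
        self.w = rng.uniform(-limit, limit, size=(self.k, self.k, self.c_in, self.c_out))
        self.b = np.zeros(self.c_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def _kernel_matrix(self) -> np.ndarray:
        w = self.w[::-1, ::-1] if self._flip_kernel else self.w
        return w.reshape(self.k * self.k * self.c_in, self.c_out)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = np.empty((n, h, w, self.k, self.k, c), dtype=x.dtype)
        for i in range(self.k):
            for j in range(self.k):
                cols[:, :, :, i, j, :] = xp[:, i : i + h, j : j + w, :]
        return cols.reshape(n * h * w, self.k * self.k * c)

    def forward(self, x):
        n, h, w, _ = x.shape
        self._cols = self._im2col(x)
        self._in_shape = x.shape
        z = self._cols @ self._kernel_matrix() + self.b
        self._y = _apply_activation(z.reshape(n, h, w, self.c_out), self.activation)
        return self._y

    def backward(self, grad):
        n, h, w, _ = self._in_shape
        dz = (grad * _activation_grad(self._y, self.activation)).reshape(-1, self.c_out)
        dw_mat = self._cols.T @ dz
        dw = dw_mat.reshape(self.k, self.k, self.c_in, self.c_out)
        if self._flip_kernel:
            dw = dw[::-1, ::-1]
        self.grads[0][...] = dw
        self.grads[1][...] = dz.sum(axis=0)
        # scatter column gradients back to the padded input
        dcols = (dz @ self._kernel_matrix().T).reshape(n, h, w, self.k, self.k, self.c_in)
        p = self.k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, self.c_in))
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, p : p + h, p : p + w, :]


class ConvTranspose2D(Conv2D):
    """Stride-1 transposed 3×3 convolution with same padding.

    At stride 1 the transpose of a same-padded correlation is a correlation
    with the spatially flipped kernel; the parameter count is identical to
    the forward convolution. Kept as its own layer type so decoder summaries
    mirror the encoder structurally.
    """

    _flip_kernel = True


class MaxPool2D(Layer):
    """2×2 max pooling, stride 2; ties route the gradient to the first max."""

    def __init__(self, name: str = "maxpool"):
        super().__init__(name)

    def output_shape(self, input_shape):
        h, w, c = input_shape
        if h % 2 or w % 2:
            raise ValueError(f"{self.name}: spatial dims must be even, got {h}x{w}")
        return (h // 2, w // 2, c)

    def forward(self, x):
        n, h, w, c = x.shape
        r = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        r = r.reshape(n, h // 2, w // 2, c, 4)
        self._argmax = r.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(r, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        n, h, w, c = self._in_shape
        flat = np.zeros((n, h // 2, w // 2, c, 4))
        np.put_along_axis(flat, self._argmax[..., None], grad[..., None], axis=-1)
        flat = flat.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return flat.reshape(n, h, w, c)


class UpSampling2D(Layer):
    """Nearest-neighbor 2× up-sampling; the backward pass sums 2×2 blocks."""

    def __init__(self, name: str = "upsample"):
        super().__init__(name)

    def output_shape(self, input_shape):
        h, w, c = input_shape
        return (2 * h, 2 * w, c)

    def forward(self, x):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, grad):
        n, h2, w2, c = grad.shape
        return grad.reshape(n, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4))


class Adam:
    """Adam optimizer: step size 0.001, moment decays 0.9 / 0.999."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self, layers: list[Layer]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for layer in layers:
            for idx, (p, g) in enumerate(zip(layer.params, layer.grads)):
                key = (id(layer), idx)
                if key not in self._m:
                    self._m[key] = np.zeros_like(p)
                    self._v[key] = np.zeros_like(p)
                m = self._m[key]
                v = self._v[key]
                m *= self.beta1
                m += (1 - self.beta1) * g
                v *= self.beta2
                v += (1 - self.beta2) * g * g
                p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def bce_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Per-element mean binary cross entropy and its gradient w.r.t. pred."""
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    n = p.size
    loss = float(-(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)).mean())
    grad = (p - target) / (p * (1.0 - p)) / n
    return loss, grad


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Per-element mean squared error and its gradient w.r.t. pred."""
    diff = pred - target
    loss = float((diff**2).mean())
    return loss, 2.0 * diff / diff.size
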