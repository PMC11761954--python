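"""Minimal NumPy layer stack used by the patch-level CNN and the MIL meta-model.

Every layer implements ``forward`` (caching what its backward pass needs) and
``backward`` (returning the gradient with respect to its input and filling
``grads``). Affine layers additionally expose ``input_grad``, a cache-light
input-gradient used by attribution, which depends only on the layer weights
and the input shape.

Convolution follows the per-channel formulation

    X_{t+1}(c) = b_c + sum_k  W_{c,k} * X_t(k)

with a cross-correlation kernel (the deep-learning convention), evaluated via
im2col + GEMM for speed. All computation is float32 unless callers pass
float64.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class; stateless layers leave ``params``/``grads`` empty."""

    affine = False  # True when output is an affine function of the input

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, oh: int, ow: int) -> np.ndarray:
    """(N, C, Hp, Wp) padded input -> (C*kh*kw, N*oh*ow) column matrix.

    The batch dimension is folded into the GEMM columns so the convolution
    becomes one large matrix product, which is what keeps single-core BLAS
    throughput high.
    """
    n, c = xp.shape[:2]
    cols = np.empty((c, kh, kw, n, oh, ow), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, i, j] = xp[:, :, i : i + stride * oh : stride,
                               j : j + stride * ow : stride].transpose(1, 0, 2, 3)
    return cols.reshape(c * kh * kw, n * oh * ow)


def _col2im(gcols: np.ndarray, shape: tuple, kh: int, kw: int, stride: int,
            pad: int, oh: int, ow: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`; scatters column gradients back to image."""
    n, c, h, w = shape
    gxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=gcols.dtype)
    g6 = gcols.reshape(c, kh, kw, n, oh, ow)
    for i in range(kh):
        for j in range(kw):
            gxp[:, :, i : i + stride * oh : stride,
                j : j + stride * ow : stride] += g6[:, i, j].transpose(1, 0, 2, 3)
    if pad:
        return gxp[:, :, pad : pad + h, pad : pad + w]
    return gxp


class Conv2d(Layer):
    affine = True

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 stride: int = 1, padding: int = 0, rng: np.random.Generator | None = None):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kh = self.kw = int(kernel_size)
        self.stride = int(stride)
        self.padding = int(padding)
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * self.kh * self.kw
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels, self.kh, self.kw))
        self.params = {"W": w.astype(np.float32), "b": np.zeros(out_channels, dtype=np.float32)}
        self._cache: tuple | None = None
        self._in_shape: tuple | None = None

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        oh = (h + 2 * self.padding - self.kh) // self.stride + 1
        ow = (w + 2 * self.padding - self.kw) // self.stride + 1
        return oh, ow

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected input (N, {self.in_channels}, H, W), got {x.shape}")
        n, c, h, w = x.shape
        oh, ow = self.out_hw(h, w)
        if oh < 1 or ow < 1:
            raise ValueError(f"kernel {self.kh}x{self.kw} does not fit input {h}x{w}")
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = _im2col(xp, self.kh, self.kw, self.stride, oh, ow)
        w2 = self.params["W"].reshape(self.out_channels, -1)
        out = w2 @ cols  # (C_out, N*oh*ow)
        out += self.params["b"][:, None]
        self._cache = (cols, x.shape, oh, ow)
        self._in_shape = x.shape
        return out.reshape(self.out_channels, n, oh, ow).transpose(1, 0, 2, 3)

    def _fold_gout(self, gout: np.ndarray) -> np.ndarray:
        n, _, oh, ow = gout.shape
        return np.ascontiguousarray(gout.transpose(1, 0, 2, 3)).reshape(
            self.out_channels, n * oh * ow)

    def backward(self, gout: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        cols, xshape, oh, ow = self._cache
        g2 = self._fold_gout(gout)
        self.grads["W"] = (g2 @ cols.T).reshape(self.params["W"].shape)
        self.grads["b"] = g2.sum(axis=1)
        if not need_input_grad:
            return None
        w2 = self.params["W"].reshape(self.out_channels, -1)
        gcols = w2.T @ g2
        return _col2im(gcols, xshape, self.kh, self.kw, self.stride, self.padding, oh, ow)

    def input_grad(self, gout: np.ndarray, in_shape: tuple | None = None) -> np.ndarray:
        shape = in_shape or self._in_shape
        _, _, h, w = shape
        oh, ow = self.out_hw(h, w)
        g2 = self._fold_gout(gout)
        w2 = self.params["W"].reshape(self.out_channels, -1)
        gcols = w2.T @ g2
        return _col2im(gcols, shape, self.kh, self.kw, self.stride, self.padding, oh, ow)


class Linear(Layer):
    """Fully connected layer computing ``x @ W + b`` (W has shape (C_in, C_out))."""

    affine = True

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(in_features, out_features))
        self.params = {"W": w.astype(np.float32), "b": np.zeros(out_features, dtype=np.float32)}
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 2 or x.shape[1] != self.in_features:
            raise ValueError(f"expected input (N, {self.in_features}), got {x.shape}")
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ gout
        self.grads["b"] = gout.sum(axis=0)
        return gout @ self.params["W"].T

    def input_grad(self, gout: np.ndarray, in_shape: tuple | None = None) -> np.ndarray:
        return gout @ self.params["W"].T


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C); linear, so attribution passes straight through."""

    affine = True

    def __init__(self) -> None:
        super().__init__()
        self._in_shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return self.input_grad(gout)

    def input_grad(self, gout: np.ndarray, in_shape: tuple | None = None) -> np.ndarray:
        n, c, h, w = in_shape or self._in_shape
        return np.broadcast_to(gout[:, :, None, None], (n, c, h, w)) / (h * w)


class AvgPool2d(Layer):
    """Non-overlapping k x k mean pooling; H and W must be divisible by k."""

    affine = True

    def __init__(self, k: int):
        super().__init__()
        self.k = int(k)
        self._in_shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.k
        if h % k or w % k:
            raise ValueError(f"input {h}x{w} not divisible by pool size {k}")
        self._in_shape = x.shape
        return x.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return self.input_grad(gout)

    def input_grad(self, gout: np.ndarray, in_shape: tuple | None = None) -> np.ndarray:
        n, c, h, w = in_shape or self._in_shape
        k = self.k
        g = np.repeat(np.repeat(gout, k, axis=2), k, axis=3) / (k * k)
        return g.astype(gout.dtype)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._mask

    @staticmethod
    def fn(x: np.ndarray) -> np.ndarray:
        return np.maximum(x, 0)

    @staticmethod
    def deriv(x: np.ndarray) -> np.ndarray:
        return (x > 0).astype(x.dtype)


class Tanh(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * (1.0 - self._y ** 2)

    @staticmethod
    def fn(x: np.ndarray) -> np.ndarray:
        return np.tanh(x)

    @staticmethod
    def deriv(x: np.ndarray) -> np.ndarray:
        t = np.tanh(x)
        return 1.0 - t ** 2


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64 if x.dtype == np.float64 else np.float32)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = sigmoid(x)
        return self._y

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._y * (1.0 - self._y)

    @staticmethod
    def fn(x: np.ndarray) -> np.ndarray:
        return sigmoid(x)

    @staticmethod
    def deriv(x: np.ndarray) -> np.ndarray:
        s = sigmoid(x)
        return s * (1.0 - s)


ELEMENTWISE = (ReLU, Tanh, Sigmoid)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    __call__ = forward

    def backward(self, gout: np.ndarray, to_input: bool = False) -> np.ndarray | None:
        """Backpropagate; unless ``to_input``, stops after the first (deepest)
        trainable layer — gradients below it are never consumed in training."""
        first_param = next((i for i, l in enumerate(self.layers) if l.params), 0)
        stop = 0 if to_input else first_param
        for i in range(len(self.layers) - 1, stop - 1, -1):
            layer = self.layers[i]
            if i == stop and isinstance(layer, Conv2d) and not to_input:
                layer.backward(gout, need_input_grad=False)
                return None
            gout = layer.backward(gout)
        return gout

    def parameters(self):
        """Yield (layer_index, name, array) triples for all trainable params."""
        for i, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                yield i, name, p

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"{i}.{name}": p for i, name, p in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = np.asarray(state[f"{i}.{name}"], dtype=np.float32)
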