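"""A small, self-contained NumPy neural-network engine.

Implements exactly the pieces the retrieval network needs — valid-mode 2D
convolution, batch normalization, 2x2 max pooling, ReLU, dense layers — with
reverse-mode gradients, plus plain gradient descent

    w  <-  w - alpha * dCost/dw

and an Adam variant.  Convolutions are lowered to matrix multiplies (im2col)
so the heavy lifting runs in BLAS.  All parameters are float32 by default;
``Sequential.astype(np.float64)`` is available for numerical gradient checks.

This is deliberately minimal: no autograd graph, just layers with
``forward``/``backward`` and explicit parameter dictionaries, which keeps the
weight-update rule inspectable.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv2D", "MaxPool2", "BatchNorm", "ReLU", "Flatten", "Dense",
    "Sequential", "SGD", "Adam", "half_squared_error", "weight_update",
]


def half_squared_error(y_pred: np.ndarray, y_true: np.ndarray
                       ) -> tuple[float, np.ndarray]:
    """Quadratic cost 0.5 (y_pred - y_true)^2 averaged over all components.

    Returns ``(cost, dcost/dy_pred)``.
    """
    y_pred = np.asarray(y_pred)
    y_true = np.asarray(y_true)
    if y_pred.shape != y_true.shape:
        raise ValueError(f"shape mismatch {y_pred.shape} vs {y_true.shape}")
    diff = y_pred - y_true
    cost = float(0.5 * np.mean(diff * diff))
    return cost, (diff / diff.size).astype(y_pred.dtype)


def weight_update(w, gradient, alpha: float):
    """One plain gradient-descent step: ``w - alpha * gradient``."""
    if alpha <= 0:
        raise ValueError("learning rate must be positive")
    return w - alpha * gradient


class Layer:
    """Base layer: ``params``/``grads`` are parallel name->array dicts."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def state(self) -> dict[str, np.ndarray]:
        """Arrays beyond parameters needed to reproduce inference (e.g. running stats)."""
        return {}


class Conv2D(Layer):
    """Valid-mode 2D convolution (cross-correlation), NCHW layout."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.kh = self.kw = int(kernel_size)
        fan_in = in_channels * self.kh * self.kw
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_channels, in_channels, self.kh, self.kw))
        self.params = {"w": w.astype(dtype), "b": np.zeros(out_channels, dtype=dtype)}

    def _cols(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        if h < self.kh or w < self.kw:
            raise ValueError(f"kernel {self.kh}x{self.kw} larger than input {h}x{w}")
        v = np.lib.stride_tricks.sliding_window_view(x, (self.kh, self.kw), axis=(2, 3))
        # (B, C, H', W', kh, kw) -> (B*H'*W', C*kh*kw) contiguous for BLAS
        ho, wo = v.shape[2], v.shape[3]
        return v.transpose(0, 2, 3, 1, 4, 5).reshape(b * ho * wo, -1), ho, wo

    def forward(self, x, training):
        cols, ho, wo = self._cols(x)
        w = self.params["w"]
        wmat = w.reshape(w.shape[0], -1)
        out = cols @ wmat.T + self.params["b"]
        self._cache = (cols, x.shape, ho, wo)
        return out.reshape(x.shape[0], ho, wo, w.shape[0]).transpose(0, 3, 1, 2)

    def backward(self, grad):
        cols, xshape, ho, wo = self._cache
        b, c, h, w_in = xshape
        w = self.params["w"]
        g2 = grad.transpose(0, 2, 3, 1).reshape(-1, w.shape[0])   # (B*H'*W', O)
        self.grads["w"] = (g2.T @ cols).reshape(w.shape)
        self.grads["b"] = g2.sum(axis=0)
        dcols = g2 @ w.reshape(w.shape[0], -1)                     # (B*H'*W', C*kh*kw)
        dcols = dcols.reshape(b, ho, wo, c, self.kh, self.kw)
        dx = np.zeros(xshape, dtype=grad.dtype)
        for i in range(self.kh):
            for j in range(self.kw):
                dx[:, :, i:i + ho, j:j + wo] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self._cache = None
        return dx


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; odd trailing rows/columns are dropped.

    Works on strided views of the input, so no im2col-style copies are made;
    on ties the gradient is routed to the first window element.
    """

    @staticmethod
    def _quadrants(x, hh, ww):
        return (x[:, :, 0:2 * hh:2, 0:2 * ww:2], x[:, :, 0:2 * hh:2, 1:2 * ww:2],
                x[:, :, 1:2 * hh:2, 0:2 * ww:2], x[:, :, 1:2 * hh:2, 1:2 * ww:2])

    def forward(self, x, training):
        hh, ww = x.shape[2] // 2, x.shape[3] // 2
        q = self._quadrants(x, hh, ww)
        out = np.maximum(np.maximum(q[0], q[1]), np.maximum(q[2], q[3]))
        self._cache = (x.shape, q, out)
        return out

    def backward(self, grad):
        xshape, q, out = self._cache
        hh, ww = out.shape[2], out.shape[3]
        dx = np.zeros(xshape, dtype=grad.dtype)
        dviews = self._quadrants(dx, hh, ww)
        remaining = np.ones(out.shape, dtype=bool)
        for s, dv in zip(q, dviews):
            sel = (s == out) & remaining
            dv += grad * sel
            remaining &= ~sel
        self._cache = None
        return dx


class BatchNorm(Layer):
    """Batch normalization over the batch (and spatial axes for NCHW input).

    Learnable per-channel scale/shift; running mean/variance (momentum 0.9)
    are used at inference time.
    """

    def __init__(self, n_channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {"gamma": np.ones(n_channels, dtype=dtype),
                       "beta": np.zeros(n_channels, dtype=dtype)}
        self.running_mean = np.zeros(n_channels, dtype=dtype)
        self.running_var = np.ones(n_channels, dtype=dtype)

    def _axes_shape(self, x):
        if x.ndim == 4:
            return (0, 2, 3), (1, -1, 1, 1)
        if x.ndim == 2:
            return (0,), (1, -1)
        raise ValueError("BatchNorm expects 2D or 4D input")

    def forward(self, x, training):
        axes, bshape = self._axes_shape(x)
        gamma, beta = self.params["gamma"], self.params["beta"]
        if not training:
            # fused inference path: y = a*x + c with frozen running statistics
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            a = (gamma * inv).reshape(bshape).astype(x.dtype)
            c = (beta - gamma * inv * self.running_mean).reshape(bshape).astype(x.dtype)
            return x * a + c
        mean = x.mean(axis=axes)
        var = np.maximum((x * x).mean(axis=axes) - mean * mean, 0.0)
        m = self.momentum
        self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(x.dtype)
        self.running_var = (m * self.running_var + (1 - m) * var).astype(x.dtype)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(bshape)) * inv.reshape(bshape)
        self._cache = (xhat, inv, axes, bshape,
                       np.prod([x.shape[a] for a in axes]))
        return gamma.reshape(bshape) * xhat + beta.reshape(bshape)

    def backward(self, grad):
        xhat, inv, axes, bshape, n = self._cache
        gsum = grad.sum(axis=axes)
        gxsum = (grad * xhat).sum(axis=axes)
        self.grads["gamma"] = gxsum
        self.grads["beta"] = gsum
        k = self.params["gamma"] * inv / n
        dx = grad * (k * n).reshape(bshape)
        dx -= xhat * (k * gxsum).reshape(bshape)
        dx -= (k * gsum).reshape(bshape)
        self._cache = None
        return dx.astype(grad.dtype, copy=False)

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    """Affine layer ``x @ w + b`` with He-normal initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.params = {"w": w.astype(dtype), "b": np.zeros(n_out, dtype=dtype)}

    def forward(self, x, training):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, grad):
        self.grads["w"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        dx = grad @ self.params["w"].T
        self._x = None
        return dx


class Sequential:
    """A plain layer stack with explicit forward/backward passes."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        """Yield ``(layer, name)`` pairs for every learnable parameter."""
        for layer in self.layers:
            for name in layer.params:
                yield layer, name

    def n_parameters(self) -> int:
        return sum(layer.params[name].size for layer, name in self.parameters())

    def astype(self, dtype) -> "Sequential":
        for layer in self.layers:
            for name in list(layer.params):
                layer.params[name] = layer.params[name].astype(dtype)
            if isinstance(layer, BatchNorm):
                layer.running_mean = layer.running_mean.astype(dtype)
                layer.running_var = layer.running_var.astype(dtype)
        return self

    # -- state flattening for serialization ---------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params.items():
                out[f"layer{i}.{name}"] = arr
            for name, arr in layer.state().items():
                out[f"layer{i}.{name}"] = arr
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = np.array(arrays[f"layer{i}.{name}"])
            if isinstance(layer, BatchNorm):
                layer.running_mean = np.array(arrays[f"layer{i}.running_mean"])
                layer.running_var = np.array(arrays[f"layer{i}.running_var"])


class SGD:
    """Plain gradient descent: every parameter moves by ``-alpha * gradient``."""

    def __init__(self, net: Sequential, alpha: float):
        if alpha <= 0:
            raise ValueError("learning rate must be positive")
        self.net = net
        self.alpha = alpha

    def step(self):
        for layer, name in self.net.parameters():
            layer.params[name] = weight_update(layer.params[name],
                                               layer.grads[name], self.alpha)


class Adam:
    """Adam optimizer (Kingma & Ba) as a drop-in alternative to plain descent."""

    def __init__(self, net: Sequential, alpha: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        if alpha <= 0:
            raise ValueError("learning rate must be positive")
        self.net = net
        self.alpha, self.beta1, self.beta2, self.eps = alpha, beta1, beta2, eps
        self.t = 0
        self._m = {}
        self._v = {}

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for layer, name in self.net.parameters():
            key = (id(layer), name)
            g = layer.grads[name]
            m = self._m.get(key, 0.0) * b1 + (1 - b1) * g
            v = self._v.get(key, 0.0) * b2 + (1 - b2) * g * g
            self._m[key], self._v[key] = m, v
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            layer.params[name] = (layer.params[name]
                                  - self.alpha * mhat / (np.sqrt(vhat) + self.eps)
                                  ).astype(layer.params[name].dtype)
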