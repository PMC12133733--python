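"""Minimal NumPy neural-network layers with hand-written backpropagation.

Every layer is a :class:`Module` caching whatever its backward pass needs
during ``forward``.  A module instance must therefore appear at most once in
a forward graph per step (the assembled networks in this package satisfy
this).  Parameters are float32 by default but all arithmetic is
dtype-agnostic so tests can run gradient checks in float64.

Dropout and weight initialisation draw from a package-level generator; call
:func:`seed_all` before building a model for reproducible runs.
"""

from __future__ import annotations

import numpy as np

_GLOBAL_RNG = np.random.default_rng(0)


def seed_all(seed: int) -> None:
    """Reset the generator used for initialisation and dropout."""
    global _GLOBAL_RNG
    _GLOBAL_RNG = np.random.default_rng(seed)


def get_rng() -> np.random.Generator:
    return _GLOBAL_RNG


class Parameter:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad", "trainable")

    def __init__(self, value: np.ndarray, trainable: bool = True):
        self.value = np.asarray(value)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable

    @property
    def shape(self):
        return self.value.shape

    @property
    def size(self):
        return self.value.size


def _kaiming(shape, fan_in, rng=None):
    rng = rng or _GLOBAL_RNG
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)


class Module:
    """Base class; tracks child modules/parameters via attribute assignment."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", False)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Parameter]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0

    def freeze(self, frozen: bool = True):
        for p in self.parameters():
            p.trainable = not frozen
        return self

    def state_dict(self) -> dict:
        out = {}
        for name, p in self._params.items():
            out[name] = p.value.copy()
        for name, m in self._modules.items():
            for k, v in m.state_dict().items():
                out[f"{name}.{k}"] = v
        for name in getattr(self, "_buffers", ()):  # running stats
            out[name] = getattr(self, name).copy()
        return out

    def load_state_dict(self, state: dict, prefix: str = ""):
        for name, p in self._params.items():
            p.value[...] = state[prefix + name]
        for name in getattr(self, "_buffers", ()):
            getattr(self, name)[...] = state[prefix + name]
        for name, m in self._modules.items():
            m.load_state_dict(state, prefix=f"{prefix}{name}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, l in enumerate(layers):
            setattr(self, f"_layer{i}", l)

    def forward(self, x):
        for l in self.layers:
            x = l(x)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


# ---------------------------------------------------------------------------
# Dense / grouped dense layers
# ---------------------------------------------------------------------------

class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(_kaiming((out_features, in_features), in_features))
        self.bias = Parameter(np.zeros(out_features, np.float32)) if bias else None

    def forward(self, x):
        self._x = x
        y = x @ self.weight.value.T
        if self.bias is not None:
            y = y + self.bias.value
        return y

    def backward(self, grad):
        self.weight.grad += grad.T @ self._x
        if self.bias is not None:
            self.bias.grad += grad.sum(0)
        return grad @ self.weight.value


class GroupedLinear(Module):
    """g independent affine maps on contiguous feature groups.

    Parameter count is in_features*out_features/g + out_features, a g-fold
    reduction over a dense map.
    """

    def __init__(self, in_features: int, out_features: int, groups: int,
                 bias: bool = True):
        super().__init__()
        if in_features % groups or out_features % groups:
            raise ValueError(
                f"in/out features ({in_features}, {out_features}) must be "
                f"divisible by groups={groups}")
        self.in_features, self.out_features, self.groups = (
            in_features, out_features, groups)
        d1g, d2g = in_features // groups, out_features // groups
        self.weight = Parameter(_kaiming((groups, d2g, d1g), d1g))
        self.bias = Parameter(np.zeros(out_features, np.float32)) if bias else None

    def forward(self, x):
        n = x.shape[0]
        xg = x.reshape(n, self.groups, -1)
        self._xg = xg
        y = np.einsum("ngi,goi->ngo", xg, self.weight.value).reshape(n, -1)
        if self.bias is not None:
            y = y + self.bias.value
        return y

    def backward(self, grad):
        n = grad.shape[0]
        gg = grad.reshape(n, self.groups, -1)
        self.weight.grad += np.einsum("ngo,ngi->goi", gg, self._xg)
        if self.bias is not None:
            self.bias.grad += grad.sum(0)
        gx = np.einsum("ngo,goi->ngi", gg, self.weight.value)
        return gx.reshape(n, -1)


def channel_shuffle(x: np.ndarray, groups: int) -> np.ndarray:
    """Reshape-to-(g, d/g), transpose, flatten permutation along axis 1."""
    n, d = x.shape
    if d % groups:
        raise ValueError(f"feature dim {d} not divisible by groups={groups}")
    return x.reshape(n, groups, d // groups).transpose(0, 2, 1).reshape(n, d)


class ChannelShuffle(Module):
    def __init__(self, groups: int):
        super().__init__()
        self.groups = groups

    def forward(self, x):
        self._d = x.shape[1]
        return channel_shuffle(x, self.groups)

    def backward(self, grad):
        # inverse permutation = shuffle with d/g groups
        return channel_shuffle(grad, self._d // self.groups)


# ---------------------------------------------------------------------------
# Convolutions
# ---------------------------------------------------------------------------

class Conv1d(Module):
    def __init__(self, in_ch, out_ch, kernel_size, stride=1, padding=0,
                 bias: bool = False):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.stride, self.padding = kernel_size, stride, padding
        self.weight = Parameter(
            _kaiming((out_ch, in_ch, kernel_size), in_ch * kernel_size))
        self.bias = Parameter(np.zeros(out_ch, np.float32)) if bias else None
        self.last_out_len = None

    def forward(self, x):
        n, c, L = x.shape
        k, s, p = self.k, self.stride, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p))) if p else x
        Lo = (L + 2 * p - k) // s + 1
        patches = np.empty((n, c, k, Lo), x.dtype)
        for i in range(k):
            patches[:, :, i] = xp[:, :, i:i + s * Lo:s]
        self._patches, self._in_shape = patches, x.shape
        w2 = self.weight.value.reshape(self.out_ch, c * k)
        y = np.matmul(w2, patches.reshape(n, c * k, Lo))
        if self.bias is not None:
            y = y + self.bias.value[:, None]
        self.last_out_len = Lo
        return y

    def backward(self, grad):
        n, c, L = self._in_shape
        k, s, p = self.k, self.stride, self.padding
        Lo = grad.shape[-1]
        pat2 = self._patches.reshape(n, c * k, Lo)
        self.weight.grad += np.matmul(
            grad, pat2.transpose(0, 2, 1)).sum(0).reshape(self.weight.shape)
        if self.bias is not None:
            self.bias.grad += grad.sum((0, 2))
        w2 = self.weight.value.reshape(self.out_ch, c * k)
        gpat = np.matmul(w2.T, grad).reshape(n, c, k, Lo)
        gxp = np.zeros((n, c, L + 2 * p), grad.dtype)
        for i in range(k):
            gxp[:, :, i:i + s * Lo:s] += gpat[:, :, i]
        return gxp[:, :, p:p + L] if p else gxp


class Conv2d(Module):
    """2-D convolution supporting dense (groups=1) and depthwise layouts."""

    def __init__(self, in_ch, out_ch, kernel_size, stride=1, padding=0,
                 groups=1, bias: bool = False):
        super().__init__()
        if groups not in (1, in_ch):
            raise NotImplementedError("only groups=1 or depthwise supported")
        if groups == in_ch and out_ch != in_ch:
            raise NotImplementedError("depthwise requires out_ch == in_ch")
        self.in_ch, self.out_ch, self.groups = in_ch, out_ch, groups
        self.k, self.stride, self.padding = kernel_size, stride, padding
        k = kernel_size
        if groups == 1:
            self.weight = Parameter(_kaiming((out_ch, in_ch, k, k), in_ch * k * k))
        else:
            self.weight = Parameter(_kaiming((out_ch, 1, k, k), k * k))
        self.bias = Parameter(np.zeros(out_ch, np.float32)) if bias else None
        self.last_out_hw = None

    def forward(self, x):
        n, c, H, W = x.shape
        k, s, p = self.k, self.stride, self.padding
        self._in_shape = x.shape
        if k == 1 and s == 1 and p == 0 and self.groups == 1:
            # pointwise conv is a plain channel-mixing matmul
            self._x1 = x
            w2 = self.weight.value.reshape(self.out_ch, c)
            y = np.matmul(w2, x.reshape(n, c, H * W)).reshape(n, self.out_ch, H, W)
            Ho, Wo = H, W
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
            Ho = (H + 2 * p - k) // s + 1
            Wo = (W + 2 * p - k) // s + 1
            if self.groups == 1:
                patches = np.empty((n, c, k, k, Ho, Wo), x.dtype)
                for i in range(k):
                    for j in range(k):
                        patches[:, :, i, j] = xp[:, :, i:i + s * Ho:s,
                                                 j:j + s * Wo:s]
                self._patches = patches
                w2 = self.weight.value.reshape(self.out_ch, c * k * k)
                y = np.matmul(w2, patches.reshape(n, c * k * k, Ho * Wo))
                y = y.reshape(n, self.out_ch, Ho, Wo)
            else:
                # depthwise: accumulate per-tap products, no patch buffer
                self._xp = xp
                w = self.weight.value
                y = np.zeros((n, c, Ho, Wo), x.dtype)
                for i in range(k):
                    for j in range(k):
                        y += xp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] \
                            * w[None, :, 0, i, j, None, None]
        if self.bias is not None:
            y = y + self.bias.value[None, :, None, None]
        self.last_out_hw = (Ho, Wo)
        return y

    def backward(self, grad):
        n, c, H, W = self._in_shape
        k, s, p = self.k, self.stride, self.padding
        Ho, Wo = grad.shape[-2:]
        if self.bias is not None:
            self.bias.grad += grad.sum((0, 2, 3))
        if k == 1 and s == 1 and p == 0 and self.groups == 1:
            g2 = grad.reshape(n, self.out_ch, Ho * Wo)
            x2 = self._x1.reshape(n, c, Ho * Wo)
            self.weight.grad += np.matmul(
                g2, x2.transpose(0, 2, 1)).sum(0).reshape(self.weight.shape)
            w2 = self.weight.value.reshape(self.out_ch, c)
            return np.matmul(w2.T, g2).reshape(n, c, H, W)
        if self.groups == 1:
            g2 = grad.reshape(n, self.out_ch, Ho * Wo)
            pat2 = self._patches.reshape(n, c * k * k, Ho * Wo)
            self.weight.grad += np.matmul(
                g2, pat2.transpose(0, 2, 1)).sum(0).reshape(self.weight.shape)
            w2 = self.weight.value.reshape(self.out_ch, c * k * k)
            gpat = np.matmul(w2.T, g2).reshape(n, c, k, k, Ho, Wo)
            gxp = np.zeros((n, c, H + 2 * p, W + 2 * p), grad.dtype)
            for i in range(k):
                for j in range(k):
                    gxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += gpat[:, :, i, j]
            return gxp[:, :, p:p + H, p:p + W] if p else gxp
        # depthwise
        xp, w = self._xp, self.weight.value
        gxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                sl = xp[:, :, i:i + s * Ho:s, j:j + s * Wo:s]
                self.weight.grad[:, 0, i, j] += (grad * sl).sum((0, 2, 3))
                gxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += \
                    grad * w[None, :, 0, i, j, None, None]
        return gxp[:, :, p:p + H, p:p + W] if p else gxp


# ---------------------------------------------------------------------------
# Normalisation, activations, pooling, dropout
# ---------------------------------------------------------------------------

class BatchNorm(Module):
    """Batch normalisation over all axes except axis 1 (channels).

    Works on (N, C), (N, C, L) and (N, C, H, W) inputs.
    """

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features, self.eps, self.momentum = num_features, eps, momentum
        self.weight = Parameter(np.ones(num_features, np.float32))
        self.bias = Parameter(np.zeros(num_features, np.float32))
        self.running_mean = np.zeros(num_features, np.float32)
        self.running_var = np.ones(num_features, np.float32)
        object.__setattr__(self, "_buffers", ("running_mean", "running_var"))

    def _bshape(self, ndim):
        return (1, -1) + (1,) * (ndim - 2)

    def forward(self, x):
        axes = (0,) + tuple(range(2, x.ndim))
        shape = self._bshape(x.ndim)
        if self.training:
            mean = x.mean(axes)
            var = x.var(axes)
            m = np.prod([x.shape[a] for a in axes])
            self.running_mean += self.momentum * (mean - self.running_mean)
            unbiased = var * m / max(m - 1, 1)
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * invstd.reshape(shape)
        self._xhat, self._invstd, self._axes = xhat, invstd, axes
        return self.weight.value.reshape(shape) * xhat + self.bias.value.reshape(shape)

    def backward(self, grad):
        shape = self._bshape(grad.ndim)
        axes = self._axes
        xhat, invstd = self._xhat, self._invstd
        self.weight.grad += (grad * xhat).sum(axes)
        self.bias.grad += grad.sum(axes)
        gxhat = grad * self.weight.value.reshape(shape)
        if not self.training:
            return gxhat * invstd.reshape(shape)
        m = np.prod([grad.shape[a] for a in axes])
        gsum = gxhat.sum(axes, keepdims=True)
        gxsum = (gxhat * xhat).sum(axes, keepdims=True)
        return (gxhat - gsum / m - xhat * gxsum / m) * invstd.reshape(shape)


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Sigmoid(Module):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Hardswish(Module):
    """x * relu6(x + 3) / 6 (MobileNetV3's cheap swish)."""

    def forward(self, x):
        self._x = x
        return x * np.clip(x + 3.0, 0.0, 6.0) / 6.0

    def backward(self, grad):
        x = self._x
        d = np.where(x <= -3.0, 0.0, np.where(x >= 3.0, 1.0, (2.0 * x + 3.0) / 6.0))
        return grad * d.astype(grad.dtype)


class Hardsigmoid(Module):
    def forward(self, x):
        self._x = x
        return np.clip(x + 3.0, 0.0, 6.0) / 6.0

    def backward(self, grad):
        x = self._x
        return grad * ((x > -3.0) & (x < 3.0)).astype(grad.dtype) / 6.0


class MaxPool1d(Module):
    """Non-overlapping max pooling with floor semantics (trailing remainder
    dropped), so 2151 -> 1075 at k=2."""

    def __init__(self, k: int):
        super().__init__()
        self.k = k

    def forward(self, x):
        n, c, L = x.shape
        Lo = L // self.k
        xr = x[:, :, :Lo * self.k].reshape(n, c, Lo, self.k)
        self._idx, self._in_len = xr.argmax(-1), L
        return xr.max(-1)

    def backward(self, grad):
        n, c, Lo = grad.shape
        gx = np.zeros((n, c, Lo, self.k), grad.dtype)
        np.put_along_axis(gx, self._idx[..., None], grad[..., None], axis=-1)
        gx = gx.reshape(n, c, Lo * self.k)
        if Lo * self.k < self._in_len:
            gx = np.pad(gx, ((0, 0), (0, 0), (0, self._in_len - Lo * self.k)))
        return gx


class GlobalAvgPool2d(Module):
    """Adaptive average pooling to 1x1, returned as (N, C)."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean((2, 3))

    def backward(self, grad):
        n, c, H, W = self._shape
        return np.broadcast_to(grad[:, :, None, None] / (H * W),
                               self._shape).astype(grad.dtype)


class Flatten(Module):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dropout(Module):
    def __init__(self, p: float):
        super().__init__()
        self.p = p

    def forward(self, x):
        if self.training and self.p > 0:
            keep = 1.0 - self.p
            self._mask = (_GLOBAL_RNG.random(x.shape) < keep) / keep
            return x * self._mask.astype(x.dtype)
        self._mask = None
        return x

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask.astype(grad.dtype)


# ---------------------------------------------------------------------------
# Loss and optimiser
# ---------------------------------------------------------------------------

def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    z = logits - logits.max(1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(probs[np.arange(n), labels] + 1e-12).mean()
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Adam:
    """Adam with parameter groups and (coupled) L2 weight decay."""

    def __init__(self, groups, weight_decay: float = 0.0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        # groups: list of {"params": [...], "lr": float, "name": str}
        self.groups = groups
        self.weight_decay = weight_decay
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.t = 0
        self._state = {}

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for grp in self.groups:
            lr = grp["lr"]
            for p in grp["params"]:
                if not p.trainable:
                    continue
                g = p.grad
                if self.weight_decay:
                    g = g + self.weight_decay * p.value
                st = self._state.get(id(p))
                if st is None:
                    st = [np.zeros_like(p.value), np.zeros_like(p.value)]
                    self._state[id(p)] = st
                m, v = st
                m += (1 - b1) * (g - m)
                v += (1 - b2) * (g * g - v)
                p.value -= lr * (m / c1) / (np.sqrt(v / c2) + self.eps)

    def zero_grad(self):
        for grp in self.groups:
            for p in grp["params"]:
                p.grad[...] = 0
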