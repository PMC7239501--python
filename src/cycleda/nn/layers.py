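"""Neural-network layers over the autodiff tensor.

Convolutions use im2col/col2im with BLAS matmuls, which is the fastest pure
numpy route at the 32-256 px image sizes this package targets. Batch
normalization keeps running statistics and honours a per-module train/eval
mode, which the trainer uses to confine statistic updates to the phase that
owns a module.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "Parameter", "Module", "Conv2d", "ConvTranspose2d", "BatchNorm2d",
    "Linear", "Sequential", "ReLU", "LeakyReLU", "Tanh", "Sigmoid", "Flatten",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal container: named parameters, named buffers, train/eval mode."""

    def __init__(self):
        self.training = True

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> dict:
        """Flat ``name -> Parameter`` map, names unique within the module."""
        out = {}

        def walk(obj, prefix):
            for k, v in obj.__dict__.items():
                if isinstance(v, Parameter):
                    out[f"{prefix}{k}"] = v
                elif isinstance(v, Module):
                    walk(v, f"{prefix}{k}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{prefix}{k}.{i}.")

        walk(self, "")
        return out

    def buffers(self) -> dict:
        """Non-trainable state (batch-norm running statistics)."""
        out = {}

        def walk(obj, prefix):
            for k, v in obj.__dict__.items():
                if isinstance(v, Module):
                    walk(v, f"{prefix}{k}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{prefix}{k}.{i}.")
            if isinstance(obj, BatchNorm2d):
                out[f"{prefix}running_mean"] = obj.running_mean
                out[f"{prefix}running_var"] = obj.running_var

        walk(self, "")
        return out

    def state_dict(self) -> dict:
        d = {k: v.data.copy() for k, v in self.parameters().items()}
        d.update({f"buffer:{k}": v.copy() for k, v in self.buffers().items()})
        return d

    def load_state_dict(self, d: dict):
        params = self.parameters()
        bufs = self.buffers()
        for k, v in d.items():
            if k.startswith("buffer:"):
                bufs[k[len("buffer:"):]][...] = v
            else:
                params[k].data[...] = v

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters().values():
            p.grad = None


# ---------------------------------------------------------------------------
# im2col helpers
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N,C,H,W) -> (N, C*k*k, Ho*Wo) patch matrix."""
    n, c, h, w = x.shape
    if pad:
        xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=x.dtype)
        xp[:, :, pad:pad + h, pad:pad + w] = x
        x = xp
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, (n, c, k, k, ho, wo), (s0, s1, s2, s3, s2 * stride, s3 * stride))
    return np.ascontiguousarray(view).reshape(n, c * k * k, ho * wo), ho, wo


def _col2im(cols: np.ndarray, out_shape, k: int, stride: int, pad: int):
    """Adjoint of _im2col: scatter-add patches back into an image."""
    n, c, h, w = out_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    cols = cols.reshape(n, c, k, k, ho, wo)
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(k):
        i_max = i + stride * ho
        for j in range(k):
            j_max = j + stride * wo
            out[:, :, i:i_max:stride, j:j_max:stride] += cols[:, :, i, j]
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return out


def _fan_init(rng: np.random.Generator, shape, std: float = 0.02):
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, pad=0, *, rng):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.weight = Parameter(_fan_init(rng, (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        k, s, p = self.kernel, self.stride, self.pad
        xd, wd = x.data, self.weight.data
        n = xd.shape[0]
        cols, ho, wo = _im2col(xd, k, s, p)
        wmat = wd.reshape(self.out_ch, -1)
        out = np.matmul(wmat, cols)                 # (N, Cout, L)
        out = out.reshape(n, self.out_ch, ho, wo) + self.bias.data[None, :, None, None]

        def backward(g):
            gmat = np.ascontiguousarray(g).reshape(n, self.out_ch, ho * wo)
            dw = np.tensordot(gmat, cols, axes=([0, 2], [0, 2]))
            dw = dw.reshape(wd.shape)
            db = gmat.sum(axis=(0, 2))
            dcols = np.matmul(wmat.T, gmat)
            dx = _col2im(dcols, xd.shape, k, s, p)
            return dx, dw, db

        return Tensor._result(out, (x, self.weight, self.bias), backward)


class ConvTranspose2d(Module):
    """Stride-s transposed convolution; the adjoint of Conv2d's forward map."""

    def __init__(self, in_ch, out_ch, kernel, stride=1, pad=0, *, rng):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.weight = Parameter(_fan_init(rng, (in_ch, out_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        k, s, p = self.kernel, self.stride, self.pad
        xd, wd = x.data, self.weight.data
        n, c, h, w = xd.shape
        ho = (h - 1) * s - 2 * p + k
        wo = (w - 1) * s - 2 * p + k
        wmat = wd.reshape(self.in_ch, -1)          # (Cin, Cout*k*k)
        xf = xd.reshape(n, c, h * w)
        cols = np.matmul(wmat.T, xf)               # (N, Cout*k*k, H*W)
        out = _col2im(cols, (n, self.out_ch, ho, wo), k, s, p)
        out = out + self.bias.data[None, :, None, None]

        def backward(g):
            dcols, _, _ = _im2col(g, k, s, p)       # (N, Cout*k*k, h*w)
            dxf = np.matmul(wmat, dcols)
            dw = np.tensordot(xf, dcols, axes=([0, 2], [0, 2]))
            db = g.sum(axis=(0, 2, 3))
            return dxf.reshape(xd.shape), dw.reshape(wd.shape), db

        return Tensor._result(out, (x, self.weight, self.bias), backward)


class BatchNorm2d(Module):
    """Batch norm with a third mode used during alternating GAN training:
    with ``frozen_stats`` set while training, the current batch statistics
    normalize the activations but the running statistics are NOT updated —
    so modules not owned by the current phase contribute well-scaled
    gradients without accumulating any state."""

    def __init__(self, ch, momentum=0.1, eps=1e-5):
        super().__init__()
        self.ch, self.momentum, self.eps = ch, momentum, eps
        self.frozen_stats = False
        self.gamma = Parameter(np.ones(ch, dtype=np.float32))
        self.beta = Parameter(np.zeros(ch, dtype=np.float32))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        xd = x.data
        gd, bd = self.gamma.data, self.beta.data
        if self.training:
            mu = xd.mean(axis=(0, 2, 3))
            var = xd.var(axis=(0, 2, 3))
            if not self.frozen_stats:
                self.running_mean += self.momentum * (mu - self.running_mean)
                self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (xd - mu[None, :, None, None]) * inv[None, :, None, None]
        out = gd[None, :, None, None] * xhat + bd[None, :, None, None]
        training = self.training

        def backward(g):
            dgamma = (g * xhat).sum(axis=(0, 2, 3))
            dbeta = g.sum(axis=(0, 2, 3))
            gi = (gd * inv)[None, :, None, None]
            if training:
                m = xd.shape[0] * xd.shape[2] * xd.shape[3]
                mean_g = g.mean(axis=(0, 2, 3))[None, :, None, None]
                mean_gx = (g * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
                dx = gi * (g - mean_g - xhat * mean_gx)
                del m
            else:
                dx = gi * g
            return dx, dgamma, dbeta

        return Tensor._result(out, (x, self.gamma, self.beta), backward)


class Linear(Module):
    def __init__(self, in_f, out_f, *, rng):
        super().__init__()
        self.weight = Parameter(_fan_init(rng, (in_f, out_f),
                                          std=1.0 / np.sqrt(in_f)))
        self.bias = Parameter(np.zeros(out_f, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope=0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return x.leaky_relu(self.slope)


class Tanh(Module):
    def forward(self, x):
        return x.tanh()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class Flatten(Module):
    def forward(self, x):
        return x.reshape(x.shape[0], -1)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x
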