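"""Minimal trainable CNN layers on numpy, with explicit backprop.

Each :class:`Module` caches what its last forward pass needs and exposes
``backward(grad_out) -> grad_in`` that accumulates parameter gradients.
The graph is static — composite modules call their children in a fixed
order and reverse it in ``backward`` — which is all a feed-forward
segmentation network needs.  Convolutions are im2col + BLAS matmuls with
stride/padding/dilation; the bilinear upsampler is expressed as two
separable interpolation matrices so its backward is just the transpose.

All tensors are NCHW ``float`` arrays; the float dtype is configurable
(float32 for training speed, float64 for gradient checking).
"""

from __future__ import annotations

import numpy as np

_DEFAULT_DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    """Set the dtype used for newly created parameters (float32/float64)."""
    global _DEFAULT_DTYPE
    _DEFAULT_DTYPE = np.dtype(dtype).type


def get_default_dtype():
    return _DEFAULT_DTYPE


class Parameter:
    __slots__ = ("data", "grad")

    def __init__(self, data):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def __call__(self, x):
        return self.forward(x)

    def forward(self, x):            # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):        # pragma: no cover - abstract
        raise NotImplementedError

    # -- traversal ---------------------------------------------------------
    def named_children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix=""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield f"{prefix}{name}", value
        for cname, child in self.named_children():
            yield from child.named_parameters(prefix=f"{prefix}{cname}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def train(self, flag: bool = True):
        self.training = flag
        for _, child in self.named_children():
            child.train(flag)
        return self

    def eval(self):
        return self.train(False)

    # -- persistence -------------------------------------------------------
    def _named_buffers(self, prefix=""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray) and name.startswith("running_"):
                yield f"{prefix}{name}", value
        for cname, child in self.named_children():
            yield from child._named_buffers(prefix=f"{prefix}{cname}.")

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self._named_buffers()})
        return state

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        buffers = dict(self._named_buffers())
        for name, value in state.items():
            if name in params:
                params[name].data[...] = value
            elif name in buffers:
                buffers[name][...] = value
            else:
                raise KeyError(f"unexpected state entry {name!r}")
        return self


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def _he_init(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    """2-D convolution (cross-correlation) with stride/padding/dilation."""

    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0,
                 dilation=1, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k = int(kernel)
        self.stride, self.padding, self.dilation = stride, padding, dilation
        fan_in = in_ch * self.k * self.k
        self.weight = Parameter(_he_init(rng, (out_ch, in_ch, self.k, self.k), fan_in))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self._cache = None

    def _out_hw(self, h, w):
        k_eff = self.dilation * (self.k - 1) + 1
        oh = (h + 2 * self.padding - k_eff) // self.stride + 1
        ow = (w + 2 * self.padding - k_eff) // self.stride + 1
        if oh < 1 or ow < 1:
            raise ValueError(f"input {h}x{w} too small for kernel {self.k} "
                             f"(dilation {self.dilation}, padding {self.padding})")
        return oh, ow

    def _im2col(self, xp, oh, ow):
        n, c, _, _ = xp.shape
        cols = np.empty((n, c, self.k, self.k, oh, ow), dtype=xp.dtype)
        for a in range(self.k):
            ia = a * self.dilation
            for b in range(self.k):
                jb = b * self.dilation
                cols[:, :, a, b] = xp[:, :, ia:ia + self.stride * oh:self.stride,
                                      jb:jb + self.stride * ow:self.stride]
        return cols.reshape(n, c * self.k * self.k, oh * ow)

    def forward(self, x):
        if x.ndim != 4 or x.shape[1] != self.in_ch:
            raise ValueError(f"expected (N,{self.in_ch},H,W), got {x.shape}")
        n, _, h, w = x.shape
        oh, ow = self._out_hw(h, w)
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = self._im2col(xp, oh, ow)
        w2 = self.weight.data.reshape(self.out_ch, -1)
        y = np.matmul(w2, cols)
        if self.bias is not None:
            y += self.bias.data[:, None]
        self._cache = (x.shape, xp.shape, cols, oh, ow)
        return y.reshape(n, self.out_ch, oh, ow)

    def backward(self, grad):
        x_shape, xp_shape, cols, oh, ow = self._cache
        n = x_shape[0]
        g2 = grad.reshape(n, self.out_ch, oh * ow)
        self.weight.grad += np.matmul(g2, cols.transpose(0, 2, 1)).sum(0) \
            .reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += g2.sum(axis=(0, 2))
        w2 = self.weight.data.reshape(self.out_ch, -1)
        dcols = np.matmul(w2.T, g2).reshape(n, self.in_ch, self.k, self.k, oh, ow)
        dxp = np.zeros(xp_shape, dtype=grad.dtype)
        for a in range(self.k):
            ia = a * self.dilation
            for b in range(self.k):
                jb = b * self.dilation
                dxp[:, :, ia:ia + self.stride * oh:self.stride,
                    jb:jb + self.stride * ow:self.stride] += dcols[:, :, a, b]
        p = self.padding
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d(Module):
    def __init__(self, ch, eps=1e-5, momentum=0.1):
        super().__init__()
        self.ch, self.eps, self.momentum = ch, eps, momentum
        self.gamma = Parameter(np.ones(ch))
        self.beta = Parameter(np.zeros(ch))
        self.running_mean = np.zeros(ch, dtype=_DEFAULT_DTYPE)
        self.running_var = np.ones(ch, dtype=_DEFAULT_DTYPE)
        self._cache = None

    def forward(self, x):
        if self.training:
            axes = (0, 2, 3)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            cnt = x.shape[0] * x.shape[2] * x.shape[3]
            self.running_mean += self.momentum * (mean - self.running_mean)
            unbiased = var * cnt / max(cnt - 1, 1)
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std)
        return self.gamma.data[None, :, None, None] * xhat \
            + self.beta.data[None, :, None, None]

    def backward(self, grad):
        xhat, inv_std = self._cache
        axes = (0, 2, 3)
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        gg = grad * self.gamma.data[None, :, None, None]
        if not self.training:
            return gg * inv_std[None, :, None, None]
        cnt = grad.shape[0] * grad.shape[2] * grad.shape[3]
        sum_gg = gg.sum(axis=axes)[None, :, None, None]
        sum_gg_xhat = (gg * xhat).sum(axis=axes)[None, :, None, None]
        return inv_std[None, :, None, None] / cnt * (
            cnt * gg - sum_gg - xhat * sum_gg_xhat)


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


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _interp_matrix(n_in: int, scale: int, dtype):
    """Row-interpolation matrix for bilinear upsampling (half-pixel centers)."""
    n_out = n_in * scale
    a = np.zeros((n_out, n_in), dtype=dtype)
    for o in range(n_out):
        src = (o + 0.5) / scale - 0.5
        i0 = int(np.floor(src))
        t = src - i0
        i0c = min(max(i0, 0), n_in - 1)
        i1c = min(max(i0 + 1, 0), n_in - 1)
        a[o, i0c] += 1.0 - t
        a[o, i1c] += t
    return a


class BilinearUpsample(Module):
    """Upsample H and W by an integer factor using bilinear interpolation."""

    def __init__(self, scale: int):
        super().__init__()
        self.scale = int(scale)
        self._mats = {}

    def _mat(self, n, dtype):
        key = (n, np.dtype(dtype).name)
        if key not in self._mats:
            self._mats[key] = _interp_matrix(n, self.scale, dtype)
        return self._mats[key]

    def forward(self, x):
        _, _, h, w = x.shape
        ah, aw = self._mat(h, x.dtype), self._mat(w, x.dtype)
        self._hw = (h, w)
        t = np.einsum("oh,nchw->ncow", ah, x, optimize=True)
        return np.einsum("pw,ncow->ncop", aw, t, optimize=True)

    def backward(self, grad):
        h, w = self._hw
        ah, aw = self._mat(h, grad.dtype), self._mat(w, grad.dtype)
        t = np.einsum("pw,ncop->ncow", aw, grad, optimize=True)
        return np.einsum("oh,ncow->nchw", ah, t, optimize=True)


class SpatialAttention(Module):
    """CBAM-style spatial gate: [avg, max] over channels -> 7x7 conv -> sigmoid.

    The attention map lies in (0, 1) and multiplies the input, so the
    output never exceeds the input in magnitude.
    """

    def __init__(self, kernel: int = 7, rng=None):
        super().__init__()
        self.conv = Conv2d(2, 1, kernel, padding=kernel // 2, bias=True, rng=rng)
        self._cache = None

    def attention_map(self, x):
        avg = x.mean(axis=1, keepdims=True)
        argmax = x.argmax(axis=1)
        mx = np.take_along_axis(x, argmax[:, None], axis=1)
        z = self.conv(np.concatenate([avg, mx], axis=1))
        s = 1.0 / (1.0 + np.exp(-z))
        return s, argmax

    def forward(self, x):
        s, argmax = self.attention_map(x)
        self._cache = (x, s, argmax)
        return x * s

    def backward(self, grad):
        x, s, argmax = self._cache
        n, c, h, w = x.shape
        dx = grad * s
        ds = (grad * x).sum(axis=1, keepdims=True)
        dz = ds * s * (1.0 - s)
        dcat = self.conv.backward(dz)
        dx += dcat[:, 0:1] / c                      # mean branch
        dmax = np.zeros_like(x)
        np.put_along_axis(dmax, argmax[:, None], dcat[:, 1:2], axis=1)
        return dx + dmax


class Add(Module):
    """Elementwise sum of two cached inputs (used by residual blocks)."""

    def forward(self, a, b):
        return a + b

    def backward(self, grad):
        return grad, grad


class BasicBlock(Module):
    """ResNet basic block: two 3x3 convs with BN, identity/projection skip."""

    def __init__(self, ch, stride=1, rng=None):
        super().__init__()
        self.conv1 = Conv2d(ch, ch, 3, stride=stride, padding=1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(ch)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(ch, ch, 3, stride=1, padding=1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(ch)
        self.relu_out = ReLU()
        if stride != 1:
            self.down_conv = Conv2d(ch, ch, 1, stride=stride, bias=False, rng=rng)
            self.down_bn = BatchNorm2d(ch)
        else:
            self.down_conv = None

    def forward(self, x):
        out = self.relu1(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        skip = self.down_bn(self.down_conv(x)) if self.down_conv else x
        return self.relu_out(out + skip)

    def backward(self, grad):
        g = self.relu_out.backward(grad)
        g_main = self.bn2.backward(g)
        g_main = self.conv2.backward(g_main)
        g_main = self.relu1.backward(g_main)
        g_main = self.bn1.backward(g_main)
        g_main = self.conv1.backward(g_main)
        if self.down_conv:
            g_skip = self.down_bn.backward(g)
            g_skip = self.down_conv.backward(g_skip)
        else:
            g_skip = g
        return g_main + g_skip
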