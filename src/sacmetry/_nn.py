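"""Minimal reverse-mode autograd engine and CNN layers on numpy.

Implements exactly the primitives the segmentation architectures in
:mod:`sacmetry.models` need: 2D convolution (stride/padding/dilation),
batch normalization, ReLU/sigmoid, max pooling, nearest and bilinear
upsampling, channel concatenation, dropout, and differentiable Dice /
Jaccard / BCE losses, plus an Adam optimizer.  Convolutions are im2col
gathers feeding BLAS matmuls; their input gradients are scatter-adds via
``np.bincount``.

The engine is deliberately small: a :class:`Tensor` holds an ndarray, its
gradient, and a backward closure; ``Tensor.backward`` runs the tape in
reverse topological order.  Shapes follow the (N, C, H, W) convention.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "Module", "Adam"]


# ---------------------------------------------------------------------------
# tensor + tape
# ---------------------------------------------------------------------------

class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward: Callable | None = None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.ascontiguousarray(data), requires_grad=True)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    g = g.astype(t.data.dtype, copy=False)
    if t.grad is None:
        t.grad = g.copy() if g.base is not None else g
    else:
        t.grad += g


# ---------------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Parameter, b: Parameter | None = None,
           stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    N, C, H, W = x.data.shape
    O, _, kh, kw = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Hp, Wp = xp.shape[2:]
    OH = (Hp - (kh - 1) * dilation - 1) // stride + 1
    OW = (Wp - (kw - 1) * dilation - 1) // stride + 1

    ri = (np.arange(kh) * dilation)[:, None] + (np.arange(OH) * stride)[None, :]
    ci = (np.arange(kw) * dilation)[:, None] + (np.arange(OW) * stride)[None, :]
    cols = xp[:, :, ri[:, None, :, None], ci[None, :, None, :]]
    cols = np.ascontiguousarray(cols).reshape(N, C * kh * kw, OH * OW)

    wmat = w.data.reshape(O, -1)
    out = np.matmul(wmat, cols).reshape(N, O, OH, OW)
    if b is not None:
        out = out + b.data.reshape(1, O, 1, 1)

    parents = (x, w) if b is None else (x, w, b)
    result = Tensor(out, parents=parents)

    def backward(grad: np.ndarray) -> None:
        go = grad.reshape(N, O, OH * OW)
        if w.requires_grad:
            dw = np.matmul(go, cols.transpose(0, 2, 1)).sum(axis=0)
            _accum(w, dw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            _accum(b, go.sum(axis=(0, 2)))
        if x.requires_grad:
            dcols = np.matmul(wmat.T, go)  # (N, C*kh*kw, L)
            base = np.arange(C)[:, None, None, None, None] * (Hp * Wp)
            idx = (base + ri[:, None, :, None] * Wp + ci[None, :, None, :])
            idx = np.broadcast_to(idx, (C, kh, kw, OH, OW)).ravel()
            gx = np.empty_like(xp)
            size = C * Hp * Wp
            for n in range(N):
                gx[n] = np.bincount(idx, weights=dcols[n].ravel(),
                                    minlength=size).reshape(C, Hp, Wp)
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding]
            _accum(x, gx)

    result._backward = backward
    return result


def batchnorm2d(x: Tensor, gamma: Parameter, beta: Parameter,
                running_mean: np.ndarray, running_var: np.ndarray,
                training: bool, momentum: float = 0.1,
                eps: float = 1e-5) -> Tensor:
    xd = x.data
    if training:
        mu = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mu
        running_var *= (1.0 - momentum)
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu.reshape(1, -1, 1, 1)) * inv_std.reshape(1, -1, 1, 1)
    out = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)
    result = Tensor(out.astype(xd.dtype, copy=False), parents=(x, gamma, beta))

    def backward(grad: np.ndarray) -> None:
        if gamma.requires_grad:
            _accum(gamma, (grad * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            _accum(beta, grad.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            g = gamma.data.reshape(1, -1, 1, 1) * inv_std.reshape(1, -1, 1, 1)
            if training:
                m = grad.shape[0] * grad.shape[2] * grad.shape[3]
                mean_g = grad.mean(axis=(0, 2, 3), keepdims=True)
                mean_gx = (grad * xhat).mean(axis=(0, 2, 3), keepdims=True)
                _accum(x, g * (grad - mean_g - xhat * mean_gx))
                del m
            else:
                _accum(x, g * grad)

    result._backward = backward
    return result


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    result = Tensor(np.where(mask, x.data, 0), parents=(x,))
    result._backward = lambda grad: _accum(x, grad * mask)
    return result


def sigmoid(x: Tensor) -> Tensor:
    from scipy.special import expit  # numerically stable logistic

    s = expit(x.data)
    result = Tensor(s.astype(x.data.dtype, copy=False), parents=(x,))
    result._backward = lambda grad: _accum(x, grad * s * (1.0 - s))
    return result


def add(a: Tensor, b: Tensor) -> Tensor:
    result = Tensor(a.data + b.data, parents=(a, b))

    def backward(grad):
        _accum(a, grad)
        _accum(b, grad)

    result._backward = backward
    return result


def sub(a: Tensor, b: Tensor) -> Tensor:
    result = Tensor(a.data - b.data, parents=(a, b))

    def backward(grad):
        _accum(a, grad)
        _accum(b, -grad)

    result._backward = backward
    return result


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    result = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                    parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * grad.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, grad[tuple(sl)])

    result._backward = backward
    return result


def slice_channels(x: Tensor, lo: int, hi: int) -> Tensor:
    result = Tensor(x.data[:, lo:hi], parents=(x,))

    def backward(grad):
        gx = np.zeros_like(x.data)
        gx[:, lo:hi] = grad
        _accum(x, gx)

    result._backward = backward
    return result


def maxpool2d(x: Tensor, kernel: int = 3, stride: int = 2,
              padding: int = 1) -> Tensor:
    N, C, H, W = x.data.shape
    neg = np.finfo(x.data.dtype).min
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=neg)
    Hp, Wp = xp.shape[2:]
    OH = (Hp - kernel) // stride + 1
    OW = (Wp - kernel) // stride + 1
    ri = np.arange(kernel)[:, None] + (np.arange(OH) * stride)[None, :]
    ci = np.arange(kernel)[:, None] + (np.arange(OW) * stride)[None, :]
    win = xp[:, :, ri[:, None, :, None], ci[None, :, None, :]]
    win = win.reshape(N, C, kernel * kernel, OH, OW)
    arg = win.argmax(axis=2)
    out = np.take_along_axis(win, arg[:, :, None], axis=2)[:, :, 0]
    result = Tensor(out, parents=(x,))

    def backward(grad):
        base = np.arange(C)[:, None, None] * (Hp * Wp)
        kr, kc = np.divmod(arg, kernel)  # (N,C,OH,OW) offsets within window
        # absolute row/col of the argmax for each output position
        rows = kr + (np.arange(OH) * stride)[None, None, :, None]
        colsa = kc + (np.arange(OW) * stride)[None, None, None, :]
        idx = base[None] + rows * Wp + colsa  # (N,C,OH,OW)
        gx = np.empty((N, C, Hp, Wp), dtype=x.data.dtype)
        size = C * Hp * Wp
        for n in range(N):
            gx[n] = np.bincount(idx[n].ravel(), weights=grad[n].ravel(),
                                minlength=size).reshape(C, Hp, Wp)
        if padding:
            gx = gx[:, :, padding:-padding, padding:-padding]
        _accum(x, gx)

    result._backward = backward
    return result


def upsample_nearest2(x: Tensor) -> Tensor:
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)
    result = Tensor(out, parents=(x,))

    def backward(grad):
        N, C, H2, W2 = grad.shape
        _accum(x, grad.reshape(N, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5)))

    result._backward = backward
    return result


def broadcast_spatial(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Expand a (N, C, 1, 1) map to (N, C, H, W) (upsampling a pooled map)."""
    H, W = size
    result = Tensor(np.broadcast_to(x.data, x.data.shape[:2] + (H, W)).copy(),
                    parents=(x,))
    result._backward = lambda grad: _accum(x, grad.sum(axis=(2, 3), keepdims=True))
    return result


def _linear_weights(out_size: int, in_size: int, scale: float):
    # torch-style align_corners=False source coordinates
    src = (np.arange(out_size) + 0.5) / scale - 0.5
    src = np.clip(src, 0, in_size - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, in_size - 1)
    w_hi = src - lo
    return lo, hi, (1.0 - w_hi), w_hi


def upsample_bilinear(x: Tensor, scale: int) -> Tensor:
    N, C, H, W = x.data.shape
    OH, OW = H * scale, W * scale
    r0, r1, wr0, wr1 = _linear_weights(OH, H, scale)
    c0, c1, wc0, wc1 = _linear_weights(OW, W, scale)
    wr0 = wr0.reshape(1, 1, -1, 1).astype(x.data.dtype)
    wr1 = wr1.reshape(1, 1, -1, 1).astype(x.data.dtype)
    wc0 = wc0.reshape(1, 1, 1, -1).astype(x.data.dtype)
    wc1 = wc1.reshape(1, 1, 1, -1).astype(x.data.dtype)
    xr = x.data[:, :, r0, :] * wr0 + x.data[:, :, r1, :] * wr1
    out = xr[:, :, :, c0] * wc0 + xr[:, :, :, c1] * wc1
    result = Tensor(out, parents=(x,))

    def backward(grad):
        gxr = np.zeros((N, C, OH, W), dtype=grad.dtype)
        np.add.at(gxr, (slice(None), slice(None), slice(None), c0), grad * wc0)
        np.add.at(gxr, (slice(None), slice(None), slice(None), c1), grad * wc1)
        gx = np.zeros((N, C, H, W), dtype=grad.dtype)
        np.add.at(gx, (slice(None), slice(None), r0, slice(None)), gxr * wr0)
        np.add.at(gx, (slice(None), slice(None), r1, slice(None)), gxr * wr1)
        _accum(x, gx)

    result._backward = backward
    return result


def global_avg_pool(x: Tensor) -> Tensor:
    N, C, H, W = x.data.shape
    result = Tensor(x.data.mean(axis=(2, 3), keepdims=True), parents=(x,))

    def backward(grad):
        _accum(x, np.broadcast_to(grad / (H * W), x.data.shape))

    result._backward = backward
    return result


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    if not training or p == 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    result = Tensor(x.data * keep, parents=(x,))
    result._backward = lambda grad: _accum(x, grad * keep)
    return result


# ---------------------------------------------------------------------------
# differentiable losses (probability map vs binary target)
# ---------------------------------------------------------------------------

def _per_sample_sums(p: np.ndarray, y: np.ndarray):
    axes = tuple(range(1, p.ndim))
    return (p * y).sum(axis=axes), p.sum(axis=axes), y.sum(axis=axes), axes


def dice_loss_t(p: Tensor, y: np.ndarray, smooth: float = 1.0) -> Tensor:
    """Soft Dice loss, averaged over the batch; gradient in closed form."""
    y = y.astype(p.data.dtype)
    spy, sp, sy, _ = _per_sample_sums(p.data, y)
    num = 2.0 * spy + smooth
    den = sp + sy + smooth
    losses = 1.0 - num / den
    result = Tensor(np.asarray(losses.mean(), dtype=p.data.dtype), parents=(p,))

    def backward(grad):
        n = p.data.shape[0]
        shape = (-1,) + (1,) * (p.data.ndim - 1)
        d = ((num.reshape(shape) - 2.0 * y * den.reshape(shape))
             / den.reshape(shape) ** 2)
        _accum(p, grad * d / n)

    result._backward = backward
    return result


def jaccard_loss_t(p: Tensor, y: np.ndarray, smooth: float = 1.0) -> Tensor:
    """Soft Jaccard loss, averaged over the batch."""
    y = y.astype(p.data.dtype)
    spy, sp, sy, _ = _per_sample_sums(p.data, y)
    inter = spy + smooth
    union = sp + sy - spy + smooth
    result = Tensor(np.asarray((1.0 - inter / union).mean(), dtype=p.data.dtype),
                    parents=(p,))

    def backward(grad):
        n = p.data.shape[0]
        shape = (-1,) + (1,) * (p.data.ndim - 1)
        u = union.reshape(shape)
        i = inter.reshape(shape)
        d = -(y * u - i * (1.0 - y)) / u ** 2
        _accum(p, grad * d / n)

    result._backward = backward
    return result


def bce_loss_t(p: Tensor, y: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Pixel-mean binary cross-entropy with probability clipping."""
    y = y.astype(p.data.dtype)
    pc = np.clip(p.data, eps, 1.0 - eps)
    val = -(y * np.log(pc) + (1.0 - y) * np.log1p(-pc)).mean()
    result = Tensor(np.asarray(val, dtype=p.data.dtype), parents=(p,))

    def backward(grad):
        inside = (p.data > eps) & (p.data < 1.0 - eps)
        d = np.where(inside, (-y / pc + (1.0 - y) / (1.0 - pc)), 0.0)
        _accum(p, grad * d / p.data.size)

    result._backward = backward
    return result


TENSOR_LOSSES = {"dl": dice_loss_t, "jl": jaccard_loss_t, "bcel": bce_loss_t}


# ---------------------------------------------------------------------------
# module system
# ---------------------------------------------------------------------------

class Module:
    def __init__(self):
        self.training = True

    @staticmethod
    def _children(value):
        """Yield (suffix, item) pairs for arbitrarily nested containers."""
        if isinstance(value, (list, tuple)):
            for i, item in enumerate(value):
                for suffix, leaf in Module._children(item):
                    yield (f"{i}.{suffix}" if suffix else str(i)), leaf
        elif isinstance(value, dict):
            for key, item in value.items():
                for suffix, leaf in Module._children(item):
                    yield (f"{key}.{suffix}" if suffix else str(key)), leaf
        elif isinstance(value, (Module, Parameter)):
            yield "", value

    def modules(self):
        yield self
        for value in self.__dict__.values():
            for _, leaf in Module._children(value):
                if isinstance(leaf, Module):
                    yield from leaf.modules()

    def named_parameters(self, prefix: str = ""):
        for name, value in self.__dict__.items():
            path = f"{prefix}{name}"
            for suffix, leaf in Module._children(value):
                full = f"{path}.{suffix}" if suffix else path
                if isinstance(leaf, Parameter):
                    yield full, leaf
                elif isinstance(leaf, Module):
                    yield from leaf.named_parameters(f"{full}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                state[f"__bn{i}.mean"] = m.running_mean.copy()
                state[f"__bn{i}.var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for name, p in self.named_parameters():
            p.data = state[name].copy()
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running_mean = state[f"__bn{i}.mean"].copy()
                m.running_var = state[f"__bn{i}.var"].copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel: int, stride: int = 1,
                 padding: int = 0, dilation: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = cin * kernel * kernel
        std = math.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, std, (cout, cin, kernel, kernel)).astype(np.float32))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None
        self.stride, self.padding, self.dilation = stride, padding, dilation

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding,
                      self.dilation)

    __call__ = forward


class BatchNorm2d(Module):
    def __init__(self, ch: int):
        super().__init__()
        self.weight = Parameter(np.ones(ch, dtype=np.float32))
        self.bias = Parameter(np.zeros(ch, dtype=np.float32))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        return batchnorm2d(x, self.weight, self.bias, self.running_mean,
                           self.running_var, self.training)

    __call__ = forward


class ConvBNReLU(Module):
    """3x3/1x1 convolution -> batch norm -> ReLU (no conv bias)."""

    def __init__(self, cin, cout, kernel, stride=1, padding=0, dilation=1,
                 rng=None):
        super().__init__()
        self.conv = Conv2d(cin, cout, kernel, stride, padding, dilation,
                           bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        return relu(self.bn(self.conv(x)))

    __call__ = forward


# ---------------------------------------------------------------------------
# ResNet50 encoder
# ---------------------------------------------------------------------------

class Bottleneck(Module):
    expansion = 4

    def __init__(self, cin, width, stride=1, dilation=1, downsample=False,
                 rng=None):
        super().__init__()
        cout = width * self.expansion
        self.conv1 = Conv2d(cin, width, 1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(width)
        self.conv2 = Conv2d(width, width, 3, stride=stride, padding=dilation,
                            dilation=dilation, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(width)
        self.conv3 = Conv2d(width, cout, 1, bias=False, rng=rng)
        self.bn3 = BatchNorm2d(cout)
        if downsample:
            self.down_conv = Conv2d(cin, cout, 1, stride=stride, bias=False,
                                    rng=rng)
            self.down_bn = BatchNorm2d(cout)
        else:
            self.down_conv = None

    def forward(self, x: Tensor) -> Tensor:
        out = relu(self.bn1(self.conv1(x)))
        out = relu(self.bn2(self.conv2(out)))
        out = self.bn3(self.conv3(out))
        shortcut = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return relu(add(out, shortcut))

    __call__ = forward


class ResNet50Encoder(Module):
    """ResNet50 feature extractor with 5 taps (strides 2..32, or 16 dilated).

    ``forward`` returns ``[x, f1, f2, f3, f4, f5]`` with channel widths
    (3, 64, 256, 512, 1024, 2048) -- the input itself plus the stem and the
    four bottleneck stages.
    """

    out_channels = (3, 64, 256, 512, 1024, 2048)

    def __init__(self, output_stride: int = 32, rng=None):
        super().__init__()
        if output_stride not in (16, 32):
            raise ValueError("output_stride must be 16 or 32")
        self.conv1 = Conv2d(3, 64, 7, stride=2, padding=3, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(64)
        blocks = [3, 4, 6, 3]
        widths = [64, 128, 256, 512]
        strides = [1, 2, 2, 2 if output_stride == 32 else 1]
        dilations = [1, 1, 1, 1 if output_stride == 32 else 2]
        self.layers = []
        cin = 64
        for nb, w, s, d in zip(blocks, widths, strides, dilations):
            layer = [Bottleneck(cin, w, stride=s, dilation=d, downsample=True,
                                rng=rng)]
            cin = w * Bottleneck.expansion
            layer += [Bottleneck(cin, w, dilation=d, rng=rng)
                      for _ in range(nb - 1)]
            self.layers.append(layer)

    def forward(self, x: Tensor) -> list[Tensor]:
        f1 = relu(self.bn1(self.conv1(x)))
        h = maxpool2d(f1, 3, 2, 1)
        feats = [x, f1]
        for layer in self.layers:
            for block in layer:
                h = block(h)
            feats.append(h)
        return feats

    __call__ = forward


# ---------------------------------------------------------------------------
# decoders
# ---------------------------------------------------------------------------

class UnetDecoderBlock(Module):
    """Upsample x2 -> concat skip -> two 3x3 conv-BN-ReLU units.

    With ``residual=True`` a 1x1 convolution (with bias) projects the
    concatenated input and is added before the final ReLU -- the
    residual-decoder variant.
    """

    def __init__(self, cin, skip, cout, residual=False, rng=None):
        super().__init__()
        total = cin + skip
        self.conv1 = ConvBNReLU(total, cout, 3, padding=1, rng=rng)
        self.residual = residual
        if residual:
            self.conv2 = Conv2d(cout, cout, 3, padding=1, bias=False, rng=rng)
            self.bn2 = BatchNorm2d(cout)
            self.shortcut = Conv2d(total, cout, 1, bias=True, rng=rng)
        else:
            self.conv2 = ConvBNReLU(cout, cout, 3, padding=1, rng=rng)

    def forward(self, x: Tensor, skip: Tensor | None = None) -> Tensor:
        x = upsample_nearest2(x)
        if skip is not None:
            x = concat([x, skip], axis=1)
        if self.residual:
            y = self.bn2(self.conv2(self.conv1(x)))
            return relu(add(y, self.shortcut(x)))
        return self.conv2(self.conv1(x))

    __call__ = forward


DECODER_CHANNELS = (256, 128, 64, 32, 16)


class UnetDecoder(Module):
    def __init__(self, encoder_channels=ResNet50Encoder.out_channels,
                 decoder_channels=DECODER_CHANNELS, residual=False, rng=None):
        super().__init__()
        enc = list(encoder_channels[1:])[::-1]          # (2048,1024,512,256,64)
        head = enc[0]
        ins = [head] + list(decoder_channels[:-1])
        skips = enc[1:] + [0]
        self.blocks = [UnetDecoderBlock(i, s, o, residual=residual, rng=rng)
                       for i, s, o in zip(ins, skips, decoder_channels)]

    def forward(self, features: list[Tensor]) -> Tensor:
        feats = features[1:][::-1]
        x = feats[0]
        skips = feats[1:]
        for i, block in enumerate(self.blocks):
            x = block(x, skips[i] if i < len(skips) else None)
        return x

    __call__ = forward


class UnetPlusPlusDecoder(Module):
    """Nested dense-skip decoder (UNet++)."""

    def __init__(self, encoder_channels=ResNet50Encoder.out_channels,
                 decoder_channels=DECODER_CHANNELS, rng=None):
        super().__init__()
        enc = list(encoder_channels[1:])[::-1]          # (2048,1024,512,256,64)
        head = enc[0]
        self.in_channels = [head] + list(decoder_channels[:-1])
        self.skip_channels = enc[1:] + [0]
        self.out_channels = list(decoder_channels)
        self.depth = len(self.in_channels) - 1
        blocks: dict[str, UnetDecoderBlock] = {}
        for layer_idx in range(len(self.in_channels) - 1):
            for depth_idx in range(layer_idx + 1):
                if depth_idx == 0:
                    in_ch = self.in_channels[layer_idx]
                    skip_ch = self.skip_channels[layer_idx] * (layer_idx + 1)
                    out_ch = self.out_channels[layer_idx]
                else:
                    out_ch = self.skip_channels[layer_idx]
                    skip_ch = self.skip_channels[layer_idx] * (layer_idx + 1 - depth_idx)
                    in_ch = self.skip_channels[layer_idx - 1]
                blocks[f"x_{depth_idx}_{layer_idx}"] = UnetDecoderBlock(
                    in_ch, skip_ch, out_ch, rng=rng)
        blocks[f"x_0_{len(self.in_channels) - 1}"] = UnetDecoderBlock(
            self.in_channels[-1], 0, self.out_channels[-1], rng=rng)
        self.blocks = blocks

    def forward(self, features: list[Tensor]) -> Tensor:
        feats = features[1:][::-1]
        dense: dict[str, Tensor] = {}
        for layer_idx in range(len(self.in_channels) - 1):
            for depth_idx in range(self.depth - layer_idx):
                if layer_idx == 0:
                    dense[f"x_{depth_idx}_{depth_idx}"] = self.blocks[
                        f"x_{depth_idx}_{depth_idx}"](feats[depth_idx],
                                                      feats[depth_idx + 1])
                else:
                    li = depth_idx + layer_idx
                    cat = [dense[f"x_{idx}_{li}"]
                           for idx in range(depth_idx + 1, li + 1)]
                    skip = concat(cat + [feats[li + 1]], axis=1)
                    dense[f"x_{depth_idx}_{li}"] = self.blocks[
                        f"x_{depth_idx}_{li}"](dense[f"x_{depth_idx}_{li - 1}"],
                                               skip)
        final = f"x_0_{self.depth}"
        dense[final] = self.blocks[final](dense[f"x_0_{self.depth - 1}"])
        return dense[final]

    __call__ = forward


class ASPP(Module):
    """Atrous spatial pyramid pooling: 1x1 + three dilated 3x3 branches +
    image-level pooling, projected back to ``out`` channels."""

    def __init__(self, cin=2048, out=256, rates=(12, 24, 36), dropout_p=0.5,
                 rng=None):
        super().__init__()
        self.branch0 = ConvBNReLU(cin, out, 1, rng=rng)
        self.branches = [ConvBNReLU(cin, out, 3, padding=r, dilation=r, rng=rng)
                         for r in rates]
        self.pool_conv = ConvBNReLU(cin, out, 1, rng=rng)
        self.project = ConvBNReLU(out * (len(rates) + 2), out, 1, rng=rng)
        self.dropout_p = dropout_p
        self._rng = rng or np.random.default_rng()

    def forward(self, x: Tensor) -> Tensor:
        size = x.data.shape[2:]
        parts = [self.branch0(x)] + [b(x) for b in self.branches]
        pooled = broadcast_spatial(self.pool_conv(global_avg_pool(x)), size)
        out = self.project(concat(parts + [pooled], axis=1))
        return dropout(out, self.dropout_p, self._rng, self.training)

    __call__ = forward


class DeepLabV3Decoder(Module):
    def __init__(self, rng=None):
        super().__init__()
        self.aspp = ASPP(rng=rng)
        self.refine = ConvBNReLU(256, 256, 3, padding=1, rng=rng)

    def forward(self, features: list[Tensor]) -> Tensor:
        return self.refine(self.aspp(features[-1]))

    __call__ = forward


# ---------------------------------------------------------------------------
# assembled segmentation models
# ---------------------------------------------------------------------------

class SegmentationNet(Module):
    """Encoder + decoder + 2-logit classification head.

    The head emits background/foreground logits; the public probability map
    is the softmax foreground channel, computed as
    ``sigmoid(logit_fg - logit_bg)`` so the network's output is a
    single-channel map in [0, 1] with the input's spatial size.
    """

    def __init__(self, arch: str, encoder: Module, decoder: Module,
                 head: Conv2d, upsample_head: int = 1):
        super().__init__()
        self.arch = arch
        self.encoder = encoder
        self.decoder = decoder
        self.head = head
        self.upsample_head = upsample_head

    def forward_logits(self, x: Tensor) -> Tensor:
        H, W = x.data.shape[2:]
        if H % 32 or W % 32:
            raise ValueError(f"input spatial dims must be divisible by 32, "
                             f"got {H}x{W}")
        logits = self.head(self.decoder(self.encoder(x)))
        if self.upsample_head > 1:
            logits = upsample_bilinear(logits, self.upsample_head)
        return logits

    def forward_proba(self, x: Tensor) -> Tensor:
        """Foreground probability map as a (N, 1, H, W) tensor on the tape."""
        z = self.forward_logits(x)
        return sigmoid(sub(slice_channels(z, 1, 2), slice_channels(z, 0, 1)))

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Inference: (N, 3, H, W) or (N, H, W)/(H, W) grayscale -> (N, H, W)."""
        x = as_model_input(images)
        was_training = self.training
        self.eval()
        try:
            p = self.forward_proba(Tensor(x)).data[:, 0]
        finally:
            if was_training:
                self.train()
        return p

    __call__ = forward_proba


def as_model_input(images: np.ndarray) -> np.ndarray:
    """Coerce grayscale input to a float32 (N, 3, H, W) batch."""
    arr = np.asarray(images, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 3:                       # (N, H, W): replicate channels
        arr = np.repeat(arr[:, None], 3, axis=1)
    if arr.ndim != 4 or arr.shape[1] != 3:
        raise ValueError(f"expected grayscale or (N,3,H,W) input, got {arr.shape}")
    return arr


def build_net(arch: str, seed: int = 0) -> SegmentationNet:
    rng = np.random.default_rng(seed)
    if arch in ("unet", "resunet"):
        encoder = ResNet50Encoder(rng=rng)
        decoder = UnetDecoder(residual=(arch == "resunet"), rng=rng)
        kernel = 1 if arch == "resunet" else 3
        head = Conv2d(DECODER_CHANNELS[-1], 2, kernel,
                      padding=(kernel - 1) // 2, bias=True, rng=rng)
        return SegmentationNet(arch, encoder, decoder, head)
    if arch == "unetpp":
        encoder = ResNet50Encoder(rng=rng)
        decoder = UnetPlusPlusDecoder(rng=rng)
        head = Conv2d(DECODER_CHANNELS[-1], 2, 3, padding=1, bias=True, rng=rng)
        return SegmentationNet(arch, encoder, decoder, head)
    if arch == "deeplabv3":
        encoder = ResNet50Encoder(output_stride=16, rng=rng)
        decoder = DeepLabV3Decoder(rng=rng)
        head = Conv2d(256, 2, 1, bias=True, rng=rng)
        return SegmentationNet(arch, encoder, decoder, head, upsample_head=16)
    raise ValueError(f"unknown architecture {arch!r}; "
                     f"expected unet, unetpp, deeplabv3 or resunet")


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: Sequence[Parameter], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
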