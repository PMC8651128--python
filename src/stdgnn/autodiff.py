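"""Compact reverse-mode automatic differentiation on numpy arrays.

The network modules in this package are small enough that a dense, eager
autodiff layer over numpy is both sufficient and fast on a single CPU: every
operation is a chunky BLAS-backed array op, and the graph per training step
has a few hundred nodes.  The engine supports exactly the operations the
STDGNN forward/backward passes need: broadcasting arithmetic, matmul,
reshape/transpose/concat, reductions, gather/sort, leaky rectifiers,
sigmoid/softmax, stride-1 3-D convolution (odd kernels, "same" padding),
non-overlapping pooling, and nearest-neighbour upsampling.

Convolution gradients w.r.t. the input are themselves computed as
convolutions with the spatially flipped kernel, which keeps the backward
pass on the same fast im2col path as the forward pass.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "concat",
    "matmul",
    "conv3d",
    "avg_pool3d",
    "max_pool3d",
    "upsample_nearest3d",
    "leaky_relu",
    "relu",
    "sigmoid",
    "log",
    "exp",
    "sqrt",
    "softmax",
    "log_softmax",
    "sort_columns",
    "take_rows",
    "no_grad",
]


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self):
        return float(self.data)

    def detach(self):
        return Tensor(self.data.copy())

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add, lambda g, a, b: (g, g))

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, np.subtract, lambda g, a, b: (g, -g))

    def __rsub__(self, other):
        return _to_tensor(other) - self

    def __mul__(self, other):
        return _binary(self, other, np.multiply,
                       lambda g, a, b: (g * b.data, g * a.data))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binary(
            self, other, np.divide,
            lambda g, a, b: (g / b.data, -g * a.data / (b.data ** 2)))

    def __rtruediv__(self, other):
        return _to_tensor(other) / self

    def __neg__(self):
        return self * -1.0

    def __pow__(self, p):
        assert np.isscalar(p)
        out = _make(self.data ** p, (self,))
        if out.requires_grad:
            def bw(g):
                _accum(self, g * p * self.data ** (p - 1))
            out._backward = bw
        return out

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        if out.requires_grad:
            src_shape = self.data.shape
            out._backward = lambda g: _accum(self, g.reshape(src_shape))
        return out

    def transpose(self, *axes):
        if not axes:
            axes = tuple(range(self.ndim))[::-1]
        out = _make(np.transpose(self.data, axes), (self,))
        if out.requires_grad:
            inv = np.argsort(axes)
            out._backward = lambda g: _accum(self, np.transpose(g, inv))
        return out

    @property
    def T(self):
        return self.transpose()

    def sum(self, axis=None, keepdims=False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            shape = self.data.shape

            def bw(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                _accum(self, np.broadcast_to(g, shape))
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=0):
        idx = np.argmax(self.data, axis=axis)
        out = _make(np.max(self.data, axis=axis), (self,))
        if out.requires_grad:
            def bw(g):
                full = np.zeros_like(self.data)
                np.put_along_axis(
                    full, np.expand_dims(idx, axis),
                    np.expand_dims(g, axis), axis)
                _accum(self, full)
            out._backward = bw
        return out


def _to_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def tensor(data, requires_grad=False):
    return Tensor(data, requires_grad=requires_grad)


_GRAD_ENABLED = [True]


class no_grad:
    def __enter__(self):
        _GRAD_ENABLED.append(False)

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()


def _make(data, parents):
    out = Tensor(data)
    if _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
    return out


def _accum(t, g):
    if not t.requires_grad:
        return
    g = _unbroadcast(g, t.data.shape)
    # grads are never mutated in place, so first-assignment may alias
    t.grad = g if t.grad is None else t.grad + g


def _unbroadcast(g, shape):
    """Sum gradient g down to `shape` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def _match_dtype(a, b):
    """Cast the constant side of a mixed float32/float64 pair to float32.

    Keeps float32 network graphs from silently upcasting when combined
    with float64 constants (masks, adjacencies, targets); pure-float64
    graphs are unaffected.  Gradient-tracked tensors are never recast.
    """
    if a.data.dtype != b.data.dtype:
        if a.data.dtype == np.float32 and not b.requires_grad:
            b = Tensor(b.data.astype(np.float32))
        elif b.data.dtype == np.float32 and not a.requires_grad:
            a = Tensor(a.data.astype(np.float32))
    return a, b


def _binary(a, b, fwd, bwd):
    a, b = _match_dtype(_to_tensor(a), _to_tensor(b))
    out = _make(fwd(a.data, b.data), (a, b))
    if out.requires_grad:
        def backward(g):
            ga, gb = bwd(g, a, b)
            _accum(a, ga)
            _accum(b, gb)
        out._backward = backward
    return out


# -- linear algebra --------------------------------------------------------

def matmul(a, b):
    a, b = _match_dtype(_to_tensor(a), _to_tensor(b))
    out = _make(a.data @ b.data, (a, b))
    if out.requires_grad:
        def bw(g):
            if a.requires_grad:
                _accum(a, g @ np.swapaxes(b.data, -1, -2))
            if b.requires_grad:
                _accum(b, np.swapaxes(a.data, -1, -2) @ g)
        out._backward = bw
    return out


def concat(tensors, axis=0):
    tensors = [_to_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                _accum(t, piece)
        out._backward = bw
    return out


def take_rows(x, idx):
    """Differentiable row gather: out[i] = x[idx[i]]."""
    x = _to_tensor(x)
    idx = np.asarray(idx)
    out = _make(x.data[idx], (x,))
    if out.requires_grad:
        def bw(g):
            full = np.zeros_like(x.data)
            np.add.at(full, idx, g)
            _accum(x, full)
        out._backward = bw
    return out


def sort_columns(x):
    """Sort each column of a 2-D tensor ascending (differentiable permute)."""
    x = _to_tensor(x)
    idx = np.argsort(x.data, axis=0, kind="stable")
    out = _make(np.take_along_axis(x.data, idx, axis=0), (x,))
    if out.requires_grad:
        def bw(g):
            full = np.zeros_like(x.data)
            np.put_along_axis(full, idx, g, axis=0)
            _accum(x, full)
        out._backward = bw
    return out


# -- pointwise nonlinearities ----------------------------------------------

def leaky_relu(x, slope=0.01):
    x = _to_tensor(x)
    out = _make(np.where(x.data > 0, x.data, slope * x.data), (x,))
    if out.requires_grad:
        factor = np.where(x.data > 0, 1.0, slope).astype(x.data.dtype)
        out._backward = lambda g: _accum(x, g * factor)
    return out


def relu(x):
    return leaky_relu(x, slope=0.0)


def sigmoid(x):
    x = _to_tensor(x)
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))
    out = _make(s, (x,))
    if out.requires_grad:
        out._backward = lambda g: _accum(x, g * s * (1 - s))
    return out


def exp(x):
    x = _to_tensor(x)
    e = np.exp(x.data)
    out = _make(e, (x,))
    if out.requires_grad:
        out._backward = lambda g: _accum(x, g * e)
    return out


def log(x, eps=0.0):
    x = _to_tensor(x)
    d = np.maximum(x.data, eps) if eps else x.data
    out = _make(np.log(d), (x,))
    if out.requires_grad:
        out._backward = lambda g: _accum(x, g / np.maximum(d, 1e-300))
    return out


def sqrt(x):
    x = _to_tensor(x)
    s = np.sqrt(x.data)
    out = _make(s, (x,))
    if out.requires_grad:
        out._backward = lambda g: _accum(x, g * 0.5 / np.maximum(s, 1e-300))
    return out


def log_softmax(x, axis=-1):
    x = _to_tensor(x)
    m = x.data.max(axis=axis, keepdims=True)
    z = x.data - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = _make(z - lse, (x,))
    if out.requires_grad:
        sm = np.exp(z - lse)

        def bw(g):
            _accum(x, g - sm * g.sum(axis=axis, keepdims=True))
        out._backward = bw
    return out


def softmax(x, axis=-1):
    return exp(log_softmax(x, axis=axis))


# -- convolution & pooling -------------------------------------------------

def _im2col(data, kernel):
    """(B, C, X, Y, Z) -> (B, C*kx*ky*kz, X*Y*Z) with 'same' zero padding.

    Built one kernel offset at a time so every copy is an axis-aligned
    strided block (no permutation), and laid out so the convolution is a
    single batched GEMM with no output transpose.
    """
    kx, ky, kz = kernel
    b, c, X, Y, Z = data.shape
    pads = [(0, 0), (0, 0), (kx // 2,) * 2, (ky // 2,) * 2, (kz // 2,) * 2]
    xp = np.pad(data, pads)
    K = kx * ky * kz
    cols = np.empty((b, c, K, X, Y, Z), dtype=data.dtype)
    koff = 0
    for dx in range(kx):
        for dy in range(ky):
            for dz in range(kz):
                cols[:, :, koff] = xp[:, :, dx:dx + X, dy:dy + Y, dz:dz + Z]
                koff += 1
    return cols.reshape(b, c * K, X * Y * Z), (b, X, Y, Z)


def _conv3d_raw(data, weight, bias=None):
    cout = weight.shape[0]
    cols, (b, X, Y, Z) = _im2col(data, weight.shape[2:])
    out = np.matmul(weight.reshape(cout, -1)[None], cols)  # (B, Co, XYZ)
    out = out.reshape(b, cout, X, Y, Z)
    if bias is not None:
        out = out + bias[None, :, None, None, None]
    return out, cols


def conv3d(x, weight, bias=None):
    """Stride-1 'same' 3-D convolution; odd kernel sizes only.

    x: (B, C_in, X, Y, Z); weight: (C_out, C_in, kx, ky, kz); bias: (C_out,)
    """
    x, weight = _to_tensor(x), _to_tensor(weight)
    if any(k % 2 == 0 for k in weight.data.shape[2:]):
        raise ValueError("conv3d supports odd kernel sizes only")
    bias = _to_tensor(bias) if bias is not None else None
    out_data, cols = _conv3d_raw(
        x.data, weight.data, None if bias is None else bias.data)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = _make(out_data, parents)
    if out.requires_grad:
        cout = weight.data.shape[0]

        def bw(g):
            gmat = g.reshape(g.shape[0], cout, -1)       # (B, Co, XYZ)
            if weight.requires_grad:
                gw = np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0)
                _accum(weight, gw.reshape(weight.data.shape))
            if bias is not None and bias.requires_grad:
                _accum(bias, gmat.sum(axis=(0, 2)))
            if x.requires_grad:
                # input gradient = conv of g with the flipped, transposed kernel
                wflip = weight.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
                gx, _ = _conv3d_raw(g, np.ascontiguousarray(wflip))
                _accum(x, gx)
        out._backward = bw
    return out


def _pool_view(data, f):
    b, c, X, Y, Z = data.shape
    fx, fy, fz = f
    assert X % fx == 0 and Y % fy == 0 and Z % fz == 0, \
        f"pooling factor {f} must divide spatial dims {(X, Y, Z)}"
    return data.reshape(b, c, X // fx, fx, Y // fy, fy, Z // fz, fz)


def avg_pool3d(x, factor=(2, 2, 2)):
    x = _to_tensor(x)
    v = _pool_view(x.data, factor)
    out = _make(v.mean(axis=(3, 5, 7)), (x,))
    if out.requires_grad:
        n = float(np.prod(factor))   # python float: no dtype promotion

        def bw(g):
            g = g / n
            g = np.repeat(np.repeat(np.repeat(
                g, factor[0], axis=2), factor[1], axis=3), factor[2], axis=4)
            _accum(x, g)
        out._backward = bw
    return out


def max_pool3d(x, factor=(2, 2, 2)):
    x = _to_tensor(x)
    v = _pool_view(x.data, factor)
    m = v.max(axis=(3, 5, 7))
    out = _make(m, (x,))
    if out.requires_grad:
        mask = (v == m[:, :, :, None, :, None, :, None]).astype(x.data.dtype)
        # ties split gradient equally — deterministic and symmetric
        mask = mask / mask.sum(axis=(3, 5, 7), keepdims=True)

        def bw(g):
            gv = g[:, :, :, None, :, None, :, None] * mask
            _accum(x, gv.reshape(x.data.shape))
        out._backward = bw
    return out


def upsample_nearest3d(x, factor=(2, 2, 2)):
    x = _to_tensor(x)
    d = np.repeat(np.repeat(np.repeat(
        x.data, factor[0], axis=2), factor[1], axis=3), factor[2], axis=4)
    out = _make(d, (x,))
    if out.requires_grad:
        def bw(g):
            v = _pool_view(g, factor)
            _accum(x, v.sum(axis=(3, 5, 7)))
        out._backward = bw
    return out


# -- modules ---------------------------------------------------------------

class Module:
    """Minimal parameter container with named-parameter traversal."""

    def parameters(self):
        out = []
        for _, p in self.named_parameters():
            out.append(p)
        return out

    def named_parameters(self, prefix=""):
        items = []
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                items.append((key, val))
            elif isinstance(val, Module):
                items.extend(val.named_parameters(prefix=key + "."))
            elif isinstance(val, (list, tuple)):
                for i, v in enumerate(val):
                    if isinstance(v, Module):
                        items.extend(v.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(v, Tensor) and v.requires_grad:
                        items.append((f"{key}.{i}", v))
        return items

    def modules(self):
        mods = [self]
        for val in vars(self).values():
            if isinstance(val, Module):
                mods.extend(val.modules())
            elif isinstance(val, (list, tuple)):
                for v in val:
                    if isinstance(v, Module):
                        mods.extend(v.modules())
        return mods

    def astype(self, dtype):
        """Cast all parameters and batch-norm statistics (in place)."""
        for _, p in self.named_parameters():
            p.data = p.data.astype(dtype)
        for m in self.modules():
            if isinstance(m, BatchNorm):
                m.running_mean = m.running_mean.astype(dtype)
                m.running_var = m.running_var.astype(dtype)
        return self

    def train(self):
        for m in self.modules():
            m._training = True

    def eval(self):
        for m in self.modules():
            m._training = False

    _training = True

    def state_dict(self):
        state = {k: p.data.copy() for k, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm):
                state[f"__bn{i}.mean"] = m.running_mean.copy()
                state[f"__bn{i}.var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state):
        for k, p in self.named_parameters():
            p.data = np.asarray(state[k]).copy()
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm):
                m.running_mean = np.asarray(state[f"__bn{i}.mean"]).copy()
                m.running_var = np.asarray(state[f"__bn{i}.var"]).copy()


def _kaiming(rng, shape, fan_in):
    return Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape),
                  requires_grad=True)


class Linear(Module):
    def __init__(self, d_in, d_out, rng):
        self.weight = _kaiming(rng, (d_in, d_out), d_in)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x):
        return matmul(x, self.weight) + self.bias


class Conv3d(Module):
    def __init__(self, c_in, c_out, kernel, rng):
        fan_in = c_in * int(np.prod(kernel))
        self.weight = _kaiming(rng, (c_out, c_in) + tuple(kernel), fan_in)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x):
        return conv3d(x, self.weight, self.bias)


class BatchNorm(Module):
    """Batch normalization over all axes except `channel_axis`."""

    def __init__(self, num_features, channel_axis=1, momentum=0.1, eps=1e-5):
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.channel_axis = channel_axis
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x):
        x = _to_tensor(x)
        ax = self.channel_axis % x.ndim
        red = tuple(i for i in range(x.ndim) if i != ax)
        bshape = [1] * x.ndim
        bshape[ax] = -1
        if self._training:
            self.running_mean = (1 - self.momentum) * self.running_mean \
                + self.momentum * x.data.mean(axis=red)
            self.running_var = (1 - self.momentum) * self.running_var \
                + self.momentum * x.data.var(axis=red)
            mu_t = x.mean(axis=red, keepdims=True)
            var_t = ((x - mu_t) ** 2).mean(axis=red, keepdims=True)
            xhat = (x - mu_t) / sqrt(var_t + self.eps)
        else:
            mu_t = Tensor(self.running_mean.reshape(bshape))
            sd_t = Tensor(np.sqrt(self.running_var + self.eps).reshape(bshape))
            xhat = (x - mu_t) / sd_t
        return xhat * self.gamma.reshape(bshape) + self.beta.reshape(bshape)


def clip_grad_norm(params, max_norm):
    """Scale gradients in place so their global L2 norm is <= max_norm."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float(np.sum(p.grad.astype(np.float64) ** 2))
    norm = np.sqrt(total)
    if norm > max_norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
    return norm


class Adam(Module):
    """Adam with decoupled-from-graph L2 weight decay folded into the gradient."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self):
        state = {"t": np.asarray(self.t)}
        for i in range(len(self.params)):
            state[f"m{i}"] = self.m[i]
            state[f"v{i}"] = self.v[i]
        return state

    def load_state_dict(self, state):
        self.t = int(state["t"])
        self.m = [np.asarray(state[f"m{i}"]).copy() for i in range(len(self.params))]
        self.v = [np.asarray(state[f"v{i}"]).copy() for i in range(len(self.params))]
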