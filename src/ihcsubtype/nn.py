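"""Minimal reverse-mode tensor engine for the segmentation networks.

A small NHWC convolutional-network toolkit on top of numpy: tensors carry a
backward closure, gradients flow through a topologically sorted tape, and
convolutions are expressed as per-kernel-offset BLAS matmuls (no im2col
buffers). It implements exactly the layer vocabulary the architecture needs —
3x3/1x1 convolutions (stride 1 or 2, 'same' padding), 2x2 stride-2 transposed
convolutions, nearest-neighbour upsampling, batch normalization, ReLU,
channel concatenation, dropout, global average pooling, dense layers and
softmax — with He-normal initialization throughout.

Everything is float32 and deterministic given the construction seed.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# Tensor and tape
# ---------------------------------------------------------------------------


class Tensor:
    """An ndarray node of the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in self._parents
        )

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate ``grad`` (defaults to ones) through the tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free intermediate state as soon as it has been consumed, so the
            # peak memory of a training step stays close to the forward pass
            if node._backward is not None and not isinstance(node, Parameter):
                node.grad = None
                node._backward = None
                node._parents = ()


class Parameter(Tensor):
    """A trainable leaf tensor."""

    __slots__ = ("name", "decay")

    def __init__(self, data, name: str = "", decay: bool = True):
        super().__init__(data, requires_grad=True)
        self.name = name
        self.decay = decay  # participates in L2 weight decay

    def zero_grad(self) -> None:
        self.grad = None


# ---------------------------------------------------------------------------
# Functional ops
# ---------------------------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(g)

    return Tensor(out_data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0.0)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor(out_data, (x,), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, part in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(part)

    return Tensor(out_data, tuple(tensors), backward)


def conv2d(x: Tensor, w: Parameter, b: Parameter | None, stride: int = 1) -> Tensor:
    """'Same'-padded 2-D convolution, NHWC input, (kh, kw, cin, cout) kernel.

    Spatial dimensions must be divisible by ``stride``.
    """
    n, h, wd, cin = x.data.shape
    kh, kw, cin_w, cout = w.data.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, kernel {cin_w}")
    if h % stride or wd % stride:
        raise ValueError("spatial size must be divisible by stride")
    ph, pw = kh // 2, kw // 2
    oh, ow = h // stride, wd // stride
    hp, wp = h + 2 * ph, wd + 2 * pw

    def _padded():
        if ph or pw:
            return np.pad(x.data, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        return x.data

    def _slc(ki, kj):
        return (
            slice(None),
            slice(ki, ki + stride * (oh - 1) + 1, stride),
            slice(kj, kj + stride * (ow - 1) + 1, stride),
            slice(None),
        )

    wm = w.data.reshape(kh * kw, cin, cout)
    xp = _padded()
    out_data = np.zeros((n, oh, ow, cout), dtype=np.float32)
    if stride == 1:
        # shifted-output formulation: one contiguous GEMM over the padded
        # grid per kernel offset, then a strided accumulate — avoids copying
        # a shifted view of the input for every offset
        xpm = xp.reshape(-1, cin)
        for ki in range(kh):
            for kj in range(kw):
                y = (xpm @ wm[ki * kw + kj]).reshape(n, hp, wp, cout)
                out_data += y[_slc(ki, kj)]
    else:
        for ki in range(kh):
            for kj in range(kw):
                out_data += (xp[_slc(ki, kj)].reshape(-1, cin) @ wm[ki * kw + kj]
                             ).reshape(n, oh, ow, cout)
    del xp  # re-padded in backward; retaining it would double activation memory
    if b is not None:
        out_data += b.data

    def backward(g):
        gm = np.ascontiguousarray(g).reshape(-1, cout)
        xp = _padded()
        if w.requires_grad:
            dw = np.empty_like(w.data)
            if stride == 1:
                # dW[k] = xp^T @ (g scattered at offset k on the padded grid)
                xpm = xp.reshape(-1, cin)
                gpad = np.zeros((n, hp, wp, cout), dtype=np.float32)
                for ki in range(kh):
                    for kj in range(kw):
                        gpad[_slc(ki, kj)] = g
                        dw[ki, kj] = xpm.T @ gpad.reshape(-1, cout)
                        gpad[_slc(ki, kj)] = 0.0
            else:
                for ki in range(kh):
                    for kj in range(kw):
                        dw[ki, kj] = xp[_slc(ki, kj)].reshape(-1, cin).T @ gm
            w._accumulate(dw)
        if b is not None and b.requires_grad:
            b._accumulate(gm.sum(axis=0))
        if x.requires_grad:
            dxp = np.zeros((n, hp, wp, cin), dtype=np.float32)
            for ki in range(kh):
                for kj in range(kw):
                    dxp[_slc(ki, kj)] += (gm @ wm[ki * kw + kj].T).reshape(
                        n, oh, ow, cin
                    )
            if ph or pw:
                dxp = dxp[:, ph : ph + h, pw : pw + wd, :]
            x._accumulate(dxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, parents, backward)


def conv_transpose2d(x: Tensor, w: Parameter, b: Parameter | None) -> Tensor:
    """2x2 stride-2 transposed convolution (exact 2x upsampling, no overlap)."""
    n, h, wd, cin = x.data.shape
    kh, kw, cin_w, cout = w.data.shape
    if (kh, kw) != (2, 2) or cin != cin_w:
        raise ValueError("conv_transpose2d expects a (2,2,cin,cout) kernel")
    xm = x.data.reshape(-1, cin)
    out_data = np.empty((n, 2 * h, 2 * wd, cout), dtype=np.float32)
    for ki in range(2):
        for kj in range(2):
            out_data[:, ki::2, kj::2, :] = (xm @ w.data[ki, kj]).reshape(
                n, h, wd, cout
            )
    if b is not None:
        out_data += b.data

    def backward(g):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1, 2)))
        dw = np.empty_like(w.data) if w.requires_grad else None
        dx = None
        for ki in range(2):
            for kj in range(2):
                gs = np.ascontiguousarray(g[:, ki::2, kj::2, :]).reshape(-1, cout)
                if dw is not None:
                    dw[ki, kj] = xm.T @ gs
                if x.requires_grad:
                    part = gs @ w.data[ki, kj].T
                    dx = part if dx is None else dx + part
        if dw is not None:
            w._accumulate(dw)
        if x.requires_grad and dx is not None:
            x._accumulate(dx.reshape(n, h, wd, cin))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, parents, backward)


def upsample_nearest2(x: Tensor) -> Tensor:
    n, h, w, c = x.data.shape
    out_data = np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g.reshape(n, h, 2, w, 2, c).sum(axis=(2, 4)))

    return Tensor(out_data, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    n, h, w, c = x.data.shape
    out_data = x.data.mean(axis=(1, 2))

    def backward(g):
        if x.requires_grad:
            x._accumulate(
                np.broadcast_to(g[:, None, None, :], x.data.shape) / (h * w)
            )

    return Tensor(out_data, (x,), backward)


def dense(x: Tensor, w: Parameter, b: Parameter | None) -> Tensor:
    out_data = x.data @ w.data
    if b is not None:
        out_data = out_data + b.data

    def backward(g):
        if w.requires_grad:
            w._accumulate(x.data.T @ g)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=0))
        if x.requires_grad:
            x._accumulate(g @ w.data.T)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, parents, backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            x._accumulate(out_data * (g - dot))

    return Tensor(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------


class Module:
    """Lightweight parameter/submodule container with a train/eval switch."""

    def __init__(self) -> None:
        self.training = True

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
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for value in self.__dict__.values():
            if isinstance(value, Module):
                value.train(mode)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def modules(self):
        """Depth-first walk over this module and all submodules."""
        yield self
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    @property
    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin, cout, kernel=3, stride=1, rng=None, name="conv"):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.stride = stride
        self.w = Parameter(
            he_normal(rng, (kernel, kernel, cin, cout), kernel * kernel * cin),
            name=f"{name}.w",
        )
        self.b = Parameter(np.zeros(cout, np.float32), name=f"{name}.b", decay=False)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride)


class ConvTranspose2d(Module):
    def __init__(self, cin, cout, rng=None, name="deconv"):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.w = Parameter(he_normal(rng, (2, 2, cin, cout), 4 * cin), name=f"{name}.w")
        self.b = Parameter(np.zeros(cout, np.float32), name=f"{name}.b", decay=False)

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.w, self.b)


class Dense(Module):
    def __init__(self, cin, cout, rng=None, name="dense"):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.w = Parameter(he_normal(rng, (cin, cout), cin), name=f"{name}.w")
        self.b = Parameter(np.zeros(cout, np.float32), name=f"{name}.b", decay=False)

    def __call__(self, x: Tensor) -> Tensor:
        return dense(x, self.w, self.b)


class BatchNorm(Module):
    """Per-channel batch normalization over (N, H, W) with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 name: str = "bn"):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, np.float32), name=f"{name}.gamma",
                               decay=False)
        self.beta = Parameter(np.zeros(channels, np.float32), name=f"{name}.beta",
                              decay=False)
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)
        self.momentum = momentum
        self.eps = eps
        self.collecting = False  # population-statistics pass (see collect_stats)
        self._collect_count = 0

    def __call__(self, x: Tensor) -> Tensor:
        axes = tuple(range(x.data.ndim - 1))
        if self.training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            if self.collecting:
                n = self._collect_count
                self.running_mean = (n * self.running_mean + mu) / (n + 1)
                self.running_var = (n * self.running_var + var) / (n + 1)
                self._collect_count = n + 1
            else:
                self.running_mean = (
                    self.momentum * self.running_mean + (1 - self.momentum) * mu
                )
                self.running_var = (
                    self.momentum * self.running_var + (1 - self.momentum) * var
                )
        else:
            mu, var = self.running_mean, self.running_var
        ivstd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        mu = mu.astype(np.float32)
        out_data = self.gamma.data * ((x.data - mu) * ivstd) + self.beta.data
        gamma, beta, training = self.gamma, self.beta, self.training

        def backward(g):
            # xhat recomputed from the stored input instead of being retained
            xhat = (x.data - mu) * ivstd
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=axes))
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=axes))
            if x.requires_grad:
                dxhat = g * gamma.data
                if training:
                    dx = (
                        dxhat
                        - dxhat.mean(axis=axes)
                        - xhat * (dxhat * xhat).mean(axis=axes)
                    ) * ivstd
                else:
                    dx = dxhat * ivstd
                x._accumulate(dx)

        return Tensor(out_data, (x, self.gamma, self.beta), backward)


class Dropout(Module):
    """Inverted dropout; active only in training mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = float(rate)
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.data.shape) < keep).astype(np.float32) / keep
        out_data = x.data * mask

        def backward(g):
            if x.requires_grad:
                x._accumulate(g * mask)

        return Tensor(out_data, (x,), backward)


def collect_batchnorm_stats(module: Module, forward, batches) -> None:
    """Replace batch-norm running statistics with population statistics.

    Re-estimates every BatchNorm's mean/variance as a uniform average over
    the given batches (forward passes only, dropout disabled), the way
    batch normalization defines its inference statistics. Call after
    training so eval-mode behavior matches the converged network.
    """
    bns = [m for m in module.modules() if isinstance(m, BatchNorm)]
    drops = [m for m in module.modules() if isinstance(m, Dropout)]
    saved_rates = [d.rate for d in drops]
    module.train(True)
    for d in drops:
        d.rate = 0.0
    for bn in bns:
        bn.collecting = True
        bn._collect_count = 0
    try:
        for batch in batches:
            forward(batch)
    finally:
        for bn in bns:
            bn.collecting = False
        for d, rate in zip(drops, saved_rates):
            d.rate = rate
        module.train(False)


class Adam:
    """Adam optimizer with optional coupled L2 regularization on kernels."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 l2: float = 0.0):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps, self.l2 = lr, beta1, beta2, eps, l2
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.l2 and p.decay:
                g = g + self.l2 * p.data
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * (g * g)
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
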