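"""Minimal reverse-mode autodiff for convolutional encoder–decoder networks.

The project trains a small residual U-Net on CPU, so this module implements
only the operations that network needs: 2-D convolution (strided/dilated,
realized as kernel-offset slices feeding BLAS matmuls), batch normalization,
ReLU, 2x2 max pooling, nearest-neighbour upsampling, tensor concatenation,
elementwise addition, and a fused sigmoid + binary-cross-entropy loss.
Everything is float32 numpy; gradients are exact (no approximation), and all
computation is deterministic on a fixed thread count.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "conv2d",
    "batchnorm2d",
    "relu",
    "maxpool2x2",
    "upsample2x",
    "concat",
    "add",
    "sigmoid",
    "sigmoid_bce",
    "Adam",
]


class Tensor:
    """A node in the reverse-mode tape.

    ``data`` is a numpy array; ``grad`` is filled by :meth:`backward`.
    Operations record their parents and a closure that pushes the incoming
    gradient to them.
    """

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        """Reverse-accumulate gradients from this (scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _conv_offsets(x_pad, w, stride, dilation, Ho, Wo):
    """Forward conv as a sum of kernel-offset slices times weight matrices."""
    N, Ci, _, _ = x_pad.shape
    Co, _, kh, kw = w.shape
    out = np.zeros((N, Ho, Wo, Co), dtype=np.float32)
    for ki in range(kh):
        for kj in range(kw):
            view = x_pad[:, :, ki * dilation: ki * dilation + stride * Ho: stride,
                         kj * dilation: kj * dilation + stride * Wo: stride]
            flat = view.transpose(0, 2, 3, 1).reshape(-1, Ci)
            out += (flat @ w[:, :, ki, kj].T).reshape(N, Ho, Wo, Co)
    return out.transpose(0, 3, 1, 2)


def conv2d(x: Tensor, w: Parameter, b: Parameter | None = None,
           stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    N, Ci, H, W = x.shape
    Co, Ci_w, kh, kw = w.shape
    if Ci != Ci_w:
        raise ValueError(f"conv2d channel mismatch: input {Ci}, weight {Ci_w}")
    eff_kh = (kh - 1) * dilation + 1
    eff_kw = (kw - 1) * dilation + 1
    Ho = (H + 2 * padding - eff_kh) // stride + 1
    Wo = (W + 2 * padding - eff_kw) // stride + 1
    x_pad = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    out = _conv_offsets(x_pad, w.data, stride, dilation, Ho, Wo)
    if b is not None:
        out += b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def _backward(g):
        g_nhwc = np.ascontiguousarray(g.transpose(0, 2, 3, 1))
        g_flat = g_nhwc.reshape(-1, Co)
        if w.requires_grad:
            dw = np.zeros_like(w.data)
        if x.requires_grad:
            dx_pad = np.zeros_like(x_pad)
        for ki in range(kh):
            for kj in range(kw):
                rs = slice(ki * dilation, ki * dilation + stride * Ho, stride)
                cs = slice(kj * dilation, kj * dilation + stride * Wo, stride)
                if w.requires_grad:
                    view = x_pad[:, :, rs, cs].transpose(0, 2, 3, 1).reshape(-1, Ci)
                    dw[:, :, ki, kj] = g_flat.T @ view
                if x.requires_grad:
                    dview = (g_flat @ w.data[:, :, ki, kj]).reshape(N, Ho, Wo, Ci)
                    dx_pad[:, :, rs, cs] += dview.transpose(0, 3, 1, 2)
        if w.requires_grad:
            w._accum(dw)
        if x.requires_grad:
            if padding:
                x._accum(dx_pad[:, :, padding:-padding, padding:-padding])
            else:
                x._accum(dx_pad)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    return Tensor(out, parents=parents, backward=_backward)


class BatchNormState:
    """Running statistics and step count for one batchnorm layer."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps


def batchnorm2d(x: Tensor, gamma: Parameter, beta: Parameter,
                state: BatchNormState, train: bool) -> Tensor:
    eps = state.eps
    if train:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        state.running_mean += state.momentum * (mean - state.running_mean)
        # unbiased running variance, matching the usual convention
        unbiased = var * m / max(m - 1, 1)
        state.running_var += state.momentum * (unbiased - state.running_var)
    else:
        mean = state.running_mean
        var = state.running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def _backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if not x.requires_grad:
            return
        gsc = g * gamma.data[None, :, None, None]
        if train:
            m = g.shape[0] * g.shape[2] * g.shape[3]
            sum_g = gsc.sum(axis=(0, 2, 3))[None, :, None, None]
            sum_gx = (gsc * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
            dx = (inv_std[None, :, None, None] / m) * (m * gsc - sum_g - xhat * sum_gx)
        else:
            dx = gsc * inv_std[None, :, None, None]
        x._accum(dx)

    return Tensor(out, parents=(x, gamma, beta), backward=_backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def _backward(g):
        if x.requires_grad:
            x._accum(g * mask)

    return Tensor(out, parents=(x,), backward=_backward)


def maxpool2x2(x: Tensor) -> Tensor:
    N, C, H, W = x.shape
    H2, W2 = H // 2, W // 2
    blocks = x.data[:, :, : 2 * H2, : 2 * W2].reshape(N, C, H2, 2, W2, 2)
    patches = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H2, W2, 4)
    idx = patches.argmax(axis=-1)
    out = np.take_along_axis(patches, idx[..., None], axis=-1)[..., 0]

    def _backward(g):
        if not x.requires_grad:
            return
        dpatch = np.zeros_like(patches)
        np.put_along_axis(dpatch, idx[..., None], g[..., None], axis=-1)
        dx = dpatch.reshape(N, C, H2, W2, 2, 2).transpose(0, 1, 2, 4, 3, 5) \
            .reshape(N, C, 2 * H2, 2 * W2)
        if 2 * H2 != H or 2 * W2 != W:
            full = np.zeros((N, C, H, W), dtype=np.float32)
            full[:, :, : 2 * H2, : 2 * W2] = dx
            dx = full
        x._accum(dx)

    return Tensor(out, parents=(x,), backward=_backward)


def upsample2x(x: Tensor) -> Tensor:
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def _backward(g):
        if x.requires_grad:
            N, C, H, W = x.shape
            x._accum(g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))

    return Tensor(out, parents=(x,), backward=_backward)


def concat(a: Tensor, b: Tensor) -> Tensor:
    out = np.concatenate([a.data, b.data], axis=1)
    ca = a.shape[1]

    def _backward(g):
        if a.requires_grad:
            a._accum(g[:, :ca])
        if b.requires_grad:
            b._accum(g[:, ca:])

    return Tensor(out, parents=(a, b), backward=_backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def _backward(g):
        if a.requires_grad:
            a._accum(g)
        if b.requires_grad:
            b._accum(g)

    return Tensor(out, parents=(a, b), backward=_backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data.astype(np.float64)))
    s = s.astype(np.float32)

    def _backward(g):
        if x.requires_grad:
            x._accum(g * s * (1.0 - s))

    return Tensor(s, parents=(x,), backward=_backward)


def sigmoid_bce(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean binary cross-entropy of sigmoid(logits) against 0/1 targets.

    Computed in the numerically stable log-sum-exp form; the gradient is the
    familiar (sigmoid(z) - y) / m.
    """
    z = logits.data.astype(np.float64)
    y = np.asarray(target, dtype=np.float64)
    # BCE(sigmoid(z), y) = max(z,0) - z*y + log(1 + exp(-|z|))
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    m = loss.size
    out = loss.sum() / m

    def _backward(g):
        if logits.requires_grad:
            p = 1.0 / (1.0 + np.exp(-z))
            logits._accum((g * (p - y) / m).astype(np.float32))

    return Tensor(np.float32(out), parents=(logits,), backward=_backward)


class Adam:
    """Adam optimizer with L2 weight decay folded into the gradient."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * (g * g)
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
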