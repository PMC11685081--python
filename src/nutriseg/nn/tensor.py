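"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine implements exactly the operations the segmentation and regression
networks need: broadcasting arithmetic, matrix products, 2-D convolution
(via im2col and BLAS), 2x2 transposed convolution, 2x2 max pooling, channel
concatenation, ReLU/sigmoid, reductions, and numerically stable
binary-cross-entropy-with-logits.  Gradients flow through a topologically
sorted tape, as in any define-by-run framework.

All tensors are float32 by default; convolution inner products run in the
array's own dtype through BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=np.float32))

    @staticmethod
    def _make(data, parents, backward, requires_grad):
        out = Tensor(data, requires_grad=requires_grad)
        if requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None):
        """Backpropagate from this tensor (scalar by default) through the tape."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free the tape and interior grads as we go; leaves keep theirs
                node._backward = None
                node._parents = ()
                if node is not self:
                    node.grad = None

    # --------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other)
        rq = self.requires_grad or other.requires_grad
        data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return self._make(data, (self, other), backward, rq)

    __radd__ = __add__

    def __sub__(self, other):
        other = self._lift(other)
        rq = self.requires_grad or other.requires_grad
        data = self.data - other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g, other.data.shape))

        return self._make(data, (self, other), backward, rq)

    def __rsub__(self, other):
        return self._lift(other).__sub__(self)

    def __mul__(self, other):
        other = self._lift(other)
        rq = self.requires_grad or other.requires_grad
        data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return self._make(data, (self, other), backward, rq)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        rq = self.requires_grad or other.requires_grad
        data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        return self._make(data, (self, other), backward, rq)

    def __neg__(self):
        return self * -1.0

    # ------------------------------------------------------------ linear algebra
    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        rq = self.requires_grad or other.requires_grad
        data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return self._make(data, (self, other), backward, rq)

    __matmul__ = matmul

    # --------------------------------------------------------------- activations
    def relu(self) -> "Tensor":
        mask = self.data > 0
        data = self.data * mask

        def backward(g):
            self._accumulate(g * mask)

        return self._make(data, (self,), backward, self.requires_grad)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accumulate(g * s * (1.0 - s))

        return self._make(s, (self,), backward, self.requires_grad)

    def abs(self) -> "Tensor":
        sign = np.sign(self.data)
        data = np.abs(self.data)

        def backward(g):
            self._accumulate(g * sign)

        return self._make(data, (self,), backward, self.requires_grad)

    # ---------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False) -> "Tensor":
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(data, (self,), backward, self.requires_grad)

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape
        data = self.data.reshape(*shape)

        def backward(g):
            self._accumulate(g.reshape(old))

        return self._make(data, (self,), backward, self.requires_grad)

    # ------------------------------------------------------------------- conv ops
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0) -> "Tensor":
        """2-D convolution, NCHW input, OIHW weight, via im2col + GEMM."""
        x, w = self.data, weight.data
        B, C, H, W = x.shape
        O, Ci, kh, kw = w.shape
        if Ci != C:
            raise ValueError(f"conv2d channel mismatch: input {C}, weight expects {Ci}")
        s, p = stride, padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        Ho = (H + 2 * p - kh) // s + 1
        Wo = (W + 2 * p - kw) // s + 1
        win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(B * Ho * Wo, C * kh * kw)
        wmat = w.reshape(O, C * kh * kw)
        out = cols @ wmat.T
        if bias is not None:
            out += bias.data
        out = out.reshape(B, Ho, Wo, O).transpose(0, 3, 1, 2)
        rq = self.requires_grad or weight.requires_grad or (bias is not None and bias.requires_grad)

        def backward(g):
            g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(B * Ho * Wo, O)
            if weight.requires_grad:
                weight._accumulate((g2.T @ cols).reshape(O, C, kh, kw))
            if bias is not None and bias.requires_grad:
                bias._accumulate(g2.sum(axis=0))
            if self.requires_grad:
                gcols = (g2 @ wmat).reshape(B, Ho, Wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
                gxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=x.dtype)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += gcols[:, :, :, :, i, j]
                self._accumulate(gxp[:, :, p:p + H, p:p + W] if p else gxp)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return self._make(out, parents, backward, rq)

    def conv_transpose2x2(self, weight: "Tensor", bias: "Tensor | None" = None) -> "Tensor":
        """Transposed convolution with kernel 2, stride 2 (exact 2x upsampling).

        Weight layout IOHW: (C_in, C_out, 2, 2).  Because stride equals the
        kernel size the output blocks do not overlap.
        """
        x, w = self.data, weight.data
        B, C, H, W = x.shape
        Ci, O, kh, kw = w.shape
        if Ci != C or kh != 2 or kw != 2:
            raise ValueError("conv_transpose2x2 expects weight (C_in, C_out, 2, 2) matching input channels")
        # out[b,o,2h+i,2w+j] = sum_c x[b,c,h,w] * w[c,o,i,j]
        xm = x.transpose(0, 2, 3, 1).reshape(B * H * W, C)
        wmat = w.reshape(C, O * 4)
        out = (xm @ wmat).reshape(B, H, W, O, 2, 2).transpose(0, 3, 1, 4, 2, 5).reshape(B, O, 2 * H, 2 * W)
        if bias is not None:
            out = out + bias.data[None, :, None, None]
        rq = self.requires_grad or weight.requires_grad or (bias is not None and bias.requires_grad)

        def backward(g):
            gb = g.reshape(B, O, H, 2, W, 2).transpose(0, 2, 4, 1, 3, 5).reshape(B * H * W, O * 4)
            if weight.requires_grad:
                weight._accumulate((xm.T @ gb).reshape(C, O, 2, 2))
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                self._accumulate((gb @ wmat.T).reshape(B, H, W, C).transpose(0, 3, 1, 2))

        parents = (self, weight) if bias is None else (self, weight, bias)
        return self._make(out, parents, backward, rq)

    def maxpool2x2(self) -> "Tensor":
        x = self.data
        B, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"maxpool2x2 needs even spatial dims, got {H}x{W}")
        xv = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H // 2, W // 2, 4)
        idx = xv.argmax(axis=-1)
        out = np.take_along_axis(xv, idx[..., None], axis=-1)[..., 0]

        def backward(g):
            gx = np.zeros_like(xv)
            np.put_along_axis(gx, idx[..., None], g[..., None], axis=-1)
            self._accumulate(
                gx.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H, W)
            )

        return self._make(out, (self,), backward, self.requires_grad)

    def concat_channels(self, other: "Tensor") -> "Tensor":
        c1 = self.data.shape[1]
        data = np.concatenate([self.data, other.data], axis=1)
        rq = self.requires_grad or other.requires_grad

        def backward(g):
            if self.requires_grad:
                self._accumulate(g[:, :c1])
            if other.requires_grad:
                other._accumulate(g[:, c1:])

        return self._make(data, (self, other), backward, rq)

    def global_avg_pool(self) -> "Tensor":
        """(B, C, H, W) -> (B, C) spatial mean — the SE 'squeeze'."""
        B, C, H, W = self.data.shape
        data = self.data.mean(axis=(2, 3))

        def backward(g):
            self._accumulate(np.broadcast_to(g[:, :, None, None] / (H * W), self.data.shape).copy())

        return self._make(data, (self,), backward, self.requires_grad)

    # --------------------------------------------------------------------- losses
    def bce_with_logits(self, target: np.ndarray) -> "Tensor":
        """Mean binary cross-entropy on logits; gradient is (sigmoid(x) - t)/n."""
        x = self.data
        t = np.asarray(target, dtype=x.dtype)
        # log(1 + e^-|x|) + max(x, 0) - x*t  (stable form)
        loss = np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0) - x * t
        data = loss.mean()

        def backward(g):
            s = 1.0 / (1.0 + np.exp(-x))
            self._accumulate(g * (s - t) / x.size)

        return self._make(data, (self,), backward, self.requires_grad)
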