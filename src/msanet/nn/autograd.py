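"""Tape-based reverse-mode automatic differentiation on numpy arrays."""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np


class Tensor:
    """A numpy array plus the closures needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from a scalar tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.accumulate(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, tuple[int, int]]:
    """(C, H, W) -> (C*k*k, H_out*W_out) patch matrix."""
    c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad))) if pad else x
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    windows = windows[:, ::stride, ::stride, :, :]  # (C, H_out, W_out, k, k)
    _, h_out, w_out, _, _ = windows.shape
    cols = windows.transpose(0, 3, 4, 1, 2).reshape(c * k * k, h_out * w_out)
    return np.ascontiguousarray(cols), (h_out, w_out)


def _col2im(
    cols: np.ndarray, x_shape: tuple[int, int, int], k: int, stride: int, pad: int, out_hw: tuple[int, int]
) -> np.ndarray:
    """Scatter-add the transpose of im2col: patch-gradient -> input-gradient."""
    c, h, w = x_shape
    h_out, w_out = out_hw
    cols = cols.reshape(c, k, k, h_out, w_out)
    xp = np.zeros((c, h + 2 * pad, w + 2 * pad))
    for i in range(k):
        for j in range(k):
            xp[:, i : i + h_out * stride : stride, j : j + w_out * stride : stride] += cols[:, i, j]
    return xp[:, pad : pad + h, pad : pad + w] if pad else xp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1) -> Tensor:
    """Same-padded 2-D convolution: (C,H,W) x (O,C,k,k) -> (O,H/stride,W/stride)."""
    o, c, k, _ = weight.shape
    pad = k // 2
    cols, out_hw = _im2col(x.data, k, stride, pad)
    w_flat = weight.data.reshape(o, c * k * k)
    out = (w_flat @ cols + bias.data[:, None]).reshape(o, *out_hw)

    def backward(g: np.ndarray) -> None:
        g_flat = g.reshape(o, -1)
        if weight.requires_grad:
            weight.accumulate((g_flat @ cols.T).reshape(weight.shape))
        if bias.requires_grad:
            bias.accumulate(g_flat.sum(axis=1))
        if x.requires_grad:
            x.accumulate(_col2im(w_flat.T @ g_flat, x.data.shape, k, stride, pad, out_hw))

    return Tensor(out, parents=(x, weight, bias), backward=backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate(g * mask)

    return Tensor(x.data * mask, parents=(x,), backward=backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate(g * s * (1.0 - s))

    return Tensor(s, parents=(x,), backward=backward)


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    """Nearest-neighbor upsampling of (C, H, W) by an integer factor."""
    out = np.repeat(np.repeat(x.data, factor, axis=1), factor, axis=2)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            c, h, w = x.data.shape
            x.accumulate(g.reshape(c, h, factor, w, factor).sum(axis=(2, 4)))

    return Tensor(out, parents=(x,), backward=backward)


def concat_channels(tensors: Sequence[Tensor]) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=0)
    splits = np.cumsum([t.data.shape[0] for t in tensors])[:-1]

    def backward(g: np.ndarray) -> None:
        for t, piece in zip(tensors, np.split(g, splits, axis=0)):
            if t.requires_grad:
                t.accumulate(piece)

    return Tensor(out, parents=tuple(tensors), backward=backward)


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean over all elements of the squared difference to a constant target."""
    target = np.asarray(target, dtype=np.float64)
    diff = pred.data - target

    def backward(g: np.ndarray) -> None:
        if pred.requires_grad:
            pred.accumulate(g * 2.0 * diff / diff.size)

    return Tensor(np.array((diff * diff).mean()), parents=(pred,), backward=backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(g)
        if b.requires_grad:
            b.accumulate(g)

    return Tensor(a.data + b.data, parents=(a, b), backward=backward)


def scale(x: Tensor, alpha: float) -> Tensor:
    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate(g * alpha)

    return Tensor(x.data * alpha, parents=(x,), backward=backward)
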