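"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operations the recurrent child models and the
denoising autoencoder need: affine maps, the four cell activations,
mean-pooling, mean-squared error and softmax cross-entropy, plus an
Adam optimizer.  Everything is deterministic given a seeded
``numpy.random.Generator``.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "matmul",
    "add",
    "mul",
    "tanh",
    "relu",
    "sigmoid",
    "identity",
    "mean_tensors",
    "scale",
    "mse_loss",
    "softmax_cross_entropy",
    "softmax",
    "Adam",
    "ACTIVATION_FNS",
]


class Tensor:
    """A numpy array with an accumulated gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Reverse-mode sweep from this (scalar) tensor."""
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def bwd(g: np.ndarray) -> None:
        if a.requires_grad or a._parents:
            a._accumulate(g @ b.data.T)
        if b.requires_grad or b._parents:
            b._accumulate(a.data.T @ g)

    return Tensor(out_data, parents=(a, b), backward=bwd)


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bwd(g: np.ndarray) -> None:
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bwd(g: np.ndarray) -> None:
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


def scale(a: Tensor, c: float) -> Tensor:
    def bwd(g: np.ndarray) -> None:
        a._accumulate(g * c)

    return Tensor(a.data * c, parents=(a,), backward=bwd)


def tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)

    def bwd(g: np.ndarray) -> None:
        a._accumulate(g * (1.0 - out_data**2))

    return Tensor(out_data, parents=(a,), backward=bwd)


def relu(a: Tensor) -> Tensor:
    out_data = np.maximum(a.data, 0.0)

    def bwd(g: np.ndarray) -> None:
        a._accumulate(g * (a.data > 0.0))

    return Tensor(out_data, parents=(a,), backward=bwd)


def sigmoid(a: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60.0, 60.0)))

    def bwd(g: np.ndarray) -> None:
        a._accumulate(g * out_data * (1.0 - out_data))

    return Tensor(out_data, parents=(a,), backward=bwd)


def identity(a: Tensor) -> Tensor:
    def bwd(g: np.ndarray) -> None:
        a._accumulate(g)

    return Tensor(a.data, parents=(a,), backward=bwd)


ACTIVATION_FNS: dict[str, Callable[[Tensor], Tensor]] = {
    "tanh": tanh,
    "relu": relu,
    "identity": identity,
    "sigmoid": sigmoid,
}


def mean_tensors(tensors: Sequence[Tensor]) -> Tensor:
    """Element-wise mean of same-shape tensors (terminal-node pooling)."""
    k = len(tensors)
    out_data = sum(t.data for t in tensors) / k

    def bwd(g: np.ndarray) -> None:
        for t in tensors:
            t._accumulate(g / k)

    return Tensor(out_data, parents=tuple(tensors), backward=bwd)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    target = np.asarray(target, dtype=np.float64)
    diff = pred.data - target

    def bwd(g: np.ndarray) -> None:
        pred._accumulate(g * 2.0 * diff / diff.size)

    return Tensor(np.mean(diff**2), parents=(pred,), backward=bwd)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy over a batch of integer class labels."""
    labels = np.asarray(labels, dtype=np.intp)
    probs = softmax(logits.data)
    n = logits.data.shape[0]
    nll = -np.log(np.clip(probs[np.arange(n), labels], 1e-12, None))

    def bwd(g: np.ndarray) -> None:
        grad = probs.copy()
        grad[np.arange(n), labels] -= 1.0
        logits._accumulate(g * grad / n)

    return Tensor(np.mean(nll), parents=(logits,), backward=bwd)


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 0.01,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
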