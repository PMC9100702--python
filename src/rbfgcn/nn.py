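"""Spectral GCN building blocks with analytic gradients.

The propagation rule is the symmetric-normalized graph convolution

    H^(k+1) = sigma( S H^(k) W^(k) ),        S = D~^{-1/2} (A + I) D~^{-1/2},

and its ANNA-augmented variant, which re-injects each node's own (native)
attributes through a learnable scalar gain alpha per layer:

    H^(k+1) = sigma( (S H^(k) + alpha^(k) H^(k)) W^(k) ).

At alpha = 0 the ANNA layer reduces exactly to the plain GCN layer. The
classifier head is a 2-layer MLP followed by log-softmax.

Everything here operates on numpy arrays, batched along a leading subject
axis: ``S`` has shape ``(n, m, m)`` and activations ``(n, m, d)``. Gradients
are computed by hand-written backpropagation (verified against finite
differences in the test suite), and optimized with Adam.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "NormalizedAdjacency",
    "GCNLayerParams",
    "MLPParams",
    "normalize_adjacency",
    "gcn_layer_forward",
    "anna_layer_forward",
    "mlp_forward",
    "log_softmax",
    "nll_loss",
    "xavier_normal",
    "GCNStack",
    "MLP",
    "Adam",
]

_ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(z.dtype)),
    "identity": (lambda z: z, lambda z: np.ones_like(z)),
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
}


def _act(name: str):
    try:
        return _ACTIVATIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown activation {name!r}; choose from {sorted(_ACTIVATIONS)}"
        ) from None


@dataclass(frozen=True)
class NormalizedAdjacency:
    """Precomputed ``D~^{-1/2} (A + I) D~^{-1/2}`` for one graph."""

    matrix: np.ndarray


def normalize_adjacency(A: np.ndarray) -> NormalizedAdjacency:
    """Symmetric renormalization with self-loops.

    ``A`` must be square, symmetric and nonnegative. The self-loop guarantees
    every degree ``D~_ii >= 1``, so the normalization is always well defined.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got {A.shape}")
    if np.abs(A - A.T).max(initial=0.0) > 1e-8:
        raise ValueError("adjacency must be symmetric")
    if A.size and A.min() < 0:
        raise ValueError("adjacency must be nonnegative")
    A_tilde = A + np.eye(A.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(A_tilde.sum(axis=1))
    S = A_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    return NormalizedAdjacency(S)


@dataclass
class GCNLayerParams:
    """Weights of one (optionally ANNA-augmented) GCN layer.

    ``anna_gain`` is ``None`` for a plain GCN layer and a trainable scalar for
    an ANNA layer; GCN layers carry no bias.
    """

    weight: np.ndarray
    anna_gain: float | None = None
    activation: str = "relu"


@dataclass
class MLPParams:
    """A 2-layer fully connected head; log-softmax is applied downstream."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    activation: str = "relu"


def _as_batched(S_or_nadj, H):
    S = S_or_nadj.matrix if isinstance(S_or_nadj, NormalizedAdjacency) else np.asarray(S_or_nadj)
    H = np.asarray(H, dtype=float)
    squeeze = H.ndim == 2
    if squeeze:
        H = H[None]
    if S.ndim == 2:
        S = S[None]
    return S, H, squeeze


def gcn_layer_forward(nadj, H, params: GCNLayerParams) -> np.ndarray:
    """One plain GCN propagation step ``sigma(S H W)``."""
    S, Hb, squeeze = _as_batched(nadj, H)
    if Hb.shape[-1] != params.weight.shape[0]:
        raise ValueError(
            f"input width {Hb.shape[-1]} does not match weight "
            f"shape {params.weight.shape}"
        )
    act, _ = _act(params.activation)
    out = act(np.matmul(np.matmul(S, Hb), params.weight))
    return out[0] if squeeze else out


def anna_layer_forward(nadj, H, params: GCNLayerParams) -> np.ndarray:
    """One ANNA step ``sigma((S H + alpha H) W)``; alpha=0 recovers the GCN step."""
    if params.anna_gain is None:
        raise ValueError("anna_layer_forward requires params.anna_gain")
    S, Hb, squeeze = _as_batched(nadj, H)
    if Hb.shape[-1] != params.weight.shape[0]:
        raise ValueError(
            f"input width {Hb.shape[-1]} does not match weight "
            f"shape {params.weight.shape}"
        )
    act, _ = _act(params.activation)
    M = np.matmul(S, Hb) + params.anna_gain * Hb
    out = act(np.matmul(M, params.weight))
    return out[0] if squeeze else out


def mlp_forward(features: np.ndarray, params: MLPParams) -> np.ndarray:
    """Two affine layers with a nonlinearity between; returns raw class scores."""
    x = np.asarray(features, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[None]
    if x.shape[1] != params.W1.shape[0]:
        raise ValueError(
            f"feature width {x.shape[1]} does not match W1 {params.W1.shape}"
        )
    act, _ = _act(params.activation)
    z = act(x @ params.W1 + params.b1) @ params.W2 + params.b2
    return z[0] if squeeze else z


def log_softmax(scores: np.ndarray) -> np.ndarray:
    """Row-wise log-softmax."""
    scores = np.asarray(scores, dtype=float)
    return scores - logsumexp(scores, axis=-1, keepdims=True)


def nll_loss(log_probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-likelihood of the true classes."""
    labels = np.asarray(labels)
    return float(-log_probs[np.arange(len(labels)), labels].mean())


def xavier_normal(rng: np.random.Generator, fan_in: int, fan_out: int,
                  gain: float = 1.0) -> np.ndarray:
    """Xavier (Glorot) normal initialization, std = gain*sqrt(2/(fan_in+fan_out))."""
    std = gain * np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, std, size=(fan_in, fan_out))


class GCNStack:
    """A stack of GCN or ANNA layers applied to batched graphs.

    Parameters live in ``self.layers`` (a list of :class:`GCNLayerParams`);
    ``forward`` caches intermediates so ``backward`` can return gradients for
    every weight matrix and every ANNA gain.
    """

    def __init__(self, widths: list[int], use_anna: bool,
                 rng: np.random.Generator, activation: str = "relu",
                 anna_init: float = 0.0):
        self.use_anna = use_anna
        self.layers = [
            GCNLayerParams(
                weight=xavier_normal(rng, widths[i], widths[i + 1]),
                anna_gain=anna_init if use_anna else None,
                activation=activation,
            )
            for i in range(len(widths) - 1)
        ]
        self._cache = None

    def forward(self, S: np.ndarray, H: np.ndarray) -> np.ndarray:
        """Run the stack; S is (n,m,m), H is (n,m,d0). Returns (n,m,d_last)."""
        cache = []
        for p in self.layers:
            alpha = p.anna_gain if p.anna_gain is not None else 0.0
            M = np.matmul(S, H) + alpha * H if alpha != 0.0 else np.matmul(S, H)
            Z = np.matmul(M, p.weight)
            act, _ = _act(p.activation)
            cache.append((H, M, Z))
            H = act(Z)
        self._cache = (S, cache)
        return H

    def backward(self, dH: np.ndarray) -> dict[str, np.ndarray]:
        """Backprop through the cached forward pass.

        Returns gradients keyed ``W0, W1, ...`` and ``alpha0, ...`` (ANNA only),
        and stores the gradient w.r.t. the input attributes in ``self.dX``.
        """
        S, cache = self._cache
        grads: dict[str, np.ndarray] = {}
        for k in range(len(self.layers) - 1, -1, -1):
            p = self.layers[k]
            H_in, M, Z = cache[k]
            _, dact = _act(p.activation)
            dZ = dH * dact(Z)
            grads[f"W{k}"] = np.einsum("nmi,nmj->ij", M, dZ)
            dM = np.matmul(dZ, p.weight.T)
            if p.anna_gain is not None:
                grads[f"alpha{k}"] = np.array(np.sum(H_in * dM))
                dH = np.matmul(np.swapaxes(S, -1, -2), dM) + p.anna_gain * dM
            else:
                dH = np.matmul(np.swapaxes(S, -1, -2), dM)
        self.dX = dH
        return grads

    def get_params(self) -> dict[str, np.ndarray]:
        out = {}
        for k, p in enumerate(self.layers):
            out[f"W{k}"] = p.weight
            if p.anna_gain is not None:
                out[f"alpha{k}"] = np.array(p.anna_gain, dtype=float)
        return out

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k, p in enumerate(self.layers):
            p.weight = np.asarray(params[f"W{k}"], dtype=float)
            if p.anna_gain is not None:
                p.anna_gain = float(params[f"alpha{k}"])


class MLP:
    """Trainable 2-layer perceptron head with cached backprop."""

    def __init__(self, widths: tuple[int, int, int], rng: np.random.Generator,
                 activation: str = "relu"):
        d_in, d_hidden, d_out = widths
        self.params = MLPParams(
            W1=xavier_normal(rng, d_in, d_hidden),
            b1=np.zeros(d_hidden),
            W2=xavier_normal(rng, d_hidden, d_out),
            b2=np.zeros(d_out),
            activation=activation,
        )
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.params
        act, _ = _act(p.activation)
        z1 = x @ p.W1 + p.b1
        a1 = act(z1)
        z2 = a1 @ p.W2 + p.b2
        self._cache = (x, z1, a1)
        return z2

    def backward(self, dz2: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        x, z1, a1 = self._cache
        _, dact = _act(p.activation)
        grads = {
            "W2": a1.T @ dz2,
            "b2": dz2.sum(axis=0),
        }
        da1 = dz2 @ p.W2.T
        dz1 = da1 * dact(z1)
        grads["W1"] = x.T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        self.dX = dz1 @ p.W1.T
        return grads

    def get_params(self) -> dict[str, np.ndarray]:
        p = self.params
        return {"W1": p.W1, "b1": p.b1, "W2": p.W2, "b2": p.b2}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        p = self.params
        p.W1, p.b1 = np.asarray(params["W1"]), np.asarray(params["b1"])
        p.W2, p.b2 = np.asarray(params["W2"]), np.asarray(params["b2"])


class Adam:
    """Adam optimizer over a flat dict of named parameter arrays."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        """Return updated parameters (new arrays; inputs are not mutated)."""
        self.t += 1
        out = {}
        for name, value in params.items():
            g = np.asarray(grads[name], dtype=float)
            m = self._m.get(name, np.zeros_like(g))
            v = self._v.get(name, np.zeros_like(g))
            m = self.beta1 * m + (1 - self.beta1) * g
            v = self.beta2 * v + (1 - self.beta2) * g * g
            self._m[name], self._v[name] = m, v
            m_hat = m / (1 - self.beta1 ** self.t)
            v_hat = v / (1 - self.beta2 ** self.t)
            out[name] = value - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
        return out
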