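"""Meta-path node embedding: GRU encoder, attentive pooling, two fusions.

Each meta-path instance's projected node features are run through a GRU
(update/reset gates, tanh candidate, dropout on the update term); the
state matrix is pooled with K independent attention heads whose outputs
are averaged; instances of one meta-path type are fused by a softmax
attention with a ReLU score and a sigmoid on the weighted sum; the type
vectors are fused by a second softmax attention (no sigmoid) into the
pair's node embedding.

Plain-numpy reference semantics mirrored by the batched autodiff forward
in the estimator (agreement is tested).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pair_model import dropout_fn

__all__ = [
    "GRUParams", "AttentionParams", "gru_step", "encode_instance",
    "attentive_pool", "fuse_instances", "fuse_types",
]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _softmax(x):
    e = np.exp(x - np.max(x))
    return e / e.sum()


@dataclass
class GRUParams:
    """Gate/candidate weights (X x Z input, X x X hidden), biases, dropout."""

    W_zx: np.ndarray
    W_rx: np.ndarray
    W_hx: np.ndarray
    W_zh: np.ndarray
    W_rh: np.ndarray
    W_hh: np.ndarray
    b_z: np.ndarray
    b_r: np.ndarray
    b_h: np.ndarray
    q: float = 0.5

    def __post_init__(self):
        X, Z = self.W_zx.shape
        for W in (self.W_rx, self.W_hx):
            if W.shape != (X, Z):
                raise ValueError("input weight shapes inconsistent")
        for W in (self.W_zh, self.W_rh, self.W_hh):
            if W.shape != (X, X):
                raise ValueError("hidden weight shapes inconsistent")
        for b in (self.b_z, self.b_r, self.b_h):
            if b.shape != (X,):
                raise ValueError("bias shapes inconsistent")
        if not (0.0 <= self.q < 1.0):
            raise ValueError("dropout rate must lie in [0, 1)")

    @property
    def X(self) -> int:
        return self.W_zx.shape[0]


@dataclass
class AttentionParams:
    """Pooling heads M (K x X); per-type fusion vectors att_p / att_P."""

    M: np.ndarray              # (K, X)
    att_p: dict                # type string -> (X,)
    att_P: dict                # type string -> (X,)

    def __post_init__(self):
        if self.M.ndim != 2 or self.M.shape[0] < 1:
            raise ValueError("need at least one attention head")

    @property
    def K(self) -> int:
        return self.M.shape[0]


def gru_step(x_t: np.ndarray, h_prev: np.ndarray, params: GRUParams,
             train: bool = False,
             rng: np.random.Generator | None = None) -> np.ndarray:
    """One GRU step: h_t = z*h_prev + (1-z)*dropout(g_t)."""
    if x_t.shape[-1] != params.W_zx.shape[1]:
        raise ValueError("input size does not match GRU parameters")
    z = _sigmoid(params.W_zx @ x_t + params.W_zh @ h_prev + params.b_z)
    r = _sigmoid(params.W_rx @ x_t + params.W_rh @ h_prev + params.b_r)
    g = np.tanh(params.W_hx @ x_t + params.W_hh @ (r * h_prev) + params.b_h)
    return z * h_prev + (1.0 - z) * dropout_fn(g, params.q, train, rng)


def encode_instance(node_features: np.ndarray, params: GRUParams,
                    train: bool = False,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """State matrix (n_nodes x X) from sequential GRU steps over an instance.

    Row t is the hidden state after consuming the t-th node's projected
    feature; the initial state is zero.
    """
    feats = np.asarray(node_features, dtype=float)
    if feats.ndim != 2 or feats.shape[0] == 0:
        raise ValueError("instance must supply a non-empty feature sequence")
    h = np.zeros(params.X)
    states = []
    for x_t in feats:
        h = gru_step(x_t, h, params, train, rng)
        states.append(h)
    return np.stack(states)


def attentive_pool(h: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Average of K attention-weighted sums of the state rows."""
    h = np.asarray(h, dtype=float)
    if h.ndim != 2 or h.shape[0] == 0:
        raise ValueError("state matrix must be non-empty")
    pooled = np.zeros(h.shape[1])
    for k in range(params.K):
        alpha = _softmax(h @ params.M[k])
        pooled += alpha @ h
    return pooled / params.K


def fuse_instances(pooled: list, att_p: np.ndarray) -> np.ndarray:
    """Fuse one type's pooled instance vectors: softmax(ReLU scores), then
    sigmoid of the weighted sum."""
    if len(pooled) == 0:
        raise ValueError("cannot fuse an empty instance list")
    H = np.stack(pooled)
    e = np.maximum(0.0, H @ att_p)
    w = _softmax(e)
    return _sigmoid(w @ H)


def fuse_types(type_vectors: dict, att_P: dict) -> np.ndarray:
    """Fuse the per-type vectors into the pair's node embedding (no sigmoid)."""
    if len(type_vectors) == 0:
        raise ValueError("cannot fuse an empty type map")
    types = list(type_vectors)
    H = np.stack([type_vectors[t] for t in types])
    scores = np.array([max(0.0, type_vectors[t] @ att_P[t]) for t in types])
    w = _softmax(scores)
    return w @ H
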