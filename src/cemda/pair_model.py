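"""Pair embedding: projection, pair-composite MLP, and validity loss.

Raw features (a node's row of the integrated similarity matrix) are
projected to a shared Z-dimensional space; a (miRNA, disease) pair is
composed as ``[h_r ; h_d ; h_r*h_d ; h_r+h_d]`` and embedded by an MLP
whose hidden layers use ReLU and dropout and whose last layer is affine.
A two-layer validity head scores the pair; its binary cross-entropy
against the association label is Loss_N.

These are plain-numpy reference semantics; the estimator reuses the same
arithmetic through the autodiff engine and is tested to agree with them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProjectionParams", "PairMLPParams", "project_node", "combine_pair",
    "dropout_fn", "pair_embed", "validity_logit", "validity_loss",
]


@dataclass
class ProjectionParams:
    """Linear projections W_R (Z x m) and W_D (Z x n) to the shared space."""

    W_R: np.ndarray
    W_D: np.ndarray

    def __post_init__(self):
        if not (np.isfinite(self.W_R).all() and np.isfinite(self.W_D).all()):
            raise ValueError("projection weights must be finite")
        if self.W_R.shape[0] != self.W_D.shape[0]:
            raise ValueError("W_R and W_D must share the output dimension Z")

    @property
    def Z(self) -> int:
        return self.W_R.shape[0]


@dataclass
class PairMLPParams:
    """MLP layer weights/biases (input 4Z -> hidden -> output X) plus the
    two-layer validity head pi (X -> hidden -> 1)."""

    weights: list  # W^(l), each (out, in)
    biases: list
    pi_weights: list = field(default_factory=list)
    pi_biases: list = field(default_factory=list)
    dropout: float = 0.5

    def __post_init__(self):
        for W, b, Wn in zip(self.weights, self.biases, self.weights[1:]):
            if W.shape[0] != b.shape[0] or Wn.shape[1] != W.shape[0]:
                raise ValueError("MLP layer shapes do not chain")


def project_node(x: np.ndarray, W: np.ndarray) -> np.ndarray:
    """h = W @ x, the exact matrix-vector projection."""
    x = np.asarray(x, dtype=float)
    if W.shape[1] != x.shape[-1]:
        raise ValueError(f"projection expects length {W.shape[1]}, got {x.shape[-1]}")
    return x @ W.T if x.ndim > 1 else W @ x


def combine_pair(h_r: np.ndarray, h_d: np.ndarray) -> np.ndarray:
    """Composite pair vector [h_r ; h_d ; h_r*h_d ; h_r+h_d] of length 4Z."""
    h_r, h_d = np.asarray(h_r, float), np.asarray(h_d, float)
    if h_r.shape != h_d.shape:
        raise ValueError("pair halves must have equal length")
    return np.concatenate([h_r, h_d, h_r * h_d, h_r + h_d], axis=-1)


def dropout_fn(x: np.ndarray, q: float, train: bool,
               rng: np.random.Generator | None = None) -> np.ndarray:
    """Bernoulli(1-q) mask in train mode; (1-q)-scaling in eval mode."""
    if q == 0.0:
        return x
    if train:
        if rng is None:
            raise ValueError("train-mode dropout needs an rng")
        return x * rng.binomial(1, 1.0 - q, size=x.shape)
    return (1.0 - q) * x


def pair_embed(h0: np.ndarray, params: PairMLPParams, train: bool = False,
               rng: np.random.Generator | None = None) -> np.ndarray:
    """Forward the composite vector through the MLP; last layer is affine."""
    h = np.asarray(h0, dtype=float)
    last = len(params.weights) - 1
    for l, (W, b) in enumerate(zip(params.weights, params.biases)):
        h = h @ W.T + b
        if l < last:
            h = dropout_fn(np.maximum(0.0, h), params.dropout, train, rng)
    return h


def validity_logit(g: np.ndarray, params: PairMLPParams) -> np.ndarray:
    """Two-layer ReLU perceptron pi mapping the pair embedding to a logit."""
    h = np.asarray(g, dtype=float)
    last = len(params.pi_weights) - 1
    for l, (W, b) in enumerate(zip(params.pi_weights, params.pi_biases)):
        h = h @ W.T + b
        if l < last:
            h = np.maximum(0.0, h)
    return h[..., 0] if h.shape[-1] == 1 else h


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    return np.where(x >= 0, -np.log1p(np.exp(-np.abs(x))),
                    x - np.log1p(np.exp(x)))


def validity_loss(logits: np.ndarray, y: np.ndarray) -> float:
    """Batch-mean binary cross-entropy of sigmoid(pi(g)) against y (Loss_N)."""
    logits = np.atleast_1d(np.asarray(logits, float))
    y = np.atleast_1d(np.asarray(y, float))
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary")
    return float(np.mean(-y * _log_sigmoid(logits) - (1 - y) * _log_sigmoid(-logits)))
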