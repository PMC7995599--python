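"""Training-facing functions: losses, negative sampling, run orchestration.

Thin wrappers over :class:`~cemda.estimator.CombinedEmbeddingPredictor`;
the loss functions are plain-numpy reference implementations of the three
objective components and their combination.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np

from .dataset import MDADataset
from .estimator import CombinedEmbeddingPredictor
from .io import AssociationMatrix, PredictionTable
from .pair_model import _log_sigmoid

__all__ = ["LossReport", "TrainConfig", "association_score",
           "node_embedding_loss", "total_loss", "sample_negatives",
           "train", "rank_candidates"]


@dataclass
class LossReport:
    """One epoch's loss components; total = N + lambda*M + (1-lambda)*reg."""

    loss_N: float
    loss_M: float
    loss_reg: float
    lam: float = 0.5

    @property
    def total(self) -> float:
        return total_loss(self.loss_N, self.loss_M, self.loss_reg, self.lam)


@dataclass
class TrainConfig:
    """All tunable settings of a training run (mirrors the estimator)."""

    embed_dim: int = 256
    proj_dim: int | None = None
    mlp_hidden: int = 100
    pi_hidden: int = 100
    n_heads: int = 4
    dropout: float = 0.5
    delta: float = 0.5
    alpha0: float = 1.0
    l_max: int = 3
    edge_rule: str = "top_k"
    top_k: int = 5
    tau: float = 0.5
    allow_revisits: bool = False
    exclude_direct: bool = True
    max_instances_per_type: int = 20
    lr: float = 0.02
    n_epochs: int = 100
    negative_ratio: float = 1.0
    lambda_: float = 0.5
    weight_decay: float = 1e-4
    use_pair_branch: bool = True
    resample_negatives: bool = True
    random_state: int = 0

    def make_estimator(self) -> CombinedEmbeddingPredictor:
        return CombinedEmbeddingPredictor(**asdict(self))

    @classmethod
    def desk_scale(cls, random_state: int = 0, **overrides) -> "TrainConfig":
        """Scaled-down configuration used for the package's own benchmark
        studies: narrow embeddings, denser similarity edges and a higher
        per-type instance cap, sized so a fit takes tens of seconds on one
        CPU (see docs/methods.md for the rationale behind each value)."""
        base = dict(embed_dim=16, dropout=0.2, weight_decay=1e-4, lr=0.02,
                    n_epochs=120, max_instances_per_type=16, top_k=8,
                    random_state=random_state)
        base.update(overrides)
        return cls(**base)


def association_score(h_node: np.ndarray, g_pair: np.ndarray,
                      w: np.ndarray, b: float) -> float:
    """sigmoid(w . [h_node ; g_pair] + b): the combined-head probability."""
    feats = np.concatenate([np.asarray(h_node, float), np.asarray(g_pair, float)])
    logit = float(np.dot(np.ravel(w), feats) + float(b))
    return float(1.0 / (1.0 + np.exp(-logit)))


def node_embedding_loss(scores_pos, scores_neg) -> float:
    """Mean negative-sampling log loss of the node-branch logits (Loss_M)."""
    pos = np.atleast_1d(np.asarray(scores_pos, float))
    neg = np.atleast_1d(np.asarray(scores_neg, float))
    if pos.size == 0:
        raise ValueError("empty positive batch")
    terms = np.concatenate([-_log_sigmoid(pos), -_log_sigmoid(-neg)])
    return float(terms.mean())


def total_loss(loss_N: float, loss_M: float, loss_reg: float,
               lam: float = 0.5) -> float:
    """Loss = Loss_N + lambda*Loss_M + (1-lambda)*Loss_reg."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    return float(loss_N + lam * loss_M + (1.0 - lam) * loss_reg)


def sample_negatives(A: AssociationMatrix, ratio: float = 1.0,
                     seed: int = 0) -> list:
    """Uniform without-replacement draw of unconfirmed (miRNA, disease) pairs.

    Sample size is ``round(ratio * |positives|)``; raises if the matrix has
    too few zero cells.
    """
    if ratio < 1.0:
        raise ValueError("negative ratio must be >= 1")
    zeros = np.argwhere(A.values == 0)
    count = int(round(ratio * int(A.values.sum())))
    if count > len(zeros):
        raise ValueError(
            f"requested {count} negatives but only {len(zeros)} zero cells")
    rng = np.random.default_rng(seed)
    picked = zeros[rng.choice(len(zeros), size=count, replace=False)]
    return [(A.mirna_names[i], A.disease_names[j]) for i, j in picked]


def train(dataset: MDADataset, config: TrainConfig):
    """Fit a predictor under `config`; returns (estimator, per-epoch log)."""
    est = config.make_estimator().fit(dataset)
    return est, est.loss_log_


def rank_candidates(dataset: MDADataset, target_disease: str,
                    config: TrainConfig, mode: str = "standard",
                    top: int | None = None) -> PredictionTable:
    """Train and rank candidate miRNAs for one disease.

    ``standard`` fits on the full matrix and excludes confirmed pairs;
    ``new_disease`` zeroes the target's column before similarity, network
    and training so the disease enters with no known miRNAs, then ranks
    every miRNA.
    """
    if target_disease not in dataset.A.disease_names:
        raise KeyError(f"unknown disease {target_disease!r}")
    if mode == "standard":
        est = config.make_estimator().fit(dataset)
        return est.rank_candidates(target_disease, exclude_confirmed=True, top=top)
    if mode == "new_disease":
        est = config.make_estimator().fit(dataset.masked_disease(target_disease))
        return est.rank_candidates(target_disease, exclude_confirmed=True, top=top)
    raise ValueError(f"unknown mode {mode!r}")
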