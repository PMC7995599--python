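"""Scikit-learn style estimator for combined-embedding association prediction.

``CombinedEmbeddingPredictor.fit`` takes an :class:`~cemda.dataset.MDADataset`
(association matrix + disease DAGs + miRNA functional similarity), computes
the integrated similarity networks, assembles the heterogeneous network,
enumerates meta-path instances for the training pairs (confirmed positives
plus sampled negatives) and minimises

    Loss = Loss_N + lambda * Loss_M + (1 - lambda) * Loss_reg

with full-batch Adam, where Loss_N is the pair-validity cross-entropy,
Loss_M the negative-sampling cross-entropy of the meta-path node embedding
logit, and Loss_reg a weight-decay functional.  The combined scoring head
over ``[h_node ; g_pair]`` is trained jointly as a stop-gradient probe, so
the representation objective is exactly the expression above.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import autodiff as ad
from ._forward import (bce_with_logits, build_path_batch, init_params,
                       l2_penalty, model_forward)
from .dataset import MDADataset
from .hetnet import EdgeRule, build_network
from .io import PredictionTable
from .similarity import build_integrated_similarities

__all__ = ["CombinedEmbeddingPredictor"]


class CombinedEmbeddingPredictor(BaseEstimator):
    """Predicts unobserved miRNA-disease associations from a combined
    pair embedding and meta-path node embedding.

    Parameters
    ----------
    embed_dim : output width X of the pair embedding and GRU state.
    proj_dim : projection width Z (defaults to ``embed_dim``; the full-scale
        default is 256 for both).
    mlp_hidden, pi_hidden : hidden widths of the pair MLP and validity head.
    n_heads : attention heads K for meta-path pooling.
    dropout : dropout rate q (Bernoulli mask in training, (1-q)-scaling at
        evaluation) shared by the MLP hidden layer and the GRU update.
    delta : semantic attenuation factor for disease DAG contributions.
    alpha0 : initial Gaussian-kernel bandwidth.
    l_max : maximum meta-path length in edges.
    edge_rule, top_k, tau : similarity-to-edge sparsifier (see `hetnet`).
    max_instances_per_type : per-pair cap on instances fed to the GRU for
        each meta-path type (deterministic: the first in sorted order).
    lr, n_epochs, negative_ratio, lambda_, weight_decay : optimisation
        settings; training is full-batch Adam.
    use_pair_branch : disable to ablate the pair embedding (Loss_N dropped,
        scoring from the node branch alone).
    random_state : seeds negative sampling, initialisation and dropout.
    """

    def __init__(self, embed_dim=256, proj_dim=None, mlp_hidden=100,
                 pi_hidden=100, n_heads=4, dropout=0.5, delta=0.5,
                 alpha0=1.0, l_max=3, edge_rule="top_k", top_k=5, tau=0.5,
                 allow_revisits=False, max_instances_per_type=20, exclude_direct=True,
                 lr=0.02, n_epochs=100, negative_ratio=1.0, lambda_=0.5,
                 weight_decay=1e-4, use_pair_branch=True, resample_negatives=True,
                 random_state=0):
        self.embed_dim = embed_dim
        self.proj_dim = proj_dim
        self.mlp_hidden = mlp_hidden
        self.pi_hidden = pi_hidden
        self.n_heads = n_heads
        self.dropout = dropout
        self.delta = delta
        self.alpha0 = alpha0
        self.l_max = l_max
        self.edge_rule = edge_rule
        self.top_k = top_k
        self.tau = tau
        self.allow_revisits = allow_revisits
        self.exclude_direct = exclude_direct
        self.max_instances_per_type = max_instances_per_type
        self.lr = lr
        self.n_epochs = n_epochs
        self.negative_ratio = negative_ratio
        self.lambda_ = lambda_
        self.weight_decay = weight_decay
        self.use_pair_branch = use_pair_branch
        self.resample_negatives = resample_negatives
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------

    def _rule(self) -> EdgeRule:
        return EdgeRule(kind=self.edge_rule, k=self.top_k, tau=self.tau)

    def _batch_for(self, pairs):
        A = self.dataset_.A
        mi = {r: i for i, r in enumerate(A.mirna_names)}
        di = {d: j for j, d in enumerate(A.disease_names)}
        return build_path_batch(
            self.network_, pairs, mi, di, l_max=self.l_max,
            max_instances_per_type=self.max_instances_per_type,
            allow_revisits=self.allow_revisits,
            instance_cache=self._instance_cache_,
            exclude_direct=self.exclude_direct)

    def _forward(self, pairs, train=False, rng=None):
        A = self.dataset_.A
        r_idx = np.array([A.mirna_index(r) for r, _ in pairs])
        d_idx = np.array([A.disease_index(d) for _, d in pairs])
        batch = self._batch_for(pairs)
        return model_forward(
            self.params_, self.sm_.values, self.sd_.values, r_idx, d_idx,
            batch, n_heads=self.n_heads, dropout=self.dropout, train=train,
            rng=rng, use_pair_branch=self.use_pair_branch)

    # -- estimator API ---------------------------------------------------

    def fit(self, X: MDADataset, y=None):
        """Fit on a dataset bundle; `y` is ignored (labels live in X.A)."""
        if not isinstance(X, MDADataset):
            raise TypeError("fit expects an MDADataset")
        from .training import sample_negatives  # local import avoids a cycle

        rng = np.random.default_rng(self.random_state)
        self.dataset_ = X
        A = X.A
        self.sm_, self.sd_ = build_integrated_similarities(
            A, X.dags, X.fs, delta=self.delta, alpha0=self.alpha0)
        self.network_ = build_network(A, self.sm_, self.sd_, self._rule())
        self._instance_cache_ = {}

        positives = X.positives
        if not positives:
            raise ValueError("association matrix has no positive pairs")
        mi = {r: i for i, r in enumerate(A.mirna_names)}
        di = {d: j for j, d in enumerate(A.disease_names)}

        zero_cells = np.argwhere(A.values == 0)
        if len(zero_cells) == 0:
            raise ValueError("association matrix has no unconfirmed pairs")
        want = int(round(self.negative_ratio * len(positives)))

        def make_batch(seed):
            if want > len(zero_cells):
                # near-dense matrix: use every unconfirmed pair
                negatives = [(A.mirna_names[i], A.disease_names[j])
                             for i, j in zero_cells]
            else:
                negatives = sample_negatives(A, self.negative_ratio, seed=seed)
            prs = positives + negatives
            yv = np.array([1.0] * len(positives) + [0.0] * len(negatives))
            ri = np.array([mi[r] for r, _ in prs])
            dj = np.array([di[d] for _, d in prs])
            return ri, dj, self._batch_for(prs), yv

        neg_seed = int(rng.integers(2 ** 31))
        fixed = None if self.resample_negatives else make_batch(neg_seed)

        Z = self.proj_dim or self.embed_dim
        self.params_ = init_params(
            rng, A.m, A.n, Z, self.embed_dim, self.mlp_hidden,
            self.pi_hidden, self.n_heads, self.l_max)
        opt = ad.Adam(self.params_, lr=self.lr)
        log = []
        for epoch in range(self.n_epochs):
            if self.resample_negatives:
                r_idx, d_idx, batch, yvec = make_batch((neg_seed + epoch) % 2 ** 31)
            else:
                r_idx, d_idx, batch, yvec = fixed
            out = model_forward(
                self.params_, self.sm_.values, self.sd_.values, r_idx, d_idx,
                batch, n_heads=self.n_heads, dropout=self.dropout,
                train=True, rng=rng, use_pair_branch=self.use_pair_branch)
            loss_n = bce_with_logits(out["logit_pi"], yvec)
            loss_m = bce_with_logits(out["s_node"], yvec)
            loss_reg = l2_penalty(self.params_, self.weight_decay)
            if self.use_pair_branch:
                total = loss_n + self.lambda_ * loss_m \
                    + (1.0 - self.lambda_) * loss_reg
            else:
                total = self.lambda_ * loss_m + (1.0 - self.lambda_) * loss_reg
            head_loss = bce_with_logits(out["logit_head"], yvec)
            objective = total + head_loss
            if not np.isfinite(objective.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: "
                    f"N={loss_n.data} M={loss_m.data} reg={loss_reg.data}")
            objective.backward()
            opt.step()
            log.append({"epoch": epoch, "loss_N": float(loss_n.data),
                        "loss_M": float(loss_m.data),
                        "loss_reg": float(loss_reg.data),
                        "total": float(total.data),
                        "head": float(head_loss.data)})
        self.loss_log_ = pd.DataFrame(log)
        return self

    def decision_function(self, pairs):
        """Combined-head logit for each (miRNA name, disease name) pair."""
        self._check_fitted()
        out = self._forward(list(pairs), train=False)
        return out["logit_head"].data.copy()

    def predict_proba(self, pairs):
        """Association probability (sigmoid of the combined-head logit)."""
        logit = self.decision_function(pairs)
        return 1.0 / (1.0 + np.exp(-logit))

    def predict(self, pairs):
        return (self.decision_function(pairs) > 0).astype(int)

    def rank_candidates(self, disease, exclude_confirmed=True,
                        top=None) -> PredictionTable:
        """Rank miRNAs for one disease by combined score.

        With ``exclude_confirmed`` (standard mode) miRNAs already associated
        in the *fitted* matrix are dropped; for the new-disease protocol fit
        on ``dataset.masked_disease(d)`` first, which leaves the column
        empty so every miRNA is scored.
        """
        self._check_fitted()
        A = self.dataset_.A
        if disease not in A.disease_names:
            raise KeyError(f"unknown disease {disease!r}")
        j = A.disease_index(disease)
        cands = [r for i, r in enumerate(A.mirna_names)
                 if not (exclude_confirmed and A.values[i, j])]
        if not cands:
            return PredictionTable([])
        scores = self.predict_proba([(r, disease) for r in cands])
        table = PredictionTable.from_scores(
            [(r, disease, float(s)) for r, s in zip(cands, scores)])
        if top is not None:
            table = PredictionTable(table.rows[:top])
        return table

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")
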