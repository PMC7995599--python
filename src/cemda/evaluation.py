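"""Cross-validation schemes and ranking AUC.

AUC is the Mann-Whitney statistic (probability a random positive outscores
a random negative, half credit for ties).  Repeated k-fold CV partitions
the confirmed pairs, zeroes each held-out group *before* similarity,
network and meta-path construction (leakage-safe), retrains, and scores
the held-out positives against all unconfirmed pairs.  Global LOOCV is
provided in a scaled mode that retrains once per disjoint block of
held-out positives; with block size 1 on a subsample it reduces to true
leave-one-out over that subsample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .dataset import MDADataset
from .training import TrainConfig

__all__ = ["CVReport", "auc", "kfold_cv", "global_loocv",
           "new_disease_auc"]


@dataclass
class CVReport:
    """Per-fold AUCs of one cross-validation run."""

    scheme: str
    folds: int
    repeats: int
    fold_aucs: list
    seed: int
    pooled_auc: float | None = None

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))


def auc(scores, labels) -> float:
    """Ranking AUC with the tie-half-credit (Mann-Whitney) convention."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def _partition(positives, k, rng):
    """Random partition of the positive pairs into k near-equal groups."""
    idx = rng.permutation(len(positives))
    return [sorted(fold.tolist()) for fold in np.array_split(idx, k)]


def _negative_pairs(dataset: MDADataset):
    A = dataset.A
    rr, cc = np.nonzero(A.values == 0)
    return [(A.mirna_names[i], A.disease_names[j]) for i, j in zip(rr, cc)]


def _fold_scores(dataset, held_out, config):
    """Retrain with `held_out` zeroed; score them and all unconfirmed pairs."""
    est = config.make_estimator().fit(dataset.masked(held_out))
    negs = _negative_pairs(dataset)
    pos_scores = est.decision_function(held_out)
    neg_scores = est.decision_function(negs)
    return pos_scores, neg_scores


def kfold_cv(dataset: MDADataset, k: int, repeats: int,
             config: TrainConfig, seed: int = 0) -> CVReport:
    """Repeated k-fold CV over the confirmed pairs; mean AUC over folds."""
    positives = dataset.positives
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(positives):
        raise ValueError("more folds than positive pairs")
    rng = np.random.default_rng(seed)
    fold_aucs = []
    for _ in range(repeats):
        for fold in _partition(positives, k, rng):
            held = [positives[i] for i in fold]
            pos_s, neg_s = _fold_scores(dataset, held, config)
            scores = np.concatenate([pos_s, neg_s])
            labels = np.concatenate([np.ones(len(pos_s)), np.zeros(len(neg_s))])
            fold_aucs.append(auc(scores, labels))
    return CVReport("kfold", k, repeats, fold_aucs, seed)


def global_loocv(dataset: MDADataset, config: TrainConfig, seed: int = 0,
                 subsample: int | None = None,
                 block_size: int = 1) -> CVReport:
    """Global leave-one-out over confirmed pairs (scaled mode).

    Each held-out positive is ranked against all unconfirmed pairs.  With
    ``block_size > 1`` disjoint blocks of positives share one retrained
    model; ``subsample`` restricts to a random subset of positives.  The
    pooled AUC over all (positive, negative) comparisons is reported as
    ``pooled_auc``; ``fold_aucs`` holds one entry per held-out positive.
    """
    positives = dataset.positives
    rng = np.random.default_rng(seed)
    if subsample is not None and subsample < len(positives):
        idx = rng.choice(len(positives), size=subsample, replace=False)
        positives = [positives[i] for i in sorted(idx)]
    order = rng.permutation(len(positives))
    blocks = [sorted(order[i:i + block_size].tolist())
              for i in range(0, len(order), block_size)]
    per_pos_aucs, all_scores, all_labels = [], [], []
    for block in blocks:
        held = [positives[i] for i in block]
        pos_s, neg_s = _fold_scores(dataset, held, config)
        for s in pos_s:
            labels = np.concatenate([[1], np.zeros(len(neg_s))])
            per_pos_aucs.append(auc(np.concatenate([[s], neg_s]), labels))
        all_scores.append(np.concatenate([pos_s, neg_s]))
        all_labels.append(np.concatenate([np.ones(len(pos_s)),
                                          np.zeros(len(neg_s))]))
    pooled = auc(np.concatenate(all_scores), np.concatenate(all_labels))
    report = CVReport("loocv", len(blocks), 1, per_pos_aucs, seed,
                      pooled_auc=pooled)
    return report


def new_disease_auc(dataset: MDADataset, disease: str,
                    config: TrainConfig) -> float:
    """AUC of ranking all miRNAs for a disease trained with its column zeroed.

    Implements the new-disease protocol: the target's confirmed
    associations are removed everywhere downstream of A, the model is
    retrained, every miRNA is scored for the target, and the original
    column provides the labels.
    """
    A = dataset.A
    j = A.disease_index(disease)
    labels = A.values[:, j].astype(int)
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("target column must contain both classes")
    est = config.make_estimator().fit(dataset.masked_disease(disease))
    scores = est.decision_function([(r, disease) for r in A.mirna_names])
    return auc(scores, labels)
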