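"""Disease semantic similarity, Gaussian profile kernels, and integration.

Two semantic-similarity variants over MeSH-style disease ancestor DAGs are
averaged into SS; Gaussian interaction-profile kernels over the rows
(miRNAs) and columns (diseases) of the association matrix give GM and GD;
the integrated networks SD (SS with GD fallback) and SM (functional
similarity FS with GM fallback) feed the heterogeneous network.

Variant 1 scores each ancestor `d` of a disease `D` by an attenuated
contribution ``C_D(d) = max(delta * C_D(d') for children d')`` with
``C_D(D) = 1`` (delta defaults to 0.5); variant 2 scores ancestors by
information content ``-ln(n_DAGs_containing(d) / n_diseases)`` shared
across all targets.  Either variant's pairwise similarity is

    sum_{d in T(i) ∩ T(j)} (C_i(d) + C_j(d)) / (V_i + V_j)

where V is the sum of contributions (the disease's semantic value).  The
logarithm base in variant 2 is immaterial: any base rescales numerator and
denominator identically (tested as a base-invariance property).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .io import DAGCollection, DiseaseDAG, SimilarityMatrix

__all__ = [
    "ContributionTable", "d1_contributions", "d2_contributions",
    "semantic_similarity", "combined_semantic_similarity",
    "gaussian_profile_kernel", "integrate_similarity",
    "build_integrated_similarities",
]


@dataclass
class ContributionTable:
    """Per-ancestor semantic contributions of one disease and their sum."""

    target: str
    contributions: dict  # node -> nonnegative contribution

    @property
    def semantic_value(self) -> float:
        return float(sum(self.contributions.values()))


def d1_contributions(dag: DiseaseDAG, delta: float = 0.5) -> ContributionTable:
    """Attenuated semantic contributions of every node of DAG(D).

    The target contributes 1; every ancestor contributes the maximum of
    ``delta`` times the contribution of its children within the DAG.
    """
    if not (0.0 < delta < 1.0):
        raise ValueError("delta must lie in (0, 1)")
    contrib: dict = {}

    def value(d):
        if d in contrib:
            return contrib[d]
        if d == dag.target:
            contrib[d] = 1.0
            return 1.0
        kids = dag.children(d)
        if not kids:
            raise ValueError(f"node {d!r} cannot reach target {dag.target!r}")
        contrib[d] = max(delta * value(c) for c in kids)
        return contrib[d]

    for node in dag.nodes:
        value(node)
    return ContributionTable(dag.target, contrib)


def d2_contributions(collection: DAGCollection) -> dict:
    """Information-content contributions shared by every target disease.

    ``-ln(count of DAGs containing d / number of diseases in the
    collection)``; the denominator is the supplied collection size.
    """
    if len(collection) == 0:
        raise ValueError("empty DAG collection")
    n = len(collection)
    counts: dict = {}
    for disease in collection.diseases:
        for node in collection[disease].nodes:
            counts[node] = counts.get(node, 0) + 1
    return {d: -math.log(c / n) for d, c in counts.items()}


def _variant_tables(collection: DAGCollection, delta: float):
    v1 = {d: d1_contributions(collection[d], delta) for d in collection.diseases}
    shared = d2_contributions(collection)
    v2 = {
        d: ContributionTable(d, {x: shared[x] for x in collection[d].nodes})
        for d in collection.diseases
    }
    return v1, v2


def semantic_similarity(contrib_i: ContributionTable,
                        contrib_j: ContributionTable) -> float:
    """Shared-ancestor similarity of two contribution tables (symmetric)."""
    vi, vj = contrib_i.semantic_value, contrib_j.semantic_value
    if vi + vj == 0.0:
        raise ValueError("both semantic values are zero")
    common = contrib_i.contributions.keys() & contrib_j.contributions.keys()
    num = sum(contrib_i.contributions[d] + contrib_j.contributions[d] for d in common)
    return num / (vi + vj)


def _variant_matrix(tables: dict, diseases: list) -> np.ndarray:
    k = len(diseases)
    out = np.zeros((k, k))
    for i, di in enumerate(diseases):
        for j in range(i, k):
            ti, tj = tables[di], tables[diseases[j]]
            if ti.semantic_value + tj.semantic_value == 0.0:
                # degenerate (every ancestor common to all diseases): no
                # information-content signal; self-similarity stays 1
                s = 1.0 if i == j else 0.0
            else:
                s = semantic_similarity(ti, tj)
            out[i, j] = out[j, i] = s
    return out


def combined_semantic_similarity(collection: DAGCollection,
                                 delta: float = 0.5) -> SimilarityMatrix:
    """SS: the entrywise average of the two semantic-similarity variants."""
    diseases = collection.diseases
    v1, v2 = _variant_tables(collection, delta)
    ss = (_variant_matrix(v1, diseases) + _variant_matrix(v2, diseases)) / 2.0
    np.fill_diagonal(ss, 1.0)
    return SimilarityMatrix(diseases, ss)


def gaussian_profile_kernel(profiles: np.ndarray,
                            names: list,
                            alpha0: float = 1.0) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over binary profile rows.

    Bandwidth ``alpha = alpha0 / mean(||profile_i||^2)``;
    ``K(i, j) = exp(-alpha * ||profile_i - profile_j||^2)``.  Pass the
    association matrix's rows for miRNAs (GM) or its columns for diseases
    (GD).
    """
    profiles = np.asarray(profiles, dtype=float)
    mean_sq = float((profiles ** 2).sum(axis=1).mean())
    if mean_sq == 0.0:
        raise ValueError("all profiles are zero; kernel bandwidth undefined")
    alpha = alpha0 / mean_sq
    sq = squareform(pdist(profiles, metric="sqeuclidean"))
    return SimilarityMatrix(list(names), np.exp(-alpha * sq))


def integrate_similarity(primary: SimilarityMatrix,
                         fallback: SimilarityMatrix,
                         defined_mask: np.ndarray) -> SimilarityMatrix:
    """Entrywise: primary where the mask holds, fallback elsewhere."""
    if primary.names != fallback.names:
        raise ValueError("integrate_similarity: name mismatch")
    mask = np.asarray(defined_mask, dtype=bool)
    if mask.shape != primary.values.shape:
        raise ValueError("integrate_similarity: mask shape mismatch")
    vals = np.where(mask, primary.values, fallback.values)
    return SimilarityMatrix(primary.names, vals)


def build_integrated_similarities(A, dags: DAGCollection,
                                  fs: SimilarityMatrix | None,
                                  delta: float = 0.5,
                                  alpha0: float = 1.0):
    """Compute the integrated miRNA (SM) and disease (SD) similarity networks.

    SD uses semantic similarity where both diseases have DAG records and the
    Gaussian kernel GD elsewhere; SM uses the supplied functional similarity
    FS where both miRNAs appear in it with a positive entry and GM elsewhere.
    Returns ``(SM, SD)`` indexed to the association matrix's names.
    """
    gm = gaussian_profile_kernel(A.values, A.mirna_names, alpha0)
    gd = gaussian_profile_kernel(A.values.T, A.disease_names, alpha0)

    # disease side: expand SS onto the study's disease list
    ss_full = np.zeros((A.n, A.n))
    has_dag = np.array([d in dags for d in A.disease_names], dtype=bool)
    with_dag = [d for d in A.disease_names if d in dags]
    if with_dag:
        sub = DAGCollection({d: dags[d] for d in with_dag})
        ss = combined_semantic_similarity(sub, delta).reindex(with_dag)
        idx = np.flatnonzero(has_dag)
        ss_full[np.ix_(idx, idx)] = ss.values
    d_mask = np.outer(has_dag, has_dag)
    sd = integrate_similarity(SimilarityMatrix(A.disease_names, ss_full), gd, d_mask)

    # miRNA side
    fs_full = np.zeros((A.m, A.m))
    if fs is not None:
        in_fs = np.array([r in fs.names for r in A.mirna_names], dtype=bool)
        present = [r for r in A.mirna_names if r in fs.names]
        if present:
            sub = fs.reindex(present)
            idx = np.flatnonzero(in_fs)
            fs_full[np.ix_(idx, idx)] = sub.values
        m_mask = np.outer(in_fs, in_fs) & (fs_full > 0)
    else:
        m_mask = np.zeros((A.m, A.m), dtype=bool)
    np.fill_diagonal(m_mask, False)  # keep diagonal from GM (exactly 1)
    np.fill_diagonal(fs_full, 1.0)
    sm = integrate_similarity(SimilarityMatrix(A.mirna_names, fs_full), gm, m_mask)
    sm.values[np.diag_indices(A.m)] = 1.0
    sd.values[np.diag_indices(A.n)] = 1.0
    return sm, sd
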