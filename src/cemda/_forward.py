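"""Batched autodiff forward pass shared by training and prediction.

Instances are flattened across pairs and grouped by sequence length so the
GRU unrolls as a handful of dense matrix operations; instance->type and
type->pair attention fusions run as segment softmaxes.  The arithmetic is
the same as the per-instance reference functions in ``pair_model`` /
``path_model`` (equivalence is tested); this path exists so that training
on hundreds of pairs with thousands of meta-path instances stays fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, concat, constant, matmul, mul, relu, segment_sum, \
    sigmoid, softmax, sum_, take, tanh, transpose
from .hetnet import all_type_strings, enumerate_meta_path_instances, group_by_type

__all__ = ["PathBatch", "build_path_batch", "enumerate_from_mirna",
           "init_params", "model_forward", "bce_with_logits", "l2_penalty"]


# ---------------------------------------------------------------------------
# batch structure

@dataclass
class PathBatch:
    """Flattened meta-path instances for a list of (miRNA, disease) pairs."""

    n_pairs: int
    # per sequence length: (node-id array (I, length+1), instance->group ids)
    length_groups: list = field(default_factory=list)
    group_type: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    group_pair: np.ndarray = field(default_factory=lambda: np.zeros(0, int))

    @property
    def n_groups(self) -> int:
        return len(self.group_type)


def enumerate_from_mirna(net, r, l_max=3, allow_revisits=False, edge_kinds=None):
    """All meta-path instances from miRNA `r` to every disease, in one DFS.

    Equivalent to calling ``enumerate_meta_path_instances`` per disease but
    a single traversal; returns {disease name: sorted instance list}.
    """
    from .hetnet import MetaPathInstance
    src = ("M", r)
    if src not in net:
        raise KeyError(f"miRNA {r!r} not in network")
    found: dict = {}
    stack = [src]

    def dfs(node):
        if node[0] == "D" and len(stack) >= 2:
            found.setdefault(node[1], []).append(tuple(stack))
        if len(stack) - 1 >= l_max:
            return
        for nxt in net.neighbors(node):
            if edge_kinds is not None and net.edges[node, nxt]["kind"] not in edge_kinds:
                continue
            if not allow_revisits and nxt in stack:
                continue
            stack.append(nxt)
            dfs(nxt)
            stack.pop()

    dfs(src)
    out = {}
    for d, seqs in found.items():
        insts = [MetaPathInstance(s) for s in seqs]
        insts.sort(key=lambda p: (p.length, p.node_sequence))
        out[d] = insts
    return out


def _uses_direct_edge(inst, r, d) -> bool:
    pair = {("M", r), ("D", d)}
    return any({a, b} == pair
               for a, b in zip(inst.node_sequence, inst.node_sequence[1:]))


def build_path_batch(net, pairs, mirna_index, disease_index, l_max=3,
                     max_instances_per_type=None, allow_revisits=False,
                     edge_kinds=None, instance_cache=None,
                     exclude_direct=True) -> PathBatch:
    """Flatten each pair's (capped) instances into length-grouped arrays.

    ``instance_cache`` maps miRNA name -> {disease: instances} as produced
    by :func:`enumerate_from_mirna`, letting callers amortise enumeration
    across many pairs sharing a miRNA.

    With ``exclude_direct`` (target-edge masking, the default) instances
    traversing the pair's own association edge are dropped, so a training
    pair's representation cannot shortcut through the very edge the model
    is asked to predict and matches what a held-out pair will see.
    """
    m_count = len(mirna_index)
    type_of = {t: i for i, t in enumerate(all_type_strings(l_max))}
    by_len: dict = {}
    group_type, group_pair = [], []
    for b, (r, d) in enumerate(pairs):
        if instance_cache is not None:
            if r not in instance_cache:
                instance_cache[r] = enumerate_from_mirna(
                    net, r, l_max, allow_revisits, edge_kinds)
            insts = instance_cache[r].get(d, [])
        else:
            insts = enumerate_meta_path_instances(
                net, r, d, l_max, allow_revisits, edge_kinds)
        if exclude_direct:
            insts = [p for p in insts if not _uses_direct_edge(p, r, d)]
        for tstr, group in group_by_type(insts).items():
            if max_instances_per_type is not None:
                group = group[:max_instances_per_type]
            gid = len(group_type)
            group_type.append(type_of[tstr])
            group_pair.append(b)
            for inst in group:
                ids = [mirna_index[nm] if t == "M" else m_count + disease_index[nm]
                       for t, nm in inst.node_sequence]
                nodes, gids = by_len.setdefault(inst.length, ([], []))
                nodes.append(ids)
                gids.append(gid)
    length_groups = [
        (np.asarray(nodes, dtype=int), np.asarray(gids, dtype=int))
        for _, (nodes, gids) in sorted(by_len.items())
    ]
    return PathBatch(len(pairs), length_groups,
                     np.asarray(group_type, int), np.asarray(group_pair, int))


# ---------------------------------------------------------------------------
# parameters

def init_params(rng: np.random.Generator, m: int, n: int, proj_dim: int,
                embed_dim: int, mlp_hidden: int, pi_hidden: int,
                n_heads: int, l_max: int) -> dict:
    """Glorot-initialised parameter dict for the full model."""
    Z, X = proj_dim, embed_dim
    g = lambda *shape: ad.parameter(ad.glorot(rng, shape))
    zeros = lambda *shape: ad.parameter(np.zeros(shape))
    params = {
        "W_R": g(Z, m), "W_D": g(Z, n),
        # pair MLP 4Z -> hidden -> X, validity head X -> hidden -> 1
        "mlp_W0": g(mlp_hidden, 4 * Z), "mlp_b0": zeros(mlp_hidden),
        "mlp_W1": g(X, mlp_hidden), "mlp_b1": zeros(X),
        "pi_W0": g(pi_hidden, X), "pi_b0": zeros(pi_hidden),
        "pi_W1": g(1, pi_hidden), "pi_b1": zeros(1),
        # GRU
        "W_zx": g(X, Z), "W_rx": g(X, Z), "W_hx": g(X, Z),
        "W_zh": g(X, X), "W_rh": g(X, X), "W_hh": g(X, X),
        "b_z": zeros(X), "b_r": zeros(X), "b_h": zeros(X),
        # attention: pooling heads and per-type fusion vectors
        "M": g(n_heads, X),
        "att_p": g(len(all_type_strings(l_max)), X),
        "att_P": g(len(all_type_strings(l_max)), X),
        # node-branch logit map
        "w_node": g(1, X), "b_node": zeros(1),
        # combined scoring head (trained as a stop-gradient probe)
        "w_head": g(1, 2 * X), "b_head": zeros(1),
    }
    return params


# ---------------------------------------------------------------------------
# forward

def _dropout(x: Tensor, q: float, train: bool, rng) -> Tensor:
    if q == 0.0:
        return x
    if train:
        mask = rng.binomial(1, 1.0 - q, size=x.shape).astype(float)
        return mul(x, constant(mask))
    return mul(x, constant(1.0 - q))


def _affine(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    return matmul(x, transpose(W)) + b


def _gru_step(x: Tensor, h: Tensor, p: dict, q: float, train: bool, rng) -> Tensor:
    z = sigmoid(_affine(x, p["W_zx"], p["b_z"]) + matmul(h, transpose(p["W_zh"])))
    r = sigmoid(_affine(x, p["W_rx"], p["b_r"]) + matmul(h, transpose(p["W_rh"])))
    g = tanh(_affine(x, p["W_hx"], p["b_h"]) + matmul(mul(r, h), transpose(p["W_hh"])))
    return mul(z, h) + mul(1.0 - z, _dropout(g, q, train, rng))


def _segment_softmax(e: Tensor, seg_ids: np.ndarray, n_seg: int) -> Tensor:
    if len(seg_ids) == 0:
        return e
    shift = np.full(n_seg, -np.inf)
    np.maximum.at(shift, seg_ids, e.data)
    ex = ad.exp(e - constant(shift[seg_ids]))
    denom = segment_sum(ad.reshape(ex, (-1, 1)), seg_ids, n_seg)
    return ex / ad.reshape(take(denom, seg_ids), (-1,))


def model_forward(params: dict, sm_values, sd_values, r_idx, d_idx,
                  batch: PathBatch, *, n_heads: int, dropout: float,
                  train: bool = False, rng=None, use_pair_branch: bool = True):
    """Full forward pass.

    Returns a dict of Tensors: pair embedding ``g``, validity logit
    ``logit_pi``, node embedding ``h_node``, node-branch logit ``s_node``
    and the stop-gradient combined-head logit ``logit_head``.
    """
    q = dropout
    H_m = matmul(constant(sm_values), transpose(params["W_R"]))   # (m, Z)
    H_d = matmul(constant(sd_values), transpose(params["W_D"]))   # (n, Z)
    H_all = concat([H_m, H_d], axis=0)

    out = {}
    B = len(r_idx)

    # -- pair branch -----------------------------------------------------
    h_r = take(H_m, r_idx)
    h_d = take(H_d, d_idx)
    h0 = concat([h_r, h_d, mul(h_r, h_d), h_r + h_d], axis=1)
    hid = _dropout(relu(_affine(h0, params["mlp_W0"], params["mlp_b0"])), q, train, rng)
    g_pair = _affine(hid, params["mlp_W1"], params["mlp_b1"])     # (B, X)
    pi_h = relu(_affine(g_pair, params["pi_W0"], params["pi_b0"]))
    logit_pi = ad.reshape(_affine(pi_h, params["pi_W1"], params["pi_b1"]), (-1,))
    out["g"] = g_pair
    out["logit_pi"] = logit_pi

    # -- node branch -----------------------------------------------------
    pooled_parts, gid_parts = [], []
    for nodes, inst_groups in batch.length_groups:
        T = nodes.shape[1]
        h = constant(np.zeros((nodes.shape[0], params["b_z"].shape[0])))
        states = []
        for t in range(T):
            x_t = take(H_all, nodes[:, t])
            h = _gru_step(x_t, h, params, q, train, rng)
            states.append(h)
        pooled = None
        for k in range(n_heads):
            m_k = ad.reshape(take(params["M"], np.array([k])), (-1, 1))  # (X, 1)
            logits = concat([matmul(s, m_k) for s in states], axis=1)    # (I, T)
            alpha = softmax(logits, axis=1)
            p_k = None
            for t in range(T):
                term = mul(ad.col(alpha, t), states[t])
                p_k = term if p_k is None else p_k + term
            pooled = p_k if pooled is None else pooled + p_k
        pooled_parts.append(mul(pooled, constant(1.0 / n_heads)))
        gid_parts.append(inst_groups)

    X = params["b_z"].shape[0]
    if pooled_parts:
        all_pooled = concat(pooled_parts, axis=0) if len(pooled_parts) > 1 else pooled_parts[0]
        inst_groups = np.concatenate(gid_parts)
        G = batch.n_groups
        # instance -> type fusion (softmax within group, sigmoid output)
        att_rows = take(params["att_p"], batch.group_type[inst_groups])
        e = relu(sum_(mul(all_pooled, att_rows), axis=1))
        w = _segment_softmax(e, inst_groups, G)
        weighted = mul(all_pooled, ad.reshape(w, (-1, 1)))
        gvec = sigmoid(segment_sum(weighted, inst_groups, G))            # (G, X)
        # type -> pair fusion (softmax across a pair's types, no sigmoid)
        att_rows2 = take(params["att_P"], batch.group_type)
        wt = relu(sum_(mul(gvec, att_rows2), axis=1))
        wp = _segment_softmax(wt, batch.group_pair, batch.n_pairs)
        h_node = segment_sum(mul(gvec, ad.reshape(wp, (-1, 1))),
                             batch.group_pair, batch.n_pairs)            # (B, X)
    else:
        h_node = constant(np.zeros((B, X)))
    out["h_node"] = h_node
    out["s_node"] = ad.reshape(_affine(h_node, params["w_node"], params["b_node"]), (-1,))

    # -- combined head (probe: gradients stop at the representations) ----
    g_det = constant(g_pair.data) if use_pair_branch else constant(np.zeros_like(g_pair.data))
    feats = concat([constant(h_node.data), g_det], axis=1)
    out["logit_head"] = ad.reshape(
        _affine(feats, params["w_head"], params["b_head"]), (-1,))
    return out


def bce_with_logits(logits: Tensor, y: np.ndarray) -> Tensor:
    """Mean binary cross-entropy of sigmoid(logits) against binary labels."""
    y_t = constant(np.asarray(y, dtype=float))
    return ad.mean_(-(mul(y_t, ad.logsigmoid(logits))
                      + mul(1.0 - y_t, ad.logsigmoid(-logits))))


def l2_penalty(params: dict, coef: float) -> Tensor:
    """Weight-decay functional: coef * sum of squared parameter entries."""
    total = None
    for p in params.values():
        term = sum_(mul(p, p))
        total = term if total is None else total + term
    return mul(total, constant(coef))
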