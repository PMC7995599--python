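"""Synthetic fixtures: toy networks, random DAG collections, planted benchmarks.

The planted benchmark emulates the structure the predictor exploits in real
data: miRNAs and diseases fall into matched functional blocks; associations
are dense within matched blocks and sparse elsewhere; miRNA functional
similarity is high within miRNA blocks; disease DAGs share ancestors within
disease blocks.  Everything regenerates bit-for-bit from a seed, so no data
files ship with the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .dataset import MDADataset
from .io import (AssociationMatrix, DAGCollection, DiseaseDAG,
                 SimilarityMatrix, write_similarity_matrix)

__all__ = ["PlantedBenchmark", "make_toy_hetnet_fixture",
           "generate_dag_collection", "generate_planted_benchmark",
           "write_benchmark_files"]


@dataclass
class PlantedBenchmark:
    """A block-structured dataset with known ground truth."""

    dataset: MDADataset
    mirna_blocks: np.ndarray
    disease_blocks: np.ndarray
    noise: float
    seed: int

    @property
    def A(self) -> AssociationMatrix:
        return self.dataset.A


def make_toy_hetnet_fixture():
    """A fixed 4-miRNA / 4-disease network with hand-enumerated meta-paths.

    Returns ``(net, expected)`` where ``expected`` maps a (miRNA, disease)
    name pair to the complete ordered list of simple meta-path instances of
    length <= 3, worked out by hand; used as an enumeration regression test.
    """
    net = nx.Graph()
    for r in ["m1", "m2", "m3", "m4"]:
        net.add_node(("M", r))
    for d in ["d1", "d2", "d3", "d4"]:
        net.add_node(("D", d))
    md = [("m1", "d1"), ("m2", "d1"), ("m2", "d3"), ("m4", "d4")]
    mm = [("m1", "m2")]
    dd = [("d1", "d2"), ("d3", "d2"), ("d1", "d4")]
    for r, d in md:
        net.add_edge(("M", r), ("D", d), weight=1.0, kind="MD")
    for a, b in mm:
        net.add_edge(("M", a), ("M", b), weight=0.8, kind="MM")
    for a, b in dd:
        net.add_edge(("D", a), ("D", b), weight=0.7, kind="DD")
    expected = {
        ("m2", "d2"): [
            (("M", "m2"), ("D", "d1"), ("D", "d2")),
            (("M", "m2"), ("D", "d3"), ("D", "d2")),
            (("M", "m2"), ("M", "m1"), ("D", "d1"), ("D", "d2")),
        ],
        ("m1", "d1"): [
            (("M", "m1"), ("D", "d1")),
            (("M", "m1"), ("M", "m2"), ("D", "d1")),
        ],
    }
    return net, expected


def generate_dag_collection(n_diseases: int, max_depth: int = 3,
                            branching: int = 2, seed: int = 0,
                            disease_names=None,
                            blocks=None) -> DAGCollection:
    """Layered random disease DAGs over a shared ancestor pool.

    A global layered term DAG is sampled (a few roots, then layers whose
    terms each pick 1..branching parents from the layer above); each
    disease attaches under terms of the deepest layer and its DAG is the
    ancestor closure.  With ``max_depth == 1`` every DAG is the target
    alone.  ``blocks`` (one id per disease) steers same-block diseases to
    shared parent terms so their semantic similarity is high.
    """
    if n_diseases < 1 or max_depth < 1:
        raise ValueError("need n_diseases >= 1 and max_depth >= 1")
    rng = np.random.default_rng(seed)
    if disease_names is None:
        disease_names = [f"disease-{i:03d}" for i in range(n_diseases)]
    if blocks is None:
        blocks = np.zeros(n_diseases, dtype=int)
    blocks = np.asarray(blocks)
    n_blocks = int(blocks.max()) + 1

    g = nx.DiGraph()
    layers = []
    if max_depth > 1:
        roots = [f"anc0-{i}" for i in range(max(2, branching))]
        layers.append(roots)
        g.add_nodes_from(roots)
        for lvl in range(1, max_depth - 1):
            size = max(n_blocks, 2 * branching)
            terms = [f"anc{lvl}-{i}" for i in range(size)]
            for i, t in enumerate(terms):
                n_par = int(rng.integers(1, branching + 1))
                parents = rng.choice(len(layers[-1]), size=min(n_par, len(layers[-1])),
                                     replace=False)
                for p in parents:
                    g.add_edge(layers[-1][p], t)
            layers.append(terms)

    dags = {}
    for i, name in enumerate(disease_names):
        g.add_node(name)
        if max_depth > 1:
            pool_layer = layers[-1]
            # same-block diseases share parent terms (interleaved assignment)
            pool = [t for j, t in enumerate(pool_layer)
                    if j % n_blocks == blocks[i] % n_blocks] or pool_layer
            n_par = int(rng.integers(1, min(2, len(pool)) + 1))
            parents = rng.choice(len(pool), size=n_par, replace=False)
            for p in parents:
                g.add_edge(pool[p], name)
        anc = nx.ancestors(g, name) | {name}
        dags[name] = DiseaseDAG(name, g.subgraph(anc).copy())
    return DAGCollection(dags)


def generate_planted_benchmark(m: int = 60, n: int = 40, n_blocks: int = 4,
                               p_in: float = 0.35, p_out: float = 0.02,
                               noise: float = 0.01, seed: int = 0,
                               fs_defined_frac: float = 0.7,
                               dag_depth: int = 3) -> PlantedBenchmark:
    """Block-structured benchmark linking associations, FS and disease DAGs.

    Associations are Bernoulli(p_in) within matched (miRNA block, disease
    block) pairs and Bernoulli(p_out) elsewhere; ``noise`` flips that
    fraction of cells.  FS is high within miRNA blocks, low between, and
    undefined (zero) on a random ``1 - fs_defined_frac`` of pairs so the
    Gaussian-kernel fallback is exercised.  Disease DAGs share block-level
    ancestors.
    """
    if p_in <= p_out:
        raise ValueError("p_in must exceed p_out")
    if not (m >= n_blocks and n >= n_blocks):
        raise ValueError("need at least one entity per block")
    rng = np.random.default_rng(seed)
    mirna_names = [f"mir-{i:03d}" for i in range(m)]
    disease_names = [f"disease-{j:03d}" for j in range(n)]
    mb = (np.arange(m) * n_blocks) // m
    db = (np.arange(n) * n_blocks) // n

    matched = mb[:, None] == db[None, :]
    prob = np.where(matched, p_in, p_out)
    A = (rng.random((m, n)) < prob).astype(np.int8)
    if noise > 0:
        n_flip = int(round(noise * m * n))
        flat = rng.choice(m * n, size=n_flip, replace=False)
        A.flat[flat] = 1 - A.flat[flat]
    if A.sum() == 0:
        A[0, 0] = 1  # degenerate draw guard; unreachable at default sizes

    # miRNA functional similarity with a partial "defined" mask
    same = mb[:, None] == mb[None, :]
    base = np.where(same, rng.uniform(0.6, 0.9, (m, m)),
                    rng.uniform(0.05, 0.3, (m, m)))
    base = (base + base.T) / 2.0
    defined = rng.random((m, m)) < fs_defined_frac
    defined = defined & defined.T
    fs_vals = np.where(defined, base, 0.0)
    np.fill_diagonal(fs_vals, 1.0)
    fs = SimilarityMatrix(mirna_names, fs_vals)

    dags = generate_dag_collection(
        n, max_depth=dag_depth, branching=2,
        seed=int(rng.integers(2 ** 31)),
        disease_names=disease_names, blocks=db)

    dataset = MDADataset(
        AssociationMatrix(mirna_names, disease_names, A), dags, fs)
    return PlantedBenchmark(dataset, mb, db, noise, seed)


def write_benchmark_files(dataset: MDADataset, out_dir) -> dict:
    """Write the three standard input files for a dataset; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pairs_path = out / "pairs.tsv"
    with open(pairs_path, "w") as fh:
        fh.write("miRNA\tdisease\n")
        for r, d in dataset.positives:
            fh.write(f"{r}\t{d}\n")
    dags_path = out / "dags.tsv"
    with open(dags_path, "w") as fh:
        fh.write("disease\tparent\tchild\n")
        for disease in dataset.dags.diseases:
            dag = dataset.dags[disease]
            edges = sorted(dag.graph.edges)
            if not edges:
                fh.write(f"{disease}\t\t\n")
            for p, c in edges:
                fh.write(f"{disease}\t{p}\t{c}\n")
    paths = {"pairs": pairs_path, "dags": dags_path}
    if dataset.fs is not None:
        fs_path = out / "fs.tsv"
        write_similarity_matrix(dataset.fs, fs_path)
        paths["fs"] = fs_path
    return paths
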