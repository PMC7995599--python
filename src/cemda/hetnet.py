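"""Typed miRNA-disease heterogeneous network and meta-path enumeration.

Nodes are ``("M", name)`` or ``("D", name)``.  MD edges come from confirmed
associations; MM and DD edges come from the integrated similarity matrices
through an explicit edge rule, because Gaussian-kernel similarities are
dense and a graph needs a sparsifier.  Two rules are provided:

* ``top_k`` (default, k=5): each node keeps its k most similar neighbours,
  union-symmetrized, ties broken by name;
* ``threshold``: keep pairs with similarity >= tau.

A meta-path instance is a concrete node walk from a miRNA to a disease with
at most ``l_max`` edges (default 3).  By default instances are simple paths
(no repeated node); set ``allow_revisits=True`` to enumerate bounded walks
instead.  Instances are returned sorted by length then node sequence, and
grouped by their node-type string (e.g. ``"M,M,D"``), the meta-path type.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import networkx as nx
import numpy as np

from .io import AssociationMatrix, SimilarityMatrix

__all__ = [
    "EdgeRule", "MetaPathInstance", "build_network",
    "enumerate_meta_path_instances", "group_by_type", "all_type_strings",
]


@dataclass(frozen=True)
class EdgeRule:
    """How similarity entries become MM / DD edges."""

    kind: str = "top_k"  # "top_k" | "threshold"
    k: int = 5
    tau: float = 0.5

    def edges(self, sim: SimilarityMatrix):
        vals = sim.values
        n = len(sim.names)
        keep = set()
        if self.kind == "top_k":
            for i in range(n):
                order = sorted(
                    (j for j in range(n) if j != i),
                    key=lambda j: (-vals[i, j], sim.names[j]),
                )
                for j in order[: self.k]:
                    keep.add((min(i, j), max(i, j)))
        elif self.kind == "threshold":
            for i in range(n):
                for j in range(i + 1, n):
                    if vals[i, j] >= self.tau:
                        keep.add((i, j))
        else:
            raise ValueError(f"unknown edge rule {self.kind!r}")
        return keep


@dataclass(frozen=True)
class MetaPathInstance:
    """A concrete miRNA-to-disease walk in the heterogeneous network."""

    node_sequence: tuple  # of ("M"|"D", name)

    def __post_init__(self):
        if self.node_sequence[0][0] != "M" or self.node_sequence[-1][0] != "D":
            raise ValueError("instance must start at a miRNA and end at a disease")

    @property
    def length(self) -> int:
        return len(self.node_sequence) - 1

    @property
    def type_string(self) -> str:
        return ",".join(t for t, _ in self.node_sequence)


def build_network(A: AssociationMatrix, SM: SimilarityMatrix,
                  SD: SimilarityMatrix, edge_rule: EdgeRule | None = None) -> nx.Graph:
    """Assemble the undirected typed network from A, SM and SD."""
    if SM.names != A.mirna_names or SD.names != A.disease_names:
        raise ValueError("similarity matrix names inconsistent with A")
    rule = edge_rule or EdgeRule()
    g = nx.Graph()
    for r in A.mirna_names:
        g.add_node(("M", r))
    for d in A.disease_names:
        g.add_node(("D", d))
    rr, cc = np.nonzero(A.values)
    for i, j in zip(rr, cc):
        g.add_edge(("M", A.mirna_names[i]), ("D", A.disease_names[j]),
                   weight=1.0, kind="MD")
    for i, j in rule.edges(SM):
        g.add_edge(("M", A.mirna_names[i]), ("M", A.mirna_names[j]),
                   weight=float(SM.values[i, j]), kind="MM")
    for i, j in rule.edges(SD):
        g.add_edge(("D", A.disease_names[i]), ("D", A.disease_names[j]),
                   weight=float(SD.values[i, j]), kind="DD")
    return g


def enumerate_meta_path_instances(net: nx.Graph, r, d, l_max: int = 3,
                                  allow_revisits: bool = False,
                                  edge_kinds: frozenset | None = None):
    """All meta-path instances from miRNA `r` to disease `d` with <= l_max edges.

    Deterministic ordering: by length, then lexicographic node sequence.
    ``edge_kinds`` optionally restricts traversable edge types (e.g. drop
    intermediate MD association edges).
    """
    src, dst = ("M", r), ("D", d)
    if src not in net:
        raise KeyError(f"miRNA {r!r} not in network")
    if dst not in net:
        raise KeyError(f"disease {d!r} not in network")
    if l_max < 1:
        raise ValueError("l_max must be >= 1")

    def ok(u, v):
        return edge_kinds is None or net.edges[u, v]["kind"] in edge_kinds

    found = []
    stack = [src]

    def dfs(node):
        if node == dst and len(stack) >= 2:
            found.append(tuple(stack))
            # a walk may continue through dst only if revisits are allowed
            if not allow_revisits:
                return
        if len(stack) - 1 >= l_max:
            return
        for nxt in net.neighbors(node):
            if not ok(node, nxt):
                continue
            if not allow_revisits and nxt in stack:
                continue
            stack.append(nxt)
            dfs(nxt)
            stack.pop()

    dfs(src)
    instances = [MetaPathInstance(seq) for seq in found]
    instances.sort(key=lambda p: (p.length, p.node_sequence))
    return instances


def group_by_type(instances):
    """Partition instances by meta-path type string (insertion-ordered)."""
    groups: dict = {}
    for inst in instances:
        groups.setdefault(inst.type_string, []).append(inst)
    return groups


def all_type_strings(l_max: int = 3):
    """Every possible meta-path type of length 1..l_max (M...D sequences)."""
    out = []
    for length in range(1, l_max + 1):
        for interior in product("MD", repeat=length - 1):
            out.append(",".join(["M", *interior, "D"]))
    return out
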