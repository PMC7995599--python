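"""Readers and writers for the three standard inputs and the prediction output.

File dialects (all plain text, tab-separated with comma autodetection):

* association pairs — two columns ``miRNA<TAB>disease``, optional header;
* disease DAGs — three columns ``disease<TAB>parent<TAB>child`` giving the
  parent-to-child edges of each disease's ancestor graph (a row with only a
  disease id declares a disease whose DAG is just itself);
* similarity matrices — dense square table with matching row/column names;
* predictions — four columns ``miRNA, disease, score, rank``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationMatrix", "SimilarityMatrix", "DiseaseDAG", "DAGCollection",
    "PredictionTable", "read_association_pairs", "read_dag_collection",
    "read_similarity_matrix", "write_similarity_matrix", "write_predictions",
]

_HEADER_WORDS = {"mirna", "mi-rna", "disease", "mir", "name", "id"}


@dataclass
class AssociationMatrix:
    """Binary m x n matrix of confirmed miRNA-disease associations.

    Rows are miRNAs, columns diseases, both indexed in first-appearance
    order of the source pair list.
    """

    mirna_names: list
    disease_names: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        m, n = self.values.shape
        if m != len(self.mirna_names) or n != len(self.disease_names):
            raise ValueError("association matrix shape does not match names")
        if len(set(self.mirna_names)) != m or len(set(self.disease_names)) != n:
            raise ValueError("duplicate entity names")
        if m < 1 or n < 1:
            raise ValueError("association matrix must be non-empty")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("association entries must be 0 or 1")

    @property
    def m(self) -> int:
        return len(self.mirna_names)

    @property
    def n(self) -> int:
        return len(self.disease_names)

    @property
    def positive_pairs(self) -> set:
        rr, cc = np.nonzero(self.values)
        return {(self.mirna_names[i], self.disease_names[j]) for i, j in zip(rr, cc)}

    def mirna_index(self, name) -> int:
        return self.mirna_names.index(name)

    def disease_index(self, name) -> int:
        return self.disease_names.index(name)

    def with_values(self, values: np.ndarray) -> "AssociationMatrix":
        return AssociationMatrix(self.mirna_names, self.disease_names, values)


@dataclass
class SimilarityMatrix:
    """Dense symmetric similarity matrix in [0, 1] with entity names."""

    names: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.names)
        if self.values.shape != (k, k):
            raise ValueError("similarity matrix must be square and match names")
        if np.isnan(self.values).any():
            raise ValueError("similarity matrix contains NaN")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("similarity matrix not symmetric within 1e-9")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("similarity values must lie in [0, 1]")

    def reindex(self, names) -> "SimilarityMatrix":
        """Re-order (and subset) to the given name list; missing names error."""
        pos = {n: i for i, n in enumerate(self.names)}
        try:
            idx = [pos[n] for n in names]
        except KeyError as e:
            raise KeyError(f"name {e.args[0]!r} absent from similarity matrix") from e
        return SimilarityMatrix(list(names), self.values[np.ix_(idx, idx)])


@dataclass
class DiseaseDAG:
    """Ancestor graph of one disease: edges point parent -> child toward it."""

    target: str
    graph: nx.DiGraph

    def __post_init__(self):
        if self.target not in self.graph:
            raise ValueError(f"target {self.target!r} not in its DAG")
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError(f"cycle detected in DAG of {self.target!r}")
        reach = nx.ancestors(self.graph, self.target) | {self.target}
        if reach != set(self.graph.nodes):
            bad = set(self.graph.nodes) - reach
            raise ValueError(
                f"nodes {sorted(bad)} cannot reach target {self.target!r}")

    @property
    def nodes(self) -> set:
        """T(D): the target and all of its ancestors."""
        return set(self.graph.nodes)

    def children(self, node) -> list:
        return sorted(self.graph.successors(node))


@dataclass
class DAGCollection:
    """Mapping disease id -> DiseaseDAG for every disease with a record."""

    dags: dict = field(default_factory=dict)

    def __contains__(self, disease):
        return disease in self.dags

    def __getitem__(self, disease) -> DiseaseDAG:
        return self.dags[disease]

    def __len__(self):
        return len(self.dags)

    @property
    def diseases(self) -> list:
        return list(self.dags)


@dataclass
class PredictionTable:
    """Ranked prediction rows (miRNA, disease, score, rank)."""

    rows: list  # list of (mirna, disease, score, rank)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["miRNA", "disease", "score", "rank"])

    @classmethod
    def from_scores(cls, scored: list) -> "PredictionTable":
        """Build from (mirna, disease, score) triples; ties break by miRNA id."""
        ordered = sorted(scored, key=lambda t: (-t[2], t[0], t[1]))
        return cls([(r, d, s, k + 1) for k, (r, d, s) in enumerate(ordered)])


def _sniff_sep(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "," if ("," in first and "\t" not in first) else "\t"


def read_association_pairs(path) -> AssociationMatrix:
    """Read a two-column (miRNA, disease) pair table into a binary matrix.

    Entities are indexed in first-appearance order.  Duplicate pairs are
    dropped with a warning; malformed rows raise with their line number.
    """
    sep = _sniff_sep(path)
    pairs, mirnas, diseases = [], {}, {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    body = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip()]
    if not body:
        raise ValueError(f"{path}: empty association file")
    # optional header: first row whose fields look like column labels
    first_fields = [f.strip().lower() for f in body[0][1].split(sep)]
    if any(f in _HEADER_WORDS for f in first_fields):
        body = body[1:]
        if not body:
            raise ValueError(f"{path}: association file has a header but no rows")
    seen = set()
    dup = 0
    for lineno, ln in body:
        fields = [f.strip() for f in ln.split(sep)]
        if len(fields) != 2 or not all(fields):
            raise ValueError(f"{path}:{lineno}: malformed row {ln!r}")
        r, d = fields
        if (r, d) in seen:
            dup += 1
            continue
        seen.add((r, d))
        mirnas.setdefault(r, len(mirnas))
        diseases.setdefault(d, len(diseases))
        pairs.append((r, d))
    if dup:
        logger.warning("%s: dropped %d duplicate pair(s)", path, dup)
    A = np.zeros((len(mirnas), len(diseases)), dtype=np.int8)
    for r, d in pairs:
        A[mirnas[r], diseases[d]] = 1
    return AssociationMatrix(list(mirnas), list(diseases), A)


def read_dag_collection(path) -> DAGCollection:
    """Read a (disease, parent, child) edge list into per-disease DAGs."""
    sep = _sniff_sep(path)
    edges: dict = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    for lineno, ln in enumerate(lines, 1):
        if not ln.strip():
            continue
        fields = [f.strip() for f in ln.split(sep)]
        low = [f.lower() for f in fields]
        if lineno == 1 and low[0] in {"disease", "id"}:
            continue
        if len(fields) == 1 or (len(fields) == 3 and not fields[1] and not fields[2]):
            edges.setdefault(fields[0], [])
        elif len(fields) == 3 and all(fields):
            edges.setdefault(fields[0], []).append((fields[1], fields[2]))
        else:
            raise ValueError(f"{path}:{lineno}: malformed DAG row {ln!r}")
    dags = {}
    for disease, es in edges.items():
        g = nx.DiGraph()
        g.add_node(disease)
        g.add_edges_from(es)
        dags[disease] = DiseaseDAG(disease, g)  # validates acyclicity/reachability
    return DAGCollection(dags)


def read_similarity_matrix(path) -> SimilarityMatrix:
    """Read a dense named similarity matrix, symmetrizing small asymmetries.

    Asymmetry above 1e-6 is repaired by averaging with the transpose and
    logged; NaN entries and non-square tables raise.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: similarity matrix is not square {df.shape}")
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column names differ")
    vals = df.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError(f"{path}: similarity matrix contains NaN")
    asym = np.abs(vals - vals.T).max()
    if asym > 1e-6:
        logger.warning("%s: asymmetry %.3g repaired by averaging", path, asym)
    vals = (vals + vals.T) / 2.0
    return SimilarityMatrix([str(c) for c in df.columns], vals)


def write_similarity_matrix(sim: SimilarityMatrix, path) -> None:
    df = pd.DataFrame(sim.values, index=sim.names, columns=sim.names)
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_predictions(table: PredictionTable, path) -> None:
    """Write a ranked prediction table; validates the rank contract."""
    ranks = [row[3] for row in table.rows]
    if ranks != list(range(1, len(ranks) + 1)):
        raise ValueError("ranks must be 1..K without gaps")
    scores = [row[2] for row in table.rows]
    if any(s1 < s2 for s1, s2 in zip(scores, scores[1:])):
        raise ValueError("scores must be non-increasing with rank")
    table.to_frame().to_csv(path, sep="\t", index=False)
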