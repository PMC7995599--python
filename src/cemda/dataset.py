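"""Bundled raw inputs for one association-prediction study."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AssociationMatrix, DAGCollection, SimilarityMatrix

__all__ = ["MDADataset"]


@dataclass
class MDADataset:
    """Association matrix plus the disease DAGs and miRNA functional
    similarity it is scored against.

    Integrated similarities (SM, SD) are *not* stored here: they depend on
    the association matrix, so the estimator recomputes them from whatever
    (possibly masked) matrix it is fitted on, which keeps cross-validation
    leakage-safe.
    """

    A: AssociationMatrix
    dags: DAGCollection
    fs: SimilarityMatrix | None = None

    def masked(self, pairs) -> "MDADataset":
        """Copy with the given (miRNA, disease) name pairs zeroed in A."""
        vals = self.A.values.copy()
        for r, d in pairs:
            vals[self.A.mirna_index(r), self.A.disease_index(d)] = 0
        return MDADataset(self.A.with_values(vals), self.dags, self.fs)

    def masked_disease(self, disease) -> "MDADataset":
        """Copy with the target disease's whole column zeroed (new-disease
        protocol)."""
        vals = self.A.values.copy()
        vals[:, self.A.disease_index(disease)] = 0
        return MDADataset(self.A.with_values(vals), self.dags, self.fs)

    @property
    def positives(self) -> list:
        rr, cc = np.nonzero(self.A.values)
        return [(self.A.mirna_names[i], self.A.disease_names[j])
                for i, j in zip(rr, cc)]
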