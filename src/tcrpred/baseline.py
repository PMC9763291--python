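"""Similarity-based baseline predictor.

The baseline rests on the assumption that TCRs binding the same peptide
share high sequence similarity: for each peptide, a database of its known
positive TCRs is built from the training set, and a query TCR's prediction
score is its weighted kernel similarity to the nearest neighbour in that
database.  The baseline is inherently peptide-specific and has no trainable
parameters, which makes it the natural yardstick for any machine-learning
model on the same task.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernel import (DEFAULT_WEIGHTS, CDRWeights, KernelParams,
                     nearest_neighbor_similarity)
from .repertoire import Repertoire, TCRRecord


@dataclass
class PeptideDatabase:
    """Training positives for one peptide plus the similarity parameters."""

    peptide: str
    positives: Repertoire
    weights: CDRWeights = DEFAULT_WEIGHTS
    params: KernelParams = field(default_factory=KernelParams)

    def __post_init__(self):
        for r in self.positives:
            if r.peptide != self.peptide or r.label != 1:
                raise ValueError(
                    f"database for {self.peptide!r} contains a record with "
                    f"peptide {r.peptide!r} and label {r.label}")

    def __len__(self) -> int:
        return len(self.positives)


def score_query(query: TCRRecord, db: PeptideDatabase) -> float:
    """Similarity of ``query`` to its nearest neighbour in the database.

    In (0, 1]; a query identical to a database member scores exactly 1.
    """
    if len(db) == 0:
        raise ValueError("empty peptide database")
    sims, _ = nearest_neighbor_similarity([query], db.positives,
                                          db.weights, db.params)
    return float(sims[0])


def predict_set(queries: Repertoire, db: PeptideDatabase) -> np.ndarray:
    """Nearest-neighbour scores for every query, order-preserving."""
    if len(db) == 0:
        raise ValueError("empty peptide database")
    if len(queries) == 0:
        return np.zeros(0)
    sims, _ = nearest_neighbor_similarity(queries, db.positives,
                                          db.weights, db.params)
    return sims
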