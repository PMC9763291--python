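"""Redundancy reduction and cross-validation partitioning.

Public TCR data is highly redundant: the same clonotype is deposited many
times with trivial sequence variation, which inflates apparent model
performance whenever near-copies straddle the train/test boundary.  The
Hobohm-1 greedy algorithm builds a maximal list of mutually dissimilar
records: records are sorted by priority (here, descending combined CDR3
length), the first is kept, and each subsequent record is kept only if its
kernel similarity to every already-kept record stays strictly below a
threshold (0.95 for positives, 0.9 for the larger negative pool).

Partitioning then splits the reduced set into equally sized random
partitions for cross-validation plus one held-out evaluation partition;
optional single-linkage pre-clustering keeps whole similarity clusters in
the same partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernel import (CDR3_ONLY_WEIGHTS, CDRWeights, KernelParams, PackedLoops,
                     _hobohm, tcr_similarity_matrix)
from .repertoire import Repertoire


@dataclass(frozen=True)
class RedundancyConfig:
    """Thresholds and partition counts for redundancy handling.

    ``threshold_positive`` (default 0.95) applies to the positive set,
    ``threshold_negative`` (default 0.9) to the background/negative pool;
    ``n_partitions`` defaults to 6 (5 cross-validation + 1 evaluation).
    """

    threshold_positive: float = 0.95
    threshold_negative: float = 0.9
    n_partitions: int = 6
    seed: int = 0
    precluster: bool = False

    def __post_init__(self):
        for t in (self.threshold_positive, self.threshold_negative):
            if not (0.0 < t <= 1.0):
                raise ValueError(f"similarity threshold {t} outside (0, 1]")
        if self.n_partitions < 2:
            raise ValueError("need at least 2 partitions")


def _priority_order(rep: Repertoire) -> list[int]:
    """Descending combined CDR3 length; ties broken by (cdr3b, cdr3a)."""
    return sorted(
        range(len(rep)),
        key=lambda i: (-(len(rep[i].cdr3a) + len(rep[i].cdr3b)),
                       rep[i].cdr3b, rep[i].cdr3a))


def hobohm1_reduce(records: Repertoire, threshold: float,
                   weights: CDRWeights = CDR3_ONLY_WEIGHTS,
                   params: KernelParams = KernelParams()) -> Repertoire:
    """Greedy Hobohm-1 redundancy reduction.

    Records are visited in priority order and kept iff their weighted TCR
    similarity to every already-kept record is strictly below ``threshold``.
    The output preserves the priority order; every kept pair is guaranteed
    to be below the threshold.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold {threshold} outside (0, 1]")
    if len(records) == 0:
        return Repertoire([], dict(records.metadata))
    order = _priority_order(records)
    ordered = [records[i] for i in order]
    packed = PackedLoops(ordered, weights, params)
    keep = _hobohm(packed.flat, packed.starts, packed.ends, packed.selfk,
                   packed.weights, float(threshold), packed.E)
    kept = [rec for rec, k in zip(ordered, keep) if k]
    meta = dict(records.metadata)
    meta["hobohm_threshold"] = threshold
    meta["n_redundant_removed"] = int(len(records) - len(kept))
    return Repertoire(kept, meta)


def single_linkage_clusters(records: Repertoire, threshold: float,
                            weights: CDRWeights = CDR3_ONLY_WEIGHTS,
                            params: KernelParams = KernelParams()) -> np.ndarray:
    """Connected components of the thresholded similarity graph.

    Two records share a cluster label iff they are connected by a chain of
    pairwise similarities >= ``threshold``.  Labels are integers in order of
    first appearance.
    """
    n = len(records)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    sim = tcr_similarity_matrix(records, records, weights, params)
    parent = np.arange(n)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if sim[i, j] >= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    roots = np.array([find(i) for i in range(n)])
    labels = np.empty(n, dtype=np.int64)
    mapping: dict[int, int] = {}
    for i, r in enumerate(roots):
        if r not in mapping:
            mapping[r] = len(mapping)
        labels[i] = mapping[r]
    return labels


def partition_data(records: Repertoire, config: RedundancyConfig,
                   cluster_labels: np.ndarray | None = None) -> Repertoire:
    """Assign every record a partition id in ``0..n_partitions-1``.

    Without cluster labels each record is its own unit; with labels, whole
    clusters are assigned together so that near-identical records can never
    straddle a partition boundary.  Units are shuffled reproducibly from the
    seed and dealt round-robin, balancing unit counts within +-1.
    """
    n = len(records)
    k = config.n_partitions
    if cluster_labels is None:
        cluster_labels = np.arange(n, dtype=np.int64)
    cluster_labels = np.asarray(cluster_labels)
    if cluster_labels.shape != (n,):
        raise ValueError("cluster_labels length must match the repertoire")
    clusters = np.unique(cluster_labels)
    if k > len(clusters):
        raise ValueError(
            f"cannot split {len(clusters)} cluster(s) into {k} partitions")
    rng = np.random.default_rng(config.seed)
    shuffled = rng.permutation(clusters)
    assignment = {int(c): i % k for i, c in enumerate(shuffled)}
    out = [rec.copy(partition=assignment[int(lab)])
           for rec, lab in zip(records, cluster_labels)]
    meta = dict(records.metadata)
    meta["n_partitions"] = k
    meta["partition_seed"] = config.seed
    return Repertoire(out, meta)
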