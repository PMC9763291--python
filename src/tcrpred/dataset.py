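"""Filtering rules and training-corpus construction.

The training corpus for a peptide consists of three record classes:

* positives — experimentally annotated binders;
* true negatives — TCRs from a non-binding background pool, paired with the
  peptide (5 per positive by default);
* swapped negatives — positive TCRs mispaired with peptides other than
  their annotated target (5 per positive by default).

Before negatives are generated the positive set is cleaned: records missing
a CDR3 chain are dropped, cross-reactive TCRs (identical six-loop sequences
annotated to more than one peptide) are removed entirely, CDR3 lengths are
restricted to 6-20 residues, and peptides with too few positives are
discarded.  Generated negatives inherit the partition of their source
positive so that mispaired copies of a TCR can never leak across the
train/evaluation boundary.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .repertoire import Repertoire, TCRRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BuildConfig:
    """Filtering bounds and negative-generation counts."""

    min_cdr3_len: int = 6
    max_cdr3_len: int = 20
    min_positives_per_peptide: int = 100
    n_true_negatives_per_positive: int = 5
    n_swaps_per_positive: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.min_cdr3_len > self.max_cdr3_len:
            raise ValueError("min_cdr3_len must be <= max_cdr3_len")
        for count in (self.min_positives_per_peptide,
                      self.n_true_negatives_per_positive,
                      self.n_swaps_per_positive):
            if count < 0:
                raise ValueError("counts must be non-negative")


def filter_records(records: Repertoire, config: BuildConfig
                   ) -> tuple[Repertoire, dict[str, int]]:
    """Apply the positive-set filtering rules in order.

    Rules, applied sequentially:

    a. drop records lacking either CDR3 chain;
    b. drop cross-reactive TCRs (same six loops, >1 distinct peptide) —
       every row of such a TCR is removed;
    c. drop records with a CDR3 length outside the configured bounds;
    d. drop all rows of peptides with fewer than the minimum number of
       positive records.

    Returns the filtered repertoire and a report with removal counts per
    rule plus the number of kept records.
    """
    report = {"missing_chain": 0, "cross_reactive": 0,
              "cdr3_length": 0, "rare_peptide": 0, "kept": 0}

    stage = [r for r in records]
    kept = []
    for r in stage:
        if not r.cdr3a or not r.cdr3b:
            report["missing_chain"] += 1
        else:
            kept.append(r)
    stage = kept

    peptides_per_tcr: dict[tuple, set] = defaultdict(set)
    for r in stage:
        peptides_per_tcr[r.tcr_key()].add(r.peptide)
    kept = []
    for r in stage:
        if len(peptides_per_tcr[r.tcr_key()]) > 1:
            report["cross_reactive"] += 1
        else:
            kept.append(r)
    stage = kept

    kept = []
    lo, hi = config.min_cdr3_len, config.max_cdr3_len
    for r in stage:
        if lo <= len(r.cdr3a) <= hi and lo <= len(r.cdr3b) <= hi:
            kept.append(r)
        else:
            report["cdr3_length"] += 1
    stage = kept

    n_pos = defaultdict(int)
    for r in stage:
        if r.label == 1:
            n_pos[r.peptide] += 1
    kept = []
    for r in stage:
        if n_pos[r.peptide] >= config.min_positives_per_peptide:
            kept.append(r)
        else:
            report["rare_peptide"] += 1
    stage = kept

    report["kept"] = len(stage)
    if not stage:
        logger.warning("filtering removed every record")
    meta = dict(records.metadata)
    meta["filter_report"] = dict(report)
    return Repertoire(stage, meta), report


def sample_true_negatives(positives: Repertoire, pool: Repertoire,
                          config: BuildConfig) -> Repertoire:
    """Pair background TCRs with each positive's peptide as true negatives.

    For each positive record, ``n_true_negatives_per_positive`` TCRs are
    drawn from the background pool, labelled 0 with provenance
    ``true_negative``, given the positive's peptide and partition.  Sampling
    is without replacement per peptide (so the same background TCR never
    serves the same peptide twice, even across partitions), but a pool TCR
    may serve different peptides.  Reproducible from the seed.

    Raises
    ------
    ValueError
        If the pool cannot cover a (partition, peptide) stratum.
    """
    pool_records = list(pool)
    if config.n_true_negatives_per_positive == 0 or len(positives) == 0:
        return Repertoire([], {"provenance": "true_negative"})
    rng = np.random.default_rng(config.seed)

    strata: dict[tuple, list[TCRRecord]] = defaultdict(list)
    for r in positives:
        strata[(r.peptide, r.partition)].append(r)

    out: list[TCRRecord] = []
    peptides = sorted({pep for pep, _ in strata})
    for pep in peptides:
        order = rng.permutation(len(pool_records))
        cursor = 0
        pep_strata = sorted(((p, part) for (p, part) in strata if p == pep),
                            key=lambda x: (-1 if x[1] is None else x[1]))
        for key in pep_strata:
            need = len(strata[key]) * config.n_true_negatives_per_positive
            if cursor + need > len(order):
                raise ValueError(
                    f"background pool exhausted for stratum peptide={key[0]!r} "
                    f"partition={key[1]}: need {need}, "
                    f"have {len(order) - cursor}")
            part = key[1]
            for idx in order[cursor:cursor + need]:
                src = pool_records[idx]
                out.append(src.copy(peptide=pep, label=0,
                                    provenance="true_negative", partition=part))
            cursor += need
    return Repertoire(out, {"provenance": "true_negative", "seed": config.seed})


def generate_swapped_negatives(positives: Repertoire,
                               config: BuildConfig) -> Repertoire:
    """Mispair each positive TCR with peptides other than its target.

    Each positive is paired with ``min(n_swaps_per_positive, #other
    peptides)`` distinct non-target peptides drawn uniformly without
    replacement; emitted records copy the TCR's loops and partition, carry
    the swapped peptide, label 0 and provenance ``swapped_negative``.  No
    emitted record pairs a TCR with any peptide that TCR is positive for.

    Raises
    ------
    ValueError
        If the positives span fewer than two distinct peptides.
    """
    peptides = sorted({r.peptide for r in positives})
    if len(peptides) < 2:
        raise ValueError("swapped negatives need at least two distinct peptides")
    positive_peptides: dict[tuple, set] = defaultdict(set)
    for r in positives:
        positive_peptides[r.tcr_key()].add(r.peptide)

    rng = np.random.default_rng(config.seed)
    out: list[TCRRecord] = []
    for r in positives:
        candidates = [p for p in peptides
                      if p not in positive_peptides[r.tcr_key()]]
        n_swaps = min(config.n_swaps_per_positive, len(candidates))
        chosen = rng.choice(len(candidates), size=n_swaps, replace=False)
        for c in sorted(chosen):
            out.append(r.copy(peptide=candidates[c], label=0,
                              provenance="swapped_negative"))
    return Repertoire(out, {"provenance": "swapped_negative", "seed": config.seed})


def build_training_corpus(positives: Repertoire, pool: Repertoire,
                          config: BuildConfig) -> Repertoire:
    """Positives + true negatives + swapped negatives as one repertoire."""
    true_negs = sample_true_negatives(positives, pool, config)
    swapped = generate_swapped_negatives(positives, config)
    records = list(positives) + list(true_negs) + list(swapped)
    meta = {"n_positives": len(positives), "n_true_negatives": len(true_negs),
            "n_swapped_negatives": len(swapped), "seed": config.seed}
    return Repertoire(records, meta)
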