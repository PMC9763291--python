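"""Metrics and evaluation protocols.

Covers the full evaluation toolkit for binding predictors:

* AUC (Mann-Whitney pair-count formulation, ties counted half),
* AUC 0.1 — the partial area under the ROC curve up to a false-positive
  rate of 0.1, normalised by 0.1,
* PPV — fraction of positives among the top-n predictions (n = number of
  positives),
* per-peptide reports with mean and positive-count-weighted mean AUC,
* a paired bootstrap test for comparing two models' AUCs,
* percentile-rank calibration against a background repertoire (lower is
  better, 0 = best),
* peptide-target ranking (which peptide does a positive TCR score highest
  against?) with the top_TP / second_TN / top_FP / FN score categories,
* performance as a function of similarity ("distance") between the
  evaluation and training sets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .kernel import (DEFAULT_WEIGHTS, CDRWeights, KernelParams,
                     nearest_neighbor_similarity)
from .repertoire import Repertoire

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Scalar metrics

def auc(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """Probability that a positive outscores a negative (ties count half)."""
    pos = np.asarray(pos_scores, dtype=np.float64)
    neg = np.asarray(neg_scores, dtype=np.float64)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[:pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2.0)
                 / (pos.size * neg.size))


def _roc_points(pos: np.ndarray, neg: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """Empirical ROC as (fpr, tpr) arrays, tied scores stepped jointly."""
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    # group boundaries at distinct score values
    distinct = np.nonzero(np.diff(scores))[0]
    cut = np.concatenate([distinct, [scores.size - 1]])
    tp = np.cumsum(labels)[cut]
    fp = np.cumsum(1 - labels)[cut]
    tpr = np.concatenate([[0.0], tp / pos.size])
    fpr = np.concatenate([[0.0], fp / neg.size])
    return fpr, tpr


def auc01(pos_scores: Sequence[float], neg_scores: Sequence[float],
          max_fpr: float = 0.1) -> float:
    """Partial ROC area for FPR in [0, max_fpr], normalised to [0, 1].

    Trapezoidal integration over the empirical ROC with linear
    interpolation at the cut-off; perfect separation gives 1, a random
    (diagonal) ROC gives ``max_fpr / 2``.
    """
    pos = np.asarray(pos_scores, dtype=np.float64)
    neg = np.asarray(neg_scores, dtype=np.float64)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    fpr, tpr = _roc_points(pos, neg)
    keep = fpr <= max_fpr
    fx, fy = fpr[keep], tpr[keep]
    if fx[-1] < max_fpr and keep.sum() < fpr.size:
        # interpolate on the segment crossing the cut-off; a vertical climb
        # exactly at max_fpr contributes zero width and is kept as-is above
        j = int(keep.sum())
        t = fy[-1] + (tpr[j] - fy[-1]) * (max_fpr - fx[-1]) / (fpr[j] - fx[-1])
        fx = np.concatenate([fx, [max_fpr]])
        fy = np.concatenate([fy, [t]])
    return float(np.trapezoid(fy, fx) / max_fpr)


def ppv(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Fraction of positives among the top-n predictions, n = #positives.

    Sorting is a stable descending sort, so tied scores keep their input
    order (deterministic and documented).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise ValueError("PPV needs at least one positive")
    order = np.argsort(-scores, kind="stable")
    top = labels[order[:n_pos]]
    return float((top == 1).mean())


def bootstrap_auc_test(preds_a: Sequence[float], preds_b: Sequence[float],
                       labels: Sequence[int], n_boot: int = 1000,
                       seed: int = 0) -> float:
    """Paired bootstrap comparison of two models' AUCs.

    Record indices are resampled jointly ``n_boot`` times at the original
    size; the p-value is the fraction of resamples where model A's AUC is
    below model B's, ties counting half.  A resample that loses one of the
    classes is redrawn (and logged).
    """
    a = np.asarray(preds_a, dtype=np.float64)
    b = np.asarray(preds_b, dtype=np.float64)
    y = np.asarray(labels)
    if not (a.size == b.size == y.size):
        raise ValueError("prediction and label vectors must share a length")
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes")
    rng = np.random.default_rng(seed)
    n = y.size
    wins_b = 0.0
    redrawn = 0
    for _ in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            ys = y[idx]
            if ys.min() == 0 and ys.max() == 1:
                break
            redrawn += 1
        pos, neg = idx[ys == 1], idx[ys == 0]
        auc_a = auc(a[pos], a[neg])
        auc_b = auc(b[pos], b[neg])
        if auc_a < auc_b:
            wins_b += 1.0
        elif auc_a == auc_b:
            wins_b += 0.5
    if redrawn:
        logger.info("bootstrap: redrew %d degenerate resamples", redrawn)
    return wins_b / n_boot


# ---------------------------------------------------------------------------
# Percentile-rank calibration

@dataclass
class RankCalibration:
    """Per-peptide background score distributions for rank calibration.

    The background repertoire must be disjoint from the training data.
    ``percentile_rank(s)`` is the proportion of background TCRs scoring
    strictly higher than ``s`` — 0 is the best possible rank.
    """

    backgrounds: dict[str, np.ndarray] = field(default_factory=dict)

    def add(self, peptide: str, scores: Sequence[float]) -> None:
        arr = np.sort(np.asarray(scores, dtype=np.float64))
        if arr.size == 0:
            raise ValueError("background score list must be non-empty")
        self.backgrounds[peptide] = arr

    def size(self, peptide: str) -> int:
        return self.backgrounds[peptide].size

    def percentile_rank(self, score: float, peptide: str) -> float:
        if peptide not in self.backgrounds:
            raise ValueError(f"no calibration for peptide {peptide!r}")
        bg = self.backgrounds[peptide]
        n_higher = bg.size - np.searchsorted(bg, score, side="right")
        return float(n_higher) / bg.size

    def percentile_ranks(self, scores: Sequence[float], peptide: str) -> np.ndarray:
        return np.array([self.percentile_rank(float(s), peptide)
                         for s in np.asarray(scores)])


def percentile_rank(score: float, calibration: RankCalibration,
                    peptide: str) -> float:
    """Functional wrapper around :meth:`RankCalibration.percentile_rank`."""
    return calibration.percentile_rank(score, peptide)


# ---------------------------------------------------------------------------
# Peptide-target ranking

def peptide_rank_analysis(models: Mapping[str, Callable[[Repertoire], np.ndarray]],
                          positives: Repertoire,
                          peptides: Optional[Sequence[str]] = None,
                          calibration: Optional[RankCalibration] = None
                          ) -> pd.DataFrame:
    """Rank each positive TCR's true peptide among all candidate peptides.

    Every positive TCR is paired with every peptide and scored by that
    peptide's model.  With raw scores, ranking is descending (rank 1 =
    highest score); when a :class:`RankCalibration` is supplied the
    percentile-rank scores are ranked ascending instead (0 is best).

    Returns one row per positive TCR with columns ``true_peptide``,
    ``rank`` (1-based), ``tied`` (True when another peptide ties at rank 1),
    ``category`` (``top_TP`` when the true peptide ranks first, else
    ``FN``), the score of the true peptide, and the runner-up/top scores
    (``second_TN`` when correct, ``top_FP`` otherwise).
    """
    if peptides is None:
        peptides = sorted(models)
    missing = {r.peptide for r in positives} - set(peptides)
    if missing:
        raise ValueError(f"positives reference unknown peptides: {sorted(missing)}")

    score_cols = {}
    for pep in peptides:
        raw = np.asarray(models[pep](positives), dtype=np.float64)
        if calibration is not None:
            raw = calibration.percentile_ranks(raw, pep)
        score_cols[pep] = raw
    S = np.column_stack([score_cols[p] for p in peptides])
    if calibration is not None:
        S = -S  # ascending percentile rank == descending negated rank

    rows = []
    for i, rec in enumerate(positives):
        scores = S[i]
        true_j = list(peptides).index(rec.peptide)
        true_score = scores[true_j]
        rank = int(1 + np.sum(scores > true_score))
        top_j = int(np.argmax(scores))
        n_top = int(np.sum(scores == scores.max()))
        tied = rank == 1 and n_top > 1
        if rank == 1:
            others = np.delete(scores, true_j)
            row = {"category": "top_TP", "true_score": true_score,
                   "other_score": float(others.max()),
                   "other_category": "second_TN",
                   "top_peptide": rec.peptide}
        else:
            row = {"category": "FN", "true_score": true_score,
                   "other_score": float(scores[top_j]),
                   "other_category": "top_FP",
                   "top_peptide": peptides[top_j]}
        if calibration is not None:
            row["true_score"] = -row["true_score"]
            row["other_score"] = -row["other_score"]
        row.update({"true_peptide": rec.peptide, "rank": rank, "tied": tied})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Performance vs distance to training data

def distance_performance_curve(train: Repertoire, eval_set: Repertoire,
                               scores: Sequence[float],
                               thresholds: Optional[Sequence[float]] = None,
                               rank_filter: float = 0.3,
                               percentile_ranks: Optional[Sequence[float]] = None,
                               weights: CDRWeights = DEFAULT_WEIGHTS,
                               params: KernelParams = KernelParams()
                               ) -> pd.DataFrame:
    """AUC of ``scores`` after excluding evaluation TCRs close to training.

    Each evaluation record's distance to training is measured as the kernel
    similarity to its nearest neighbour anywhere in the training set
    (positive or negative).  For each threshold, records whose similarity
    exceeds the threshold are dropped and the AUC recomputed on the
    remainder.  When ``percentile_ranks`` are supplied, positives with a
    rank above ``rank_filter`` are first removed (noise suppression);
    negatives are never rank-filtered.

    Returns a frame with columns ``threshold``, ``auc`` (NaN when fewer
    than 2 records of either class remain) and ``n_retained_pos`` /
    ``n_retained_neg``.
    """
    if thresholds is None:
        thresholds = np.linspace(0.89, 0.98, 10)
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.array([r.label for r in eval_set])
    if scores.size != len(eval_set):
        raise ValueError("scores length must match the evaluation set")

    keep = np.ones(len(eval_set), dtype=bool)
    if percentile_ranks is not None:
        pr = np.asarray(percentile_ranks, dtype=np.float64)
        keep &= ~((labels == 1) & (pr > rank_filter))
    idx = np.nonzero(keep)[0]
    nn_sim, _ = nearest_neighbor_similarity(
        eval_set.subset(idx), train, weights, params)

    rows = []
    for thr in thresholds:
        mask = nn_sim <= thr
        y = labels[idx][mask]
        s = scores[idx][mask]
        n_pos = int((y == 1).sum())
        n_neg = int((y == 0).sum())
        if n_pos >= 2 and n_neg >= 2:
            value = auc(s[y == 1], s[y == 0])
        else:
            value = np.nan
        rows.append({"threshold": float(thr), "auc": value,
                     "n_retained_pos": n_pos, "n_retained_neg": n_neg})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reports

@dataclass
class EvalReport:
    """Per-peptide and averaged metrics for one model.

    ``per_peptide`` maps peptide -> task -> metric dict, where tasks are
    ``"true_negative"`` and ``"swapped_negative"`` (positives versus that
    negative class).  Averages are the plain mean over peptides and the
    mean weighted by the number of positive evaluation TCRs.
    """

    per_peptide: dict[str, dict[str, dict[str, float]]]
    n_positives: dict[str, int]
    mean_auc: dict[str, float]
    weighted_mean_auc: dict[str, float]

    def to_json(self) -> str:
        return json.dumps({
            "per_peptide": self.per_peptide,
            "n_positives": self.n_positives,
            "mean_auc": self.mean_auc,
            "weighted_mean_auc": self.weighted_mean_auc,
        }, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        d = json.loads(text)
        return cls(d["per_peptide"], d["n_positives"],
                   d["mean_auc"], d["weighted_mean_auc"])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pep, tasks in self.per_peptide.items():
            for task, metrics in tasks.items():
                rows.append({"peptide": pep, "task": task,
                             "n_positives": self.n_positives[pep], **metrics})
        return pd.DataFrame(rows)


def compute_report(per_peptide_scores: Mapping[str, Mapping[str, tuple]]
                   ) -> EvalReport:
    """Build an :class:`EvalReport` from per-peptide score/label pairs.

    ``per_peptide_scores[peptide][task]`` is a ``(scores, labels)`` pair
    for the positives-versus-that-negative-class task.
    """
    per_peptide: dict[str, dict[str, dict[str, float]]] = {}
    n_positives: dict[str, int] = {}
    for pep, tasks in per_peptide_scores.items():
        per_peptide[pep] = {}
        for task, (scores, labels) in tasks.items():
            scores = np.asarray(scores, dtype=np.float64)
            labels = np.asarray(labels)
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            per_peptide[pep][task] = {
                "auc": auc(pos, neg),
                "auc01": auc01(pos, neg),
                "ppv": ppv(scores, labels),
            }
            n_positives[pep] = int((labels == 1).sum())
    tasks = sorted({t for d in per_peptide.values() for t in d})
    mean_auc = {}
    weighted = {}
    for task in tasks:
        peps = [p for p in per_peptide if task in per_peptide[p]]
        values = np.array([per_peptide[p][task]["auc"] for p in peps])
        w = np.array([n_positives[p] for p in peps], dtype=np.float64)
        mean_auc[task] = float(values.mean())
        weighted[task] = float(np.average(values, weights=w))
    return EvalReport(per_peptide, n_positives, mean_auc, weighted)
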