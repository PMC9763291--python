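"""Alignment-free k-mer string-kernel similarity between CDR loops.

Because CDR3 junctions arise from stochastic V(D)J recombination, classical
gap-penalised alignment scores are not meaningful for TCR loops.  Instead,
two sequences are compared through a k-mer kernel: all k-mers of the first
sequence are scored against all k-mers of the second, for every k from 1 to
the length of the shorter sequence.  In the default (product-exponential)
form, a pair of k-mers contributes the product over aligned positions of
``exp(beta * B(x, y))`` where ``B`` is a substitution matrix (BLOSUM62) and
``beta`` a scaling constant (0.11387).  The raw kernel is then
self-similarity normalised,

    sim(s, t) = K(s, t) / sqrt(K(s, s) * K(t, t))  in (0, 1],

so that identical sequences score exactly 1.  A whole TCR is compared as a
weighted mean of the six per-loop similarities (default loop weights
[1, 1, 4] per chain, i.e. CDR3 counts four times CDR1/2).

The naive enumeration over all k-mer pairs is O(L^4); the implementation
uses the suffix-product recurrence ``S[i,j] = E[i,j] * (1 + S[i+1,j+1])``
with ``K = sum_ij S[i,j]``, which visits each residue pair once.  A literal
additive reading of the kernel (plain sum of BLOSUM scores over k-mer
pairs) is available via ``KernelParams(form="additive")`` for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .repertoire import AMINO_ACIDS, LOOP_FIELDS, Repertoire, TCRRecord

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@lru_cache(maxsize=8)
def load_substitution_matrix(matrix_id: str) -> np.ndarray:
    """20x20 substitution matrix over :data:`AMINO_ACIDS`, loaded via Biopython."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load(matrix_id)
    out = np.empty((20, 20), dtype=np.float64)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            out[i, j] = mat[a, b]
    return out


@dataclass(frozen=True)
class KernelParams:
    """Parameters of the k-mer kernel.

    Parameters
    ----------
    matrix_id:
        Substitution matrix name understood by Biopython (default BLOSUM62).
    beta:
        Positive scaling constant inside the per-residue exponential;
        the default 0.11387 is the published TCRMatch constant.
    max_k:
        Optional cap on the k-mer length; ``None`` means "up to the length
        of the shorter sequence".
    form:
        ``"product"`` (default) for the product-exponential kernel, or
        ``"additive"`` for the plain sum of substitution scores.
    """

    matrix_id: str = "BLOSUM62"
    beta: float = 0.11387
    max_k: Optional[int] = None
    form: str = "product"

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.max_k is not None and self.max_k < 1:
            raise ValueError("max_k must be >= 1")
        if self.form not in ("product", "additive"):
            raise ValueError(f"unknown kernel form {self.form!r}")

    def exp_matrix(self) -> np.ndarray:
        """``exp(beta * B)`` as a 20x20 array (cached per parameters)."""
        return _exp_matrix(self.matrix_id, self.beta)


@lru_cache(maxsize=8)
def _exp_matrix(matrix_id: str, beta: float) -> np.ndarray:
    return np.exp(beta * load_substitution_matrix(matrix_id))


@dataclass(frozen=True)
class CDRWeights:
    """Non-negative weights of the six CDR loops (order 1a,2a,3a,1b,2b,3b)."""

    w1a: float = 1.0
    w2a: float = 1.0
    w3a: float = 4.0
    w1b: float = 1.0
    w2b: float = 1.0
    w3b: float = 4.0

    def __post_init__(self):
        arr = self.as_array()
        if np.any(arr < 0):
            raise ValueError("loop weights must be non-negative")
        if not np.any(arr > 0):
            raise ValueError("at least one loop weight must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.w1a, self.w2a, self.w3a,
                         self.w1b, self.w2b, self.w3b], dtype=np.float64)


#: Default all-CDR weighting, CDR3 counted four times CDR1/2 on each chain.
DEFAULT_WEIGHTS = CDRWeights()
#: CDR3-only weighting: the plain average of the alpha and beta CDR3 scores.
CDR3_ONLY_WEIGHTS = CDRWeights(0, 0, 1, 0, 0, 1)


def encode_sequence_indices(seq: str) -> np.ndarray:
    """Map an amino-acid string to int64 alphabet indices."""
    try:
        return np.array([_AA_INDEX[a] for a in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-canonical amino acid {exc.args[0]!r} in {seq!r}") from exc


# ---------------------------------------------------------------------------
# Jitted inner loops

@njit(cache=True)
def _kraw(a, b, E):  # pragma: no cover - exercised through wrappers
    """Raw product-exponential kernel via the suffix-product recurrence."""
    la = a.shape[0]
    lb = b.shape[0]
    cur = np.zeros(lb)
    nxt = np.zeros(lb)
    total = 0.0
    for i in range(la - 1, -1, -1):
        for j in range(lb - 1, -1, -1):
            down = nxt[j + 1] if j + 1 < lb else 0.0
            v = E[a[i], b[j]] * (1.0 + down)
            cur[j] = v
            total += v
        tmp = nxt
        nxt = cur
        cur = tmp
    return total


@njit(cache=True)
def _self_kernels(flat, starts, ends, E):  # pragma: no cover
    n = starts.shape[0]
    out = np.zeros((n, 6))
    for i in range(n):
        for l in range(6):
            s, e = starts[i, l], ends[i, l]
            if e > s:
                out[i, l] = _kraw(flat[s:e], flat[s:e], E)
    return out


@njit(cache=True)
def _pair_sim(flat1, st1, en1, self1, i, flat2, st2, en2, self2, j, w, E):  # pragma: no cover
    num = 0.0
    den = 0.0
    for l in range(6):
        if w[l] > 0.0:
            k = _kraw(flat1[st1[i, l]:en1[i, l]], flat2[st2[j, l]:en2[j, l]], E)
            num += w[l] * k / np.sqrt(self1[i, l] * self2[j, l])
            den += w[l]
    return num / den


@njit(cache=True)
def _sim_matrix(flat1, st1, en1, self1, flat2, st2, en2, self2, w, E):  # pragma: no cover
    n1 = st1.shape[0]
    n2 = st2.shape[0]
    out = np.empty((n1, n2))
    for i in range(n1):
        for j in range(n2):
            out[i, j] = _pair_sim(flat1, st1, en1, self1, i,
                                  flat2, st2, en2, self2, j, w, E)
    return out


@njit(cache=True)
def _nn_max(flatq, stq, enq, selfq, flatr, str_, enr, selfr, w, E):  # pragma: no cover
    nq = stq.shape[0]
    nr = str_.shape[0]
    best = np.zeros(nq)
    arg = np.full(nq, -1, dtype=np.int64)
    for i in range(nq):
        b = -1.0
        a = -1
        for j in range(nr):
            s = _pair_sim(flatq, stq, enq, selfq, i, flatr, str_, enr, selfr, j, w, E)
            if s > b:
                b = s
                a = j
        best[i] = b
        arg[i] = a
    return best, arg


@njit(cache=True)
def _hobohm(flat, st, en, selfk, w, thr, E):  # pragma: no cover
    """Greedy Hobohm-1 pass over records already in priority order."""
    n = st.shape[0]
    keep = np.zeros(n, dtype=np.bool_)
    kept_idx = np.empty(n, dtype=np.int64)
    n_kept = 0
    for i in range(n):
        ok = True
        for m in range(n_kept):
            j = kept_idx[m]
            s = _pair_sim(flat, st, en, selfk, i, flat, st, en, selfk, j, w, E)
            if s >= thr:
                ok = False
                break
        if ok:
            keep[i] = True
            kept_idx[n_kept] = i
            n_kept += 1
    return keep


# ---------------------------------------------------------------------------
# Packing records for the jitted routines

class PackedLoops:
    """Six CDR loops of a record collection, flattened for jitted kernels.

    Only loops with a positive weight need to be non-empty; empty loops are
    stored as zero-length slices and must not be touched by the kernels.
    """

    def __init__(self, records: Sequence[TCRRecord], weights: CDRWeights,
                 params: KernelParams):
        w = weights.as_array()
        flat: list[int] = []
        n = len(records)
        starts = np.zeros((n, 6), dtype=np.int64)
        ends = np.zeros((n, 6), dtype=np.int64)
        for i, rec in enumerate(records):
            for l, name in enumerate(LOOP_FIELDS):
                seq = getattr(rec, name)
                if w[l] > 0 and not seq:
                    raise ValueError(
                        f"record {i}: loop {name} is empty but has weight {w[l]}")
                starts[i, l] = len(flat)
                if w[l] > 0:
                    flat.extend(encode_sequence_indices(seq))
                ends[i, l] = len(flat)
        self.flat = np.array(flat, dtype=np.int64)
        self.starts = starts
        self.ends = ends
        self.weights = w
        self.E = params.exp_matrix()
        self.selfk = _self_kernels(self.flat, starts, ends, self.E)


# ---------------------------------------------------------------------------
# Public API

def kmer_kernel_raw(s: str, t: str, params: KernelParams = KernelParams()) -> float:
    """Un-normalised kernel K(s, t); symmetric and strictly positive."""
    if not s or not t:
        raise ValueError("kernel sequences must be non-empty")
    a = encode_sequence_indices(s)
    b = encode_sequence_indices(t)
    cap = params.max_k
    uncapped = cap is None or cap >= min(len(s), len(t))
    if params.form == "product" and uncapped:
        return float(_kraw(a, b, params.exp_matrix()))
    if params.form == "product":
        return _kraw_capped(a, b, params.exp_matrix(), cap)
    B = load_substitution_matrix(params.matrix_id)
    return _additive_raw(a, b, B, None if uncapped else cap)


def _kraw_capped(a: np.ndarray, b: np.ndarray, E: np.ndarray, cap: int) -> float:
    # w_t = sum over window lengths 1..cap of products along each diagonal.
    total = 0.0
    la, lb = len(a), len(b)
    for off in range(-(la - 1), lb):
        i0, j0 = (0, off) if off >= 0 else (-off, 0)
        m = min(la - i0, lb - j0)
        e = np.array([E[a[i0 + t], b[j0 + t]] for t in range(m)])
        w_next = 0.0
        for t in range(m - 1, -1, -1):
            w_t = e[t] * (1.0 + w_next)
            if t + cap < m:
                w_t -= np.prod(e[t:t + cap + 1])
            total += w_t
            w_next = w_t
    return float(total)


def _additive_raw(a: np.ndarray, b: np.ndarray, B: np.ndarray,
                  cap: Optional[int]) -> float:
    # Sum of substitution scores over all k-mer pairs: along each diagonal a
    # position t is covered by (number of windows containing t) windows.
    total = 0.0
    la, lb = len(a), len(b)
    for off in range(-(la - 1), lb):
        i0, j0 = (0, off) if off >= 0 else (-off, 0)
        m = min(la - i0, lb - j0)
        for t in range(m):
            if cap is None:
                count = (t + 1) * (m - t)
            else:
                count = sum(1 for start in range(t + 1)
                            for length in range(1, min(cap, m - start) + 1)
                            if start + length > t)
            total += count * B[a[i0 + t], b[j0 + t]]
    return float(total)


def kernel_similarity(s: str, t: str, params: KernelParams = KernelParams()) -> float:
    """Self-similarity-normalised kernel, in (0, 1]; 1 iff ``s == t``."""
    kst = kmer_kernel_raw(s, t, params)
    kss = kmer_kernel_raw(s, s, params)
    ktt = kmer_kernel_raw(t, t, params)
    if kss <= 0 or ktt <= 0:
        raise ValueError("non-positive self-kernel; normalization undefined "
                         "(additive form with negative scores?)")
    return float(kst / np.sqrt(kss * ktt))


def tcr_similarity(a: TCRRecord, b: TCRRecord,
                   weights: CDRWeights = DEFAULT_WEIGHTS,
                   params: KernelParams = KernelParams()) -> float:
    """Weighted mean of per-loop kernel similarities between two TCRs.

    Loops with zero weight are ignored (and may be empty); with the
    CDR3-only weights this is the plain average of the alpha- and beta-CDR3
    similarities used for redundancy reduction.
    """
    w = weights.as_array()
    num = 0.0
    den = 0.0
    for l, name in enumerate(LOOP_FIELDS):
        if w[l] <= 0:
            continue
        sa, sb = getattr(a, name), getattr(b, name)
        if not sa or not sb:
            raise ValueError(f"loop {name} has weight {w[l]} but is empty")
        num += w[l] * kernel_similarity(sa, sb, params)
        den += w[l]
    return num / den


def tcr_similarity_matrix(a: Repertoire | Sequence[TCRRecord],
                          b: Repertoire | Sequence[TCRRecord],
                          weights: CDRWeights = DEFAULT_WEIGHTS,
                          params: KernelParams = KernelParams()) -> np.ndarray:
    """All-pairs weighted TCR similarity, shape (len(a), len(b))."""
    if params.form != "product" or (params.max_k is not None):
        raise NotImplementedError("batch similarity supports the default "
                                  "uncapped product kernel only")
    pa = PackedLoops(list(a), weights, params)
    pb = PackedLoops(list(b), weights, params)
    return _sim_matrix(pa.flat, pa.starts, pa.ends, pa.selfk,
                       pb.flat, pb.starts, pb.ends, pb.selfk,
                       weights.as_array(), pa.E)


def nearest_neighbor_similarity(queries: Repertoire | Sequence[TCRRecord],
                                refs: Repertoire | Sequence[TCRRecord],
                                weights: CDRWeights = DEFAULT_WEIGHTS,
                                params: KernelParams = KernelParams()
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Max weighted similarity of each query to any reference record.

    Returns ``(similarities, argmax_indices)``.
    """
    refs = list(refs)
    if not refs:
        raise ValueError("reference set must be non-empty")
    if params.form != "product" or (params.max_k is not None):
        raise NotImplementedError("batch similarity supports the default "
                                  "uncapped product kernel only")
    pq = PackedLoops(list(queries), weights, params)
    pr = PackedLoops(refs, weights, params)
    return _nn_max(pq.flat, pq.starts, pq.ends, pq.selfk,
                   pr.flat, pr.starts, pr.ends, pr.selfk,
                   weights.as_array(), pq.E)
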