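"""Synthetic TCR repertoires with controllable peptide-specific signal.

Real peptide-specific repertoires show four exploitable regularities that
the generator emulates so every pipeline stage is testable without any
external download:

* convergent recombination: a peptide's binders cluster into founder
  clonotype families whose CDR3 junctions differ by a few substitutions,
  so binders of the same peptide share high kernel similarity;
* a short CDR3beta sequence motif conserved across ALL of a peptide's
  families (the learnable binding signal), blurred by per-residue motif
  mutation at a configurable rate;
* biased V-gene usage — for some peptides the great majority of binders
  carry one particular alpha V gene (melanoma ELAGIGILTV binders are the
  canonical example, ~85% TRAV12-2), which leaks signal into CDR1/2;
* heavy redundancy: clonotypes re-deposited with identical CDR3 junctions
  but re-drawn V/J gene annotations, which is exactly what Hobohm
  reduction at a high similarity threshold exists to remove.

Background (non-binding) TCRs are motif-free random sequences with uniform
gene usage.  Everything is reproducible from the seed.  CDR3 loops follow
the standard junction convention (start with the conserved C, end with
F/W), so generated records survive full-chain reconstruction against the
generated germline gene table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .repertoire import (AMINO_ACIDS, GeneEntry, GeneTable, Repertoire,
                         TCRRecord)

_AA = np.array(list(AMINO_ACIDS))
_AA_NO_C = np.array([a for a in AMINO_ACIDS if a != "C"])


@dataclass(frozen=True)
class PeptideSpec:
    """Signal definition for one peptide's positive TCRs."""

    peptide: str
    motif: str
    n_positives: int = 200
    mutation_rate: float = 0.15
    v_bias_gene: str = ""      # alpha-chain V gene receiving the bias mass
    v_bias: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must be in [0, 1]")
        if not (0.0 <= self.v_bias <= 1.0):
            raise ValueError("v_bias must be in [0, 1]")
        if self.v_bias > 0 and not self.v_bias_gene:
            raise ValueError("v_bias requires v_bias_gene")


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; the defaults define the standard study conditions.

    Four peptides with 200 positives each drawn from 25 founder clonotype
    families, motif mutation rate 0.15, family diversification rate 0.10
    outside the motif, an 85% alpha V-gene bias on the ELAGIGILTV-like
    peptide, a background pool of 4000 TCRs, 10% near-duplicates (clonotype
    re-deposits), and CDR3 lengths 10-16.
    """

    peptides: tuple[PeptideSpec, ...] = (
        PeptideSpec("GILGFVFTL", "WQDR"),
        PeptideSpec("RAKFKQLL", "HLGA"),
        PeptideSpec("ELAGIGILTV", "FYNE", v_bias_gene="TRAV3", v_bias=0.85),
        PeptideSpec("NLVPMVATV", "KVSP"),
    )
    n_founders: int = 25
    diversification_rate: float = 0.10
    background_size: int = 4000
    near_duplicate_rate: float = 0.1
    cdr3_len_range: tuple[int, int] = (10, 16)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.cdr3_len_range
        if not (6 <= lo <= hi <= 20):
            raise ValueError("cdr3_len_range must lie within [6, 20]")
        if not (0.0 <= self.near_duplicate_rate <= 1.0):
            raise ValueError("near_duplicate_rate must be in [0, 1]")
        if not (0.0 <= self.diversification_rate <= 1.0):
            raise ValueError("diversification_rate must be in [0, 1]")
        if self.n_founders < 1:
            raise ValueError("n_founders must be >= 1")
        for spec in self.peptides:
            if len(spec.motif) >= lo - 2:
                raise ValueError(
                    f"motif {spec.motif!r} does not fit inside the shortest "
                    f"CDR3 (length {lo}) with its anchors")
            if len(spec.peptide) > 13:
                raise ValueError("peptide longer than the pad length 13")


def generate_gene_table(n_v_per_chain: int = 8, n_j_per_chain: int = 4,
                        seed: int = 0) -> GeneTable:
    """Random germline gene table satisfying the reconstruction anchors.

    Every V gene carries a cysteine among its last six residues (and its
    CDR1/CDR2 are substrings of the germline sequence); every J gene has an
    F/W-followed-by-G motif within its first 11 residues.
    """
    if n_v_per_chain < 1 or n_j_per_chain < 1:
        raise ValueError("gene counts must be >= 1")
    rng = np.random.default_rng(seed)
    table = GeneTable()
    for chain in "AB":
        for i in range(n_v_per_chain):
            seq = rng.choice(_AA_NO_C, size=25)
            seq[-3] = "C"  # conserved junction cysteine in the last six
            seq = "".join(seq)
            table.add(chain, "V", f"TR{chain}V{i + 1}",
                      GeneEntry(seq, cdr1=seq[4:10], cdr2=seq[13:19]))
        for i in range(n_j_per_chain):
            seq = rng.choice(_AA_NO_C, size=14)
            seq[1] = rng.choice(["F", "W"])
            seq[2] = "G"
            table.add(chain, "J", f"TR{chain}J{i + 1}",
                      GeneEntry("".join(seq)))
    return table


def _random_cdr3(rng: np.random.Generator, length: int) -> str:
    body = "".join(rng.choice(_AA, size=length - 2))
    return "C" + body + str(rng.choice(["F", "W"], p=[0.8, 0.2]))


def _implant_motif(cdr3: str, motif: str, rate: float,
                   rng: np.random.Generator) -> str:
    """Place a (possibly mutated) motif at a random internal position.

    Position 0 (the conserved C) and the terminal anchor are never touched.
    """
    lo, hi = 1, len(cdr3) - 1 - len(motif)
    if hi < lo:
        raise ValueError(f"motif {motif!r} too long for CDR3 {cdr3!r}")
    pos = int(rng.integers(lo, hi + 1))
    mutated = [a if rng.random() >= rate else str(rng.choice(_AA))
               for a in motif]
    return cdr3[:pos] + "".join(mutated) + cdr3[pos + len(motif):]


def _pick_gene(genes: list[str], rng: np.random.Generator,
               bias_gene: str = "", bias: float = 0.0) -> str:
    if bias > 0 and rng.random() < bias:
        return bias_gene
    return str(rng.choice(genes))


def _mutate_positions(seq: str, positions: list[int], rate: float,
                      rng: np.random.Generator) -> str:
    out = list(seq)
    for i in positions:
        if rng.random() < rate:
            out[i] = str(rng.choice(_AA))
    return "".join(out)


def generate_repertoire(config: SynthConfig, table: GeneTable
                        ) -> tuple[Repertoire, Repertoire]:
    """Generate (positives, background pool) under the configured signal.

    Each peptide's positives derive from ``n_founders`` founder clonotypes.
    A founder carries the peptide's motif verbatim at a fixed internal
    CDR3beta position; each positive copies a random founder, mutates
    internal non-motif CDR3 residues at the diversification rate and motif
    residues at the peptide's motif mutation rate, and draws V/J genes
    independently (the alpha V gene under the peptide's bias, if any), with
    CDR1/2 filled from the gene table.  A fraction of positives is
    re-emitted as a near-duplicate: identical CDR3 loops with re-drawn gene
    annotations (a clonotype re-deposit; CDR3 similarity exactly 1).
    Background TCRs are motif-free with uniform gene usage, carry no
    peptide, and are labelled 0.
    """
    rng = np.random.default_rng(config.seed)
    va_genes = table.genes("A", "V")
    vb_genes = table.genes("B", "V")
    ja_genes = table.genes("A", "J")
    jb_genes = table.genes("B", "J")
    lo, hi = config.cdr3_len_range

    # Antigen-driven V-gene skew: each peptide draws its V genes from a
    # concentrated usage distribution (a few preferred genes), background
    # from the uniform one.  An explicit v_bias puts that much mass on one
    # named alpha V gene (the extreme single-gene case).
    usage: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for spec in config.peptides:
        pa = rng.dirichlet(np.full(len(va_genes), 0.3))
        if spec.v_bias > 0:
            pa = (1.0 - spec.v_bias) * pa
            pa[va_genes.index(spec.v_bias_gene)] += spec.v_bias
        pb = rng.dirichlet(np.full(len(vb_genes), 0.3))
        usage[spec.peptide] = (pa, pb)

    def draw_genes(spec: PeptideSpec | None) -> tuple[str, str, str, str]:
        if spec is None:
            va = _pick_gene(va_genes, rng)
            vb = _pick_gene(vb_genes, rng)
        else:
            pa, pb = usage[spec.peptide]
            va = str(rng.choice(va_genes, p=pa))
            vb = str(rng.choice(vb_genes, p=pb))
        return (va, _pick_gene(ja_genes, rng),
                vb, _pick_gene(jb_genes, rng))

    def assemble(cdr3a: str, cdr3b: str, peptide: str, label: int,
                 provenance: str, genes: tuple[str, str, str, str]) -> TCRRecord:
        va, ja, vb, jb = genes
        ea = table.lookup("A", "V", va)
        eb = table.lookup("B", "V", vb)
        return TCRRecord(
            cdr3a=cdr3a, cdr3b=cdr3b, peptide=peptide,
            cdr1a=ea.cdr1, cdr2a=ea.cdr2, cdr1b=eb.cdr1, cdr2b=eb.cdr2,
            v_gene_a=va, j_gene_a=ja, v_gene_b=vb, j_gene_b=jb,
            label=label, provenance=provenance)

    seen: set[tuple[str, ...]] = set()

    def emit(target: list[TCRRecord], rec: TCRRecord) -> bool:
        key = rec.identity_key()
        if key in seen:
            return False
        seen.add(key)
        target.append(rec)
        return True

    positives: list[TCRRecord] = []
    n_near_dups = 0
    for spec in config.peptides:
        # founder clonotypes: motif placed once, inherited by the family
        founders = []
        for _ in range(config.n_founders):
            cdr3a = _random_cdr3(rng, int(rng.integers(lo, hi + 1)))
            cdr3b = _random_cdr3(rng, int(rng.integers(lo, hi + 1)))
            mpos = int(rng.integers(1, len(cdr3b) - len(spec.motif)))
            cdr3b = (cdr3b[:mpos] + spec.motif
                     + cdr3b[mpos + len(spec.motif):])
            founders.append((cdr3a, cdr3b, mpos))

        base: list[TCRRecord] = []
        while len(base) < spec.n_positives:
            cdr3a, cdr3b, mpos = founders[int(rng.integers(len(founders)))]
            motif_span = set(range(mpos, mpos + len(spec.motif)))
            free_b = [i for i in range(1, len(cdr3b) - 1) if i not in motif_span]
            cdr3a = _mutate_positions(cdr3a, list(range(1, len(cdr3a) - 1)),
                                      config.diversification_rate, rng)
            cdr3b = _mutate_positions(cdr3b, free_b,
                                      config.diversification_rate, rng)
            cdr3b = _mutate_positions(cdr3b, sorted(motif_span),
                                      spec.mutation_rate, rng)
            emit(base, assemble(cdr3a, cdr3b, spec.peptide, 1, "positive",
                                draw_genes(spec)))
        positives.extend(base)
        # clonotype re-deposits: same CDR3s, re-drawn gene annotations
        for rec in base:
            if rng.random() < config.near_duplicate_rate:
                dup = assemble(rec.cdr3a, rec.cdr3b, rec.peptide, 1,
                               "positive", draw_genes(spec))
                if emit(positives, dup):
                    n_near_dups += 1

    background: list[TCRRecord] = []
    while len(background) < config.background_size:
        cdr3a = _random_cdr3(rng, int(rng.integers(lo, hi + 1)))
        cdr3b = _random_cdr3(rng, int(rng.integers(lo, hi + 1)))
        emit(background, assemble(cdr3a, cdr3b, "", 0, "background",
                                  draw_genes(None)))

    meta = {"seed": config.seed, "generator": "tcrpred.synthetic",
            "n_near_duplicates": n_near_dups}
    return (Repertoire(positives, dict(meta)),
            Repertoire(background, dict(meta)))


def _best_motif_window(cdr3b: str, motif: str) -> int:
    """Start of the window with minimal Hamming distance to the motif."""
    best, best_pos = len(motif) + 1, 1
    for pos in range(1, len(cdr3b) - len(motif)):
        d = sum(a != b for a, b in zip(cdr3b[pos:pos + len(motif)], motif))
        if d < best:
            best, best_pos = d, pos
    return best_pos


def perturb_positives(records: Repertoire, n_substitutions: int,
                      rng: np.random.Generator,
                      protect_motif: str | None = None,
                      shuffle_genes: bool = True) -> Repertoire:
    """Copies of ``records`` with a fixed number of CDR3 substitutions.

    Substitution positions are drawn over the internal positions of both
    CDR3 loops; when ``protect_motif`` is given, the CDR3beta window best
    matching that motif is left untouched, so the implanted binding signal
    survives while the overall similarity to the source record decays.
    When ``n_substitutions > 0`` and ``shuffle_genes`` is set, gene
    annotations (and hence CDR1/2 loops) are additionally permuted across
    records per chain, preserving marginal gene usage while breaking the
    exact gene match a mere copy would keep.  Used to inject evaluation
    records at a controlled distance from training data.
    """
    out = []
    n = len(records)
    if shuffle_genes and n_substitutions > 0 and n > 1:
        perm_a = rng.permutation(n)
        perm_b = rng.permutation(n)
    else:
        perm_a = perm_b = np.arange(n)
    for ridx, rec in enumerate(records):
        cdr3a, cdr3b = list(rec.cdr3a), list(rec.cdr3b)
        protected: set[tuple[str, int]] = set()
        if protect_motif:
            start = _best_motif_window(rec.cdr3b, protect_motif)
            protected = {("b", i) for i in range(start, start + len(protect_motif))}
        sites = ([("a", i) for i in range(1, len(cdr3a) - 1)]
                 + [("b", i) for i in range(1, len(cdr3b) - 1)])
        sites = [s for s in sites if s not in protected]
        take = min(n_substitutions, len(sites))
        for si in rng.choice(len(sites), size=take, replace=False):
            chain, i = sites[int(si)]
            target = cdr3a if chain == "a" else cdr3b
            choices = [a for a in AMINO_ACIDS if a != target[i]]
            target[i] = str(rng.choice(choices))
        donor_a = records[int(perm_a[ridx])]
        donor_b = records[int(perm_b[ridx])]
        out.append(rec.copy(
            cdr3a="".join(cdr3a), cdr3b="".join(cdr3b),
            cdr1a=donor_a.cdr1a, cdr2a=donor_a.cdr2a,
            v_gene_a=donor_a.v_gene_a, j_gene_a=donor_a.j_gene_a,
            cdr1b=donor_b.cdr1b, cdr2b=donor_b.cdr2b,
            v_gene_b=donor_b.v_gene_b, j_gene_b=donor_b.j_gene_b))
    return Repertoire(out, dict(records.metadata))
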