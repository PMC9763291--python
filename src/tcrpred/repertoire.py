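"""Core domain types and repertoire IO.

A T-cell receptor (TCR) is represented by its six complementarity-determining
region (CDR) loops — CDR1/2/3 on the alpha and beta chains — plus the V/J
germline gene names it was recombined from, the peptide it is annotated
against, and a binary binder label.  Records are read from and written to
plain delimited text; full-chain sequences can be reconstructed by stitching
a CDR3 junction onto germline V and J segments, and CDR1/2 loops are filled
in by lookup in a germline gene table.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids, alphabetical single-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Names of the six CDR loop fields on :class:`TCRRecord`, alpha then beta.
LOOP_FIELDS = ("cdr1a", "cdr2a", "cdr3a", "cdr1b", "cdr2b", "cdr3b")

#: Valid provenance tags for a record.
PROVENANCES = ("positive", "true_negative", "swapped_negative", "background")


class ConfigurationError(ValueError):
    """A required column, file or setting is missing or inconsistent."""


class ReconstructionError(ValueError):
    """Full-chain stitching failed (missing anchor motif in V or J)."""


class AnnotationError(KeyError):
    """A germline gene could not be found in the gene table."""


def is_valid_sequence(seq: str, allow_empty: bool = True) -> bool:
    """True if ``seq`` contains only canonical amino-acid letters."""
    if seq == "":
        return allow_empty
    return set(seq) <= _AA_SET


@dataclass
class TCRRecord:
    """One TCR: six CDR loops, gene names, peptide, label and provenance.

    ``label`` is 1 for a binder and 0 otherwise; by convention label 1 goes
    with provenance ``positive`` and label 0 with every other provenance.
    ``partition`` is the cross-validation partition id, or ``None`` when the
    record has not been partitioned yet.
    """

    cdr3a: str
    cdr3b: str
    peptide: str
    cdr1a: str = ""
    cdr2a: str = ""
    cdr1b: str = ""
    cdr2b: str = ""
    v_gene_a: str = ""
    j_gene_a: str = ""
    v_gene_b: str = ""
    j_gene_b: str = ""
    label: int = 1
    provenance: str = "positive"
    partition: Optional[int] = None

    def loops(self) -> tuple[str, str, str, str, str, str]:
        """The six CDR loops in canonical order (1a, 2a, 3a, 1b, 2b, 3b)."""
        return (self.cdr1a, self.cdr2a, self.cdr3a,
                self.cdr1b, self.cdr2b, self.cdr3b)

    def identity_key(self) -> tuple[str, ...]:
        """Key identifying a record: the six loops plus the peptide."""
        return self.loops() + (self.peptide,)

    def tcr_key(self) -> tuple[str, ...]:
        """Key identifying the TCR itself (six loops, peptide excluded)."""
        return self.loops()

    def validate(self) -> None:
        """Raise ``ValueError`` on a non-canonical sequence or bad label."""
        for name in LOOP_FIELDS:
            if not is_valid_sequence(getattr(self, name)):
                raise ValueError(f"invalid characters in {name}: {getattr(self, name)!r}")
        if not is_valid_sequence(self.peptide):
            raise ValueError(f"invalid characters in peptide: {self.peptide!r}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if (self.label == 1) != (self.provenance == "positive"):
            raise ValueError(
                f"label {self.label} inconsistent with provenance {self.provenance!r}")

    def copy(self, **changes) -> "TCRRecord":
        return replace(self, **changes)


@dataclass
class Repertoire:
    """An ordered collection of :class:`TCRRecord` with free-form metadata.

    The container itself permits duplicate records (intermediate curation
    steps such as redundancy reduction need to see them); readers and
    generators enforce uniqueness over (six loops, peptide) at the boundary
    via :meth:`deduplicated`.
    """

    records: list[TCRRecord] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TCRRecord]:
        return iter(self.records)

    def __getitem__(self, idx):
        if isinstance(idx, slice):
            return Repertoire(self.records[idx], dict(self.metadata))
        return self.records[idx]

    def subset(self, indices: Iterable[int]) -> "Repertoire":
        recs = [self.records[i] for i in indices]
        return Repertoire(recs, dict(self.metadata))

    def peptides(self) -> list[str]:
        """Distinct peptides in order of first appearance."""
        seen: dict[str, None] = {}
        for r in self.records:
            if r.peptide and r.peptide not in seen:
                seen[r.peptide] = None
        return list(seen)

    def deduplicated(self) -> "Repertoire":
        """Drop records byte-identical over the six loops + peptide."""
        seen: set[tuple[str, ...]] = set()
        kept: list[TCRRecord] = []
        for r in self.records:
            key = r.identity_key()
            if key not in seen:
                seen.add(key)
                kept.append(r)
        dropped = len(self.records) - len(kept)
        if dropped:
            logger.warning("dropped %d duplicate records", dropped)
        meta = dict(self.metadata)
        meta["n_duplicates_dropped"] = meta.get("n_duplicates_dropped", 0) + dropped
        return Repertoire(kept, meta)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "A1": r.cdr1a, "A2": r.cdr2a, "A3": r.cdr3a,
                "B1": r.cdr1b, "B2": r.cdr2b, "B3": r.cdr3b,
                "peptide": r.peptide, "binder": r.label,
                "provenance": r.provenance,
                "partition": -1 if r.partition is None else r.partition,
                "TRAV": r.v_gene_a, "TRAJ": r.j_gene_a,
                "TRBV": r.v_gene_b, "TRBJ": r.j_gene_b,
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Column dialects

#: Default column names, as written by :func:`write_repertoire`.
DEFAULT_DIALECT: Mapping[str, str] = {
    "cdr1a": "A1", "cdr2a": "A2", "cdr3a": "A3",
    "cdr1b": "B1", "cdr2b": "B2", "cdr3b": "B3",
    "peptide": "peptide", "label": "binder", "partition": "partition",
    "provenance": "provenance",
    "v_gene_a": "TRAV", "j_gene_a": "TRAJ",
    "v_gene_b": "TRBV", "j_gene_b": "TRBJ",
}

#: Gene-centric dialect (CDR3 + gene names, no CDR1/2 columns).
GENE_DIALECT: Mapping[str, str] = {
    "cdr3a": "CDR3a", "cdr3b": "CDR3b",
    "v_gene_a": "TRAV", "j_gene_a": "TRAJ",
    "v_gene_b": "TRBV", "j_gene_b": "TRBJ",
    "peptide": "peptide", "label": "binder", "partition": "partition",
    "provenance": "provenance",
}

_SEQ_FIELDS = LOOP_FIELDS + ("peptide",)


def _infer_dialect(columns: Sequence[str]) -> Mapping[str, str]:
    cols = set(columns)
    if "A3" in cols and "B3" in cols:
        return DEFAULT_DIALECT
    if "CDR3a" in cols and "CDR3b" in cols:
        return GENE_DIALECT
    raise ConfigurationError(
        "cannot infer column dialect: expected columns A3/B3 or CDR3a/CDR3b, "
        f"found {sorted(cols)}")


def read_repertoire(path, dialect: Optional[Mapping[str, str]] = None,
                    sep: str = ",") -> Repertoire:
    """Read a delimited repertoire file into a :class:`Repertoire`.

    Rows containing non-amino-acid characters in any sequence column are
    reported (via logging and ``metadata['n_invalid_dropped']``) and dropped;
    row order is preserved.  Labels default to 1 (binder) when absent.

    Raises
    ------
    ConfigurationError
        If a required column (cdr3a, cdr3b, peptide) is missing.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"repertoire file not found: {path}")
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()
    if df.empty and df.columns.size == 0:
        logger.warning("empty repertoire file: %s", path)
        return Repertoire([], {"source": str(path), "n_invalid_dropped": 0})
    if dialect is None:
        dialect = _infer_dialect(df.columns)
    for required in ("cdr3a", "cdr3b", "peptide"):
        col = dialect.get(required, required)
        if col not in df.columns:
            raise ConfigurationError(
                f"missing required column {col!r} (field {required}) in {path}")

    records: list[TCRRecord] = []
    n_invalid = 0
    for _, row in df.iterrows():
        kwargs = {}
        for fieldname, col in dialect.items():
            if col not in df.columns:
                continue
            value = row[col]
            if fieldname == "label":
                kwargs["label"] = int(float(value)) if value != "" else 1
            elif fieldname == "partition":
                p = int(float(value)) if value != "" else -1
                kwargs["partition"] = None if p < 0 else p
            else:
                kwargs[fieldname] = str(value)
        if "label" not in kwargs:
            kwargs["label"] = 1
        if "provenance" not in kwargs or kwargs.get("provenance") == "":
            kwargs["provenance"] = "positive" if kwargs["label"] == 1 else "background"
        bad = [f for f in _SEQ_FIELDS
               if f in kwargs and not is_valid_sequence(kwargs[f])]
        if bad:
            n_invalid += 1
            continue
        records.append(TCRRecord(**kwargs))
    if n_invalid:
        logger.warning("dropped %d rows with invalid sequence characters", n_invalid)
    if not records:
        logger.warning("repertoire %s contains no valid records", path)
    rep = Repertoire(records, {"source": str(path), "n_invalid_dropped": n_invalid})
    return rep.deduplicated()


def write_repertoire(rep: Repertoire, path, sep: str = ",") -> None:
    """Write a repertoire in the default column dialect."""
    rep.to_dataframe().to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Germline gene table

@dataclass(frozen=True)
class GeneEntry:
    """Germline amino-acid sequence of one V or J gene, with its CDR loops.

    ``cdr1``/``cdr2`` are empty for J genes; for V genes they are substrings
    of ``sequence``.
    """

    sequence: str
    cdr1: str = ""
    cdr2: str = ""


class GeneTable:
    """Mapping (chain, segment, gene name) -> germline entry.

    Chains are ``"A"``/``"B"``, segments ``"V"``/``"J"``; the four
    namespaces are disjoint.  Lookup falls back to the allele-stripped gene
    name (``TRAV12-2*01`` -> ``TRAV12-2``) when the exact name is absent.
    """

    def __init__(self) -> None:
        self._entries: dict[tuple[str, str, str], GeneEntry] = {}

    def add(self, chain: str, segment: str, gene: str, entry: GeneEntry) -> None:
        chain, segment = chain.upper(), segment.upper()
        if chain not in ("A", "B") or segment not in ("V", "J"):
            raise ConfigurationError(f"bad chain/segment: {chain}/{segment}")
        if segment == "V":
            if entry.cdr1 not in entry.sequence or entry.cdr2 not in entry.sequence:
                raise ConfigurationError(
                    f"CDR1/2 of {gene} are not substrings of its germline sequence")
            if "C" not in entry.sequence[-6:]:
                raise ConfigurationError(
                    f"V gene {gene} lacks a cysteine in its last six residues")
        self._entries[(chain, segment, gene)] = entry

    def lookup(self, chain: str, segment: str, gene: str) -> GeneEntry:
        key = (chain.upper(), segment.upper(), gene)
        if key in self._entries:
            return self._entries[key]
        stripped = gene.split("*")[0]
        key2 = (chain.upper(), segment.upper(), stripped)
        if key2 in self._entries:
            return self._entries[key2]
        raise AnnotationError(f"gene {gene!r} not in table for chain "
                              f"{chain} segment {segment}")

    def __contains__(self, key: tuple[str, str, str]) -> bool:
        chain, segment, gene = key
        try:
            self.lookup(chain, segment, gene)
            return True
        except AnnotationError:
            return False

    def __len__(self) -> int:
        return len(self._entries)

    def genes(self, chain: str, segment: str) -> list[str]:
        return sorted(g for (c, s, g) in self._entries
                      if c == chain.upper() and s == segment.upper())

    @classmethod
    def read(cls, path, sep: str = ",") -> "GeneTable":
        """Read a gene table (columns chain,segment,gene,sequence,cdr1,cdr2)."""
        table = cls()
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter=sep)
            needed = {"chain", "segment", "gene", "sequence"}
            if reader.fieldnames is None or not needed <= set(reader.fieldnames):
                raise ConfigurationError(
                    f"gene table {path} must have columns {sorted(needed)}")
            for row in reader:
                table.add(row["chain"], row["segment"], row["gene"],
                          GeneEntry(row["sequence"], row.get("cdr1", "") or "",
                                    row.get("cdr2", "") or ""))
        return table

    def write(self, path, sep: str = ",") -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter=sep)
            writer.writerow(["chain", "segment", "gene", "sequence", "cdr1", "cdr2"])
            for (chain, segment, gene), e in sorted(self._entries.items()):
                writer.writerow([chain, segment, gene, e.sequence, e.cdr1, e.cdr2])


# ---------------------------------------------------------------------------
# Full-chain reconstruction and CDR1/2 annotation

def reconstruct_full_sequence(cdr3: str, v: str, j: str) -> str:
    """Stitch a CDR3 junction onto germline V and J segments.

    The V prefix ends immediately before the rightmost cysteine within the
    last six residues of ``v`` (the conserved junction cysteine, which the
    CDR3 string itself carries as its first residue).  The J suffix starts at
    the glycine that follows the first F/W-followed-by-G motif within the
    first 11 residues of ``j`` (the CDR3 carries the F/W anchor).

    Raises
    ------
    ValueError
        If any input contains a non-canonical letter.
    ReconstructionError
        If no junction cysteine is found in V or no F/W+G motif in J.
    """
    for name, seq in (("cdr3", cdr3), ("v", v), ("j", j)):
        if seq == "" or not is_valid_sequence(seq, allow_empty=False):
            raise ValueError(f"invalid or empty {name} sequence: {seq!r}")
    window_start = max(0, len(v) - 6)
    cys = v.rfind("C", window_start)
    if cys < 0:
        raise ReconstructionError(
            "no cysteine in the last six residues of the V gene")
    g_index = -1
    limit = min(11, len(j))
    for p in range(limit):
        if j[p] in "FW" and p + 1 < len(j) and j[p + 1] == "G":
            g_index = p + 1
            break
    if g_index < 0:
        raise ReconstructionError(
            "no F/W followed by G in the first 11 residues of the J gene")
    return v[:cys] + cdr3 + j[g_index:]


def annotate_cdr12(record: TCRRecord, table: GeneTable) -> TCRRecord:
    """Fill CDR1/CDR2 loops of both chains from the germline gene table.

    Returns a new record; idempotent.  Raises :class:`AnnotationError` when
    a V gene is absent from the table even after allele stripping.
    """
    if not record.v_gene_a or not record.v_gene_b:
        raise AnnotationError("record lacks V gene names for annotation")
    ea = table.lookup("A", "V", record.v_gene_a)
    eb = table.lookup("B", "V", record.v_gene_b)
    return record.copy(cdr1a=ea.cdr1, cdr2a=ea.cdr2, cdr1b=eb.cdr1, cdr2b=eb.cdr2)
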