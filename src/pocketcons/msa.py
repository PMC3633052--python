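"""E-value-ordered multiple sequence alignments.

The alignment contract: row 0 is the query (the structure's own sequence);
homolog rows follow in order of increasing e-value, so that truncating to a
prefix keeps the closest homologs.  Ordering is normally the caller's
responsibility; as a convenience, records whose FASTA headers all carry an
``evalue=<float>`` token are sorted by it (query row stays first).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio import SeqIO

from .errors import ParseError, ValidationError

_EVALUE_RE = re.compile(r"evalue=([0-9.eE+-]+)")


@dataclass(frozen=True)
class OrderedAlignment:
    """An aligned FASTA with rows ordered by increasing e-value, query first."""

    rows: tuple[tuple[str, str], ...]  # (id, aligned sequence with '-')

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValidationError("alignment needs the query plus >=1 homolog row")
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) != 1:
            raise ValidationError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_homologs(self) -> int:
        """N: number of homolog rows (query excluded)."""
        return len(self.rows) - 1

    @property
    def query_id(self) -> str:
        return self.rows[0][0]

    @property
    def query_row(self) -> str:
        return self.rows[0][1]

    def ungapped_query(self) -> str:
        return self.rows[0][1].replace("-", "")


def read_ordered_msa(path) -> OrderedAlignment:
    """Read an aligned FASTA; uppercase, '.' normalized to '-'.

    Rows must be equal length (ragged input is an error) and there must be at
    least two.  If every header carries ``evalue=<float>``, homolog rows are
    sorted by it (stable); otherwise file order is kept.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise ParseError(f"{path}: alignment needs >=2 records, found {len(records)}")
    rows = [(rec.id, str(rec.seq).upper().replace(".", "-")) for rec in records]
    lengths = {len(seq) for _, seq in rows}
    if len(lengths) != 1:
        raise ParseError(f"{path}: ragged alignment, row lengths {sorted(lengths)}")
    evalues = [_EVALUE_RE.search(rec.description) for rec in records]
    if all(m is not None for m in evalues[1:]) and len(records) > 2:
        homologs = sorted(zip(rows[1:], evalues[1:]), key=lambda t: float(t[1].group(1)))
        rows = [rows[0]] + [r for r, _ in homologs]
    return OrderedAlignment(tuple(rows))


def write_msa(alignment: OrderedAlignment, path) -> None:
    with open(path, "w") as fh:
        for rid, seq in alignment.rows:
            fh.write(f">{rid}\n{seq}\n")


def prefix(alignment: OrderedAlignment, j: int) -> OrderedAlignment:
    """Keep the query and the first *j* homolog rows; columns untouched.

    Column indices are stable across prefixes — conserved columns found at a
    shallow depth index the same positions at a deeper one.
    """
    if not 1 <= j <= alignment.n_homologs:
        raise ValidationError(
            f"prefix depth j={j} out of range [1, {alignment.n_homologs}]")
    return OrderedAlignment(alignment.rows[: j + 1])


def pairwise_identity(row_a: str, row_b: str) -> float:
    """Fraction of identical residues over co-aligned (both non-gap) columns.

    Returns 0.0 when the rows share no co-aligned column.
    """
    if len(row_a) != len(row_b):
        raise ValidationError(
            f"length mismatch: {len(row_a)} vs {len(row_b)}")
    matches = 0
    shared = 0
    for a, b in zip(row_a, row_b):
        if a != "-" and b != "-":
            shared += 1
            if a == b:
                matches += 1
    return matches / shared if shared else 0.0


def filter_redundant(alignment: OrderedAlignment,
                     max_identity: float = 0.70) -> OrderedAlignment:
    """Greedy redundancy filter in e-value order.

    The query is always kept; each homolog row is kept only if its identity
    to every already-kept row is below *max_identity*.  Relative order is
    preserved, so the output is still e-value ordered.  Idempotent.
    """
    kept: list[tuple[str, str]] = [alignment.rows[0]]
    for rid, seq in alignment.rows[1:]:
        if all(pairwise_identity(seq, kseq) < max_identity for _, kseq in kept):
            kept.append((rid, seq))
    if len(kept) < 2:
        raise ValidationError(
            "redundancy filter removed every homolog; lower max_identity or "
            "supply more distant sequences")
    return OrderedAlignment(tuple(kept))
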