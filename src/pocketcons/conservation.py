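"""Conserved-column identification and mapping onto structure residues.

A column is conserved when the query's residue is the modal residue of the
column and its frequency over *all* rows reaches the identity threshold.
Gaps count in the denominator and never match, so a gap anywhere in a column
disqualifies strict 100% conservation.  When no column reaches the starting
threshold (100% by default), the threshold is lowered in fixed steps until at
least one column qualifies or a floor is reached — an adaptive rule that
avoids committing to an arbitrary conservation score.

TCA(j), the total heavy-atom count of residues conserved in the depth-j
alignment prefix, is the quantity the Poisson enrichment model needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .msa import OrderedAlignment
from .structure_io import ResidueKey, Structure, chain_sequence

_EPS = 1e-9

GAP = ord("-")


@dataclass(frozen=True)
class ConservationProfile:
    """Conservation state of one alignment prefix mapped onto a structure."""

    j: int
    threshold_used: float
    conserved_columns: frozenset[int]
    conserved_residues: frozenset[ResidueKey]
    tca: int  # total heavy atoms of conserved residues


def _column_matrix(alignment: OrderedAlignment) -> np.ndarray:
    return np.frombuffer(
        "".join(seq for _, seq in alignment.rows).encode("ascii"), dtype=np.uint8
    ).reshape(len(alignment.rows), alignment.n_cols)


def conserved_columns(alignment: OrderedAlignment,
                      start_threshold: float = 1.0,
                      step: float = 0.05,
                      floor: float = 0.50) -> tuple[set[int], float]:
    """Columns conserved under the adaptive-threshold rule.

    Returns ``(columns, threshold_used)``.  If no column qualifies even at
    *floor*, the set is empty and ``threshold_used == floor``.
    """
    mat = _column_matrix(alignment)
    n_rows = mat.shape[0]
    query = mat[0]
    # frequency of the query residue per column, gaps in the denominator
    match_frac = (mat == query[None, :]).sum(axis=0) / n_rows
    # the query residue must also be modal among non-gap residues
    col_max = np.zeros(mat.shape[1])
    for aa in np.unique(mat):
        if aa == GAP:
            continue
        col_max = np.maximum(col_max, (mat == aa).sum(axis=0) / n_rows)
    eligible = (query != GAP) & (match_frac >= col_max - _EPS)

    t = start_threshold
    while True:
        cols = np.nonzero(eligible & (match_frac >= t - _EPS))[0]
        if cols.size or step <= 0 or t <= floor + _EPS:
            return set(int(c) for c in cols), round(t, 10)
        t = max(t - step, floor)


def map_columns_to_residues(alignment: OrderedAlignment,
                            structure: Structure,
                            columns: set[int]) -> set[ResidueKey]:
    """Map conserved column indices to residue keys of the query structure.

    Every chain whose sequence equals the ungapped query contributes its
    residues — a homodimer with two identical chains yields keys from both.
    """
    ungapped = alignment.ungapped_query()
    # column index -> ungapped query position
    col_to_pos: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(alignment.query_row):
        if ch != "-":
            col_to_pos[col] = pos
            pos += 1

    matched = False
    keys: set[ResidueKey] = set()
    mismatches: list[str] = []
    for chain_id in structure.chains:
        seq, res_keys = chain_sequence(structure, chain_id)
        if seq == ungapped:
            matched = True
            for col in columns:
                if col in col_to_pos:  # query gap columns never map
                    keys.add(res_keys[col_to_pos[col]])
        else:
            mismatches.append(_diff_summary(chain_id, seq, ungapped))
    if not matched:
        raise ValidationError(
            "ungapped query sequence matches no chain of the structure:\n"
            + "\n".join(mismatches))
    return keys


def _diff_summary(chain_id: str, chain_seq: str, query: str) -> str:
    if len(chain_seq) != len(query):
        return (f"  chain {chain_id}: length {len(chain_seq)} vs query "
                f"{len(query)}")
    first = next(i for i in range(len(query)) if chain_seq[i] != query[i])
    return (f"  chain {chain_id}: first mismatch at position {first} "
            f"({chain_seq[first]} vs {query[first]})")


def total_conserved_atoms(structure: Structure,
                          conserved_residues: set[ResidueKey]) -> int:
    """TCA: summed heavy-atom counts of the conserved residues, all chains."""
    return sum(structure.residue_by_key(k).n_atoms for k in conserved_residues)


def build_profile(alignment: OrderedAlignment,
                  structure: Structure,
                  start_threshold: float = 1.0,
                  step: float = 0.05,
                  floor: float = 0.50) -> ConservationProfile:
    """Full conservation profile for one (already prefixed) alignment."""
    cols, threshold = conserved_columns(alignment, start_threshold, step, floor)
    residues = map_columns_to_residues(alignment, structure, cols)
    tca = total_conserved_atoms(structure, residues)
    return ConservationProfile(
        j=alignment.n_homologs,
        threshold_used=threshold,
        conserved_columns=frozenset(cols),
        conserved_residues=frozenset(residues),
        tca=tca,
    )
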