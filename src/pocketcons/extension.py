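"""Composite active sites: merging contiguous conserved pockets.

Active sites are often hive-shaped — a primary catalytic pocket surrounded
by adjoining pockets that together accommodate the natural substrate.  The
composite site starts from the predicted active-site pocket and grows by
adding conserved pockets contiguous to the current composite, in order of
decreasing conservation (increasing p-value).

Contiguity is operational: two pockets are adjacent when they share a lining
residue or their closest heavy atoms are within a distance cutoff (4.5 A by
default, roughly van der Waals contact).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.spatial.distance import cdist

from .errors import ValidationError
from .pockets import Pocket, PocketSet, pocket_residues
from .scoring import OptimizationResult
from .structure_io import ResidueKey, Structure


@dataclass(frozen=True)
class CompositeSite:
    """Seed pocket plus contiguous conserved pockets, in addition order."""

    member_pockets: tuple[str, ...]
    atoms: frozenset[int]
    residues: tuple[ResidueKey, ...]


def pocket_adjacency(pocket_set: PocketSet,
                     structure: Structure,
                     distance_cutoff: float = 4.5) -> dict[str, set[str]]:
    """Symmetric adjacency: shared residue or min inter-atom gap <= cutoff."""
    ids = [p.pocket_id for p in pocket_set]
    res_sets = {p.pocket_id: set(pocket_residues(p, structure)) for p in pocket_set}
    coords = {p.pocket_id: structure.coords_for_serials(p.atom_serials)
              for p in pocket_set}
    adj: dict[str, set[str]] = {pid: set() for pid in ids}
    for a_idx in range(len(ids)):
        for b_idx in range(a_idx + 1, len(ids)):
            a, b = ids[a_idx], ids[b_idx]
            touching = bool(res_sets[a] & res_sets[b])
            if not touching:
                touching = float(cdist(coords[a], coords[b]).min()) <= distance_cutoff
            if touching:
                adj[a].add(b)
                adj[b].add(a)
    return adj


def extend_active_site(result: OptimizationResult,
                       adjacency: dict[str, set[str]],
                       pocket_set: PocketSet,
                       structure: Structure) -> CompositeSite:
    """Grow the active-site pocket with contiguous conserved pockets.

    Iterates the conserved pockets by increasing p-value, adding each one
    adjacent to the current composite, and repeats until no further addition
    is possible — so growth is transitive through chains of adjacency.
    """
    if result.active_site_pocket is None:
        raise ValidationError("no active-site pocket to extend")
    members = [result.active_site_pocket]
    candidates = [pid for pid in result.conserved_pockets
                  if pid != result.active_site_pocket]
    grown = True
    while grown:
        grown = False
        for pid in candidates:
            if pid in members:
                continue
            if any(pid in adjacency[m] for m in members):
                members.append(pid)
                grown = True
    atoms: set[int] = set()
    residues: set[ResidueKey] = set()
    for pid in members:
        pocket = pocket_set[pid]
        atoms |= pocket.atom_serials
        residues |= set(pocket_residues(pocket, structure))
    return CompositeSite(member_pockets=tuple(members),
                         atoms=frozenset(atoms),
                         residues=tuple(sorted(residues)))


def composite_to_tsv(site: CompositeSite, structure: Structure, path) -> None:
    """Residue list of the composite site as TSV."""
    with open(path, "w") as fh:
        fh.write("chain\tresidue_number\tinsertion_code\taa\n")
        for chain, num, icode in site.residues:
            res = structure.residue_by_key((chain, num, icode))
            fh.write(f"{chain}\t{num}\t{icode}\t{res.aa}\n")


def pymol_selection(site: CompositeSite, name: str = "composite_site") -> str:
    """A PyMOL-style selection string for the composite-site residues."""
    by_chain: dict[str, list[int]] = {}
    for chain, num, _ in site.residues:
        by_chain.setdefault(chain, []).append(num)
    parts = [f"(chain {chain} and resi {'+'.join(str(n) for n in sorted(set(nums)))})"
             for chain, nums in sorted(by_chain.items())]
    return f"select {name}, " + " or ".join(parts)
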