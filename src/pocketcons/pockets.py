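"""Pocket definitions: parsing, validation and attachment to a structure.

Pockets are detected externally (typically by CastP-style alpha-shape
analysis) and consumed here as groups of lining atoms.  Two dialects are
supported: the annotated-PDB ``.poc`` dialect, where each ATOM line carries a
trailing ``POC`` tag and pocket id, and a plain TSV interchange format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .errors import ParseError, ValidationError
from .structure_io import ResidueKey, Structure, _parse_atom_line

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Pocket:
    """A surface pocket: id, lining atom serials, optional volume (A^3)."""

    pocket_id: str
    atom_serials: frozenset[int]
    volume: float | None = None

    @property
    def n_atoms(self) -> int:
        """PA: number of atoms lining this pocket."""
        return len(self.atom_serials)

    def size(self) -> float:
        """Pocket size for largest-pocket predictors: volume if known, else PA."""
        return self.volume if self.volume is not None else float(self.n_atoms)


class PocketSet:
    """A collection of pockets attached to a :class:`Structure`."""

    def __init__(self, pockets: list[Pocket], structure: Structure) -> None:
        ids = [p.pocket_id for p in pockets]
        if len(set(ids)) != len(ids):
            raise ValidationError("pocket ids must be unique")
        missing = sorted(
            s for p in pockets for s in p.atom_serials if not structure.has_serial(s))
        if missing:
            raise ValidationError(
                f"pocket atoms reference serials absent from structure: {missing[:10]}")
        for p in pockets:
            if p.n_atoms < 1:
                raise ValidationError(f"pocket {p.pocket_id} has no atoms")
        self.pockets = list(pockets)
        self.structure = structure

    def __iter__(self):
        return iter(self.pockets)

    def __len__(self) -> int:
        return len(self.pockets)

    def __getitem__(self, pocket_id: str) -> Pocket:
        for p in self.pockets:
            if p.pocket_id == pocket_id:
                return p
        raise KeyError(pocket_id)

    def total_lining_atoms(self) -> int:
        """Sum of PA over pockets (counts shared atoms once per pocket)."""
        return sum(p.n_atoms for p in self.pockets)


def parse_castp_poc(path, structure: Structure) -> PocketSet:
    """Parse the annotated-PDB pocket dialect.

    Each pocket line is a standard ATOM record followed by the literal tag
    ``POC`` and an integer pocket id in the trailing columns.  Atoms are
    grouped by pocket id and serials cross-checked against *structure*.
    """
    groups: dict[str, set[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("ATOM"):
                continue
            atom, _ = _parse_atom_line(line, lineno)
            tail = line[66:].split()
            if "POC" not in tail:
                raise ParseError(
                    f"line {lineno}: ATOM record lacks the POC pocket tag")
            idx = tail.index("POC")
            try:
                pocket_id = str(int(tail[idx + 1]))
            except (IndexError, ValueError):
                raise ParseError(
                    f"line {lineno}: POC tag not followed by an integer pocket id"
                ) from None
            prev = [pid for pid, serials in groups.items() if atom.serial in serials]
            if prev and pocket_id not in prev:
                logger.warning("atom serial %d annotated in pockets %s and %s",
                               atom.serial, prev[0], pocket_id)
            groups.setdefault(pocket_id, set()).add(atom.serial)
    if not groups:
        raise ParseError(f"no POC-annotated ATOM records in {path}")
    pockets = [Pocket(pid, frozenset(serials)) for pid, serials in groups.items()]
    return PocketSet(pockets, structure)


def parse_pocket_tsv(path, structure: Structure) -> PocketSet:
    """Parse the plain TSV pocket format.

    Columns: ``pocket_id``, ``atom_serial``, optional ``volume`` (must agree
    across the rows of one pocket).
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"pocket_id": str})
    except Exception as exc:
        raise ParseError(f"cannot read pocket TSV {path}: {exc}") from None
    required = {"pocket_id", "atom_serial"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"pocket TSV must have columns {sorted(required)}, got {list(df.columns)}")
    pockets = []
    for pid, grp in df.groupby("pocket_id", sort=False):
        volume = None
        if "volume" in df.columns:
            vols = grp["volume"].dropna().unique()
            if len(vols) > 1:
                raise ParseError(
                    f"conflicting volumes for pocket {pid}: {sorted(vols)}")
            if len(vols) == 1:
                volume = float(vols[0])
        pockets.append(Pocket(str(pid), frozenset(int(s) for s in grp["atom_serial"]),
                              volume=volume))
    return PocketSet(pockets, structure)


def write_pocket_tsv(pocket_set: PocketSet, path) -> None:
    """Write the TSV dialect; lossless for (pocket_id, serial, volume)."""
    rows = []
    for p in pocket_set:
        for serial in sorted(p.atom_serials):
            rows.append({"pocket_id": p.pocket_id, "atom_serial": serial,
                         "volume": p.volume})
    df = pd.DataFrame(rows, columns=["pocket_id", "atom_serial", "volume"])
    if df["volume"].isna().all():
        df = df.drop(columns=["volume"])
    df.to_csv(path, sep="\t", index=False)


def pocket_residues(pocket: Pocket, structure: Structure) -> list[ResidueKey]:
    """Residues owning at least one lining atom, in chain/number order."""
    keys = {structure.atom_by_serial(s).residue_key for s in pocket.atom_serials}
    return sorted(keys)
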