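"""Protein structure model and PDB reading/writing.

The structure model is deliberately minimal: heavy atoms grouped into
residues grouped into chains, with author numbering preserved.  It exists to
support atom bookkeeping for pocket conservation scoring — the total
heavy-atom count of the protein (TA), per-residue atom counts, and the
mapping from atom serial numbers to residues.

Parsing rules:

* only ``ATOM`` records are kept — ``HETATM`` (waters, ligands, ions) never
  contribute to TA;
* hydrogens (and deuterium) are dropped even when present;
* for alternate locations, the first-listed conformer of each atom wins;
* residues with non-standard names are kept but typed ``'X'``, so they count
  toward TA while never being treated as conserved amino acids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import ParseError, ValidationError

#: chain id, author residue number, insertion code ('' if none)
ResidueKey = tuple[str, int, str]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass(frozen=True)
class Atom:
    """A single heavy atom of the polypeptide."""

    serial: int
    name: str
    element: str
    residue_key: ResidueKey
    alt_loc: str
    coords: tuple[float, float, float]


@dataclass
class Residue:
    """An amino-acid residue and its heavy atoms."""

    residue_key: ResidueKey
    aa: str  # one-letter code, 'X' for non-standard
    atoms: list[Atom] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


class Structure:
    """Heavy atoms of a protein grouped by chain and residue.

    Parameters
    ----------
    chains
        Ordered mapping ``chain id -> list of Residue`` in file order.
    name
        Free-form identifier carried along for reporting.
    """

    def __init__(self, chains: dict[str, list[Residue]], name: str = "") -> None:
        if not chains:
            raise ValidationError("structure must contain at least one chain")
        self.chains = chains
        self.name = name
        self._by_serial: dict[int, Atom] = {}
        self._by_key: dict[ResidueKey, Residue] = {}
        for residues in chains.values():
            for res in residues:
                if not res.atoms:
                    raise ValidationError(f"residue {res.residue_key} has no atoms")
                self._by_key[res.residue_key] = res
                for atom in res.atoms:
                    if atom.serial in self._by_serial:
                        raise ValidationError(f"duplicate atom serial {atom.serial}")
                    self._by_serial[atom.serial] = atom

    # -- bookkeeping -------------------------------------------------------
    @property
    def total_atoms(self) -> int:
        """TA: total heavy-atom count of the protein."""
        return len(self._by_serial)

    def residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    def atom_by_serial(self, serial: int) -> Atom:
        try:
            return self._by_serial[serial]
        except KeyError:
            raise ValidationError(f"atom serial {serial} not present in structure") from None

    def has_serial(self, serial: int) -> bool:
        return serial in self._by_serial

    def residue_by_key(self, key: ResidueKey) -> Residue:
        try:
            return self._by_key[key]
        except KeyError:
            raise ValidationError(f"residue key {key!r} not present in structure") from None

    def coords_for_serials(self, serials) -> np.ndarray:
        return np.array([self._by_serial[s].coords for s in sorted(serials)], dtype=float)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<Structure {self.name or '?'}: {len(self.chains)} chain(s), "
                f"{self.total_atoms} heavy atoms>")


def _parse_atom_line(line: str, lineno: int) -> tuple[Atom, str]:
    """Parse one fixed-column ATOM record; returns (atom, three-letter resname)."""
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        alt_loc = line[16].strip()
        resname = line[17:20].strip()
        chain_id = line[21].strip() or " "
        resseq = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"malformed ATOM record at line {lineno}: {exc}") from None
    element = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not element:
        # infer from the atom name: leading digits (e.g. "1HB") mark hydrogens
        stripped = name.lstrip("0123456789")
        element = stripped[:1].upper() if stripped else ""
    key: ResidueKey = (chain_id, resseq, icode)
    atom = Atom(serial=serial, name=name, element=element, residue_key=key,
                alt_loc=alt_loc, coords=(x, y, z))
    return atom, resname


def read_pdb(path, name: str | None = None) -> Structure:
    """Read a PDB file into a :class:`Structure` of protein heavy atoms.

    Hydrogens, waters and all HETATM records are excluded; for alternate
    locations only the first-listed conformer of each atom is retained;
    non-standard residue names are typed ``'X'``.

    Raises
    ------
    ParseError
        If the file has no protein ATOM records or a malformed line.
    """
    chains: dict[str, list[Residue]] = {}
    current: dict[ResidueKey, Residue] = {}
    seen_atom_slots: set[tuple[ResidueKey, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("ENDMDL"):
                break  # first model only
            if not line.startswith("ATOM"):
                continue
            atom, resname = _parse_atom_line(line, lineno)
            if resname in _WATER_NAMES:
                continue
            if atom.element in ("H", "D"):
                continue
            slot = (atom.residue_key, atom.name)
            if slot in seen_atom_slots:  # later altLoc conformer of a kept atom
                continue
            seen_atom_slots.add(slot)
            chain_id = atom.residue_key[0]
            if atom.residue_key not in current:
                res = Residue(residue_key=atom.residue_key,
                              aa=THREE_TO_ONE.get(resname, "X"))
                current[atom.residue_key] = res
                chains.setdefault(chain_id, []).append(res)
            current[atom.residue_key].atoms.append(atom)
    if not chains:
        raise ParseError(f"no protein atoms: {path} contains no usable ATOM records")
    return Structure(chains, name=name or str(path))


def chain_sequence(structure: Structure, chain_id: str) -> tuple[str, list[ResidueKey]]:
    """One-letter sequence of a chain plus the parallel residue keys."""
    if chain_id not in structure.chains:
        raise ValidationError(
            f"unknown chain id {chain_id!r}; available: {sorted(structure.chains)}")
    residues = structure.chains[chain_id]
    return "".join(r.aa for r in residues), [r.residue_key for r in residues]


def write_pdb(structure: Structure, path) -> None:
    """Serialize a structure back to fixed-column ATOM records."""
    with open(path, "w") as fh:
        for res in structure.residues():
            resname = ONE_TO_THREE.get(res.aa, "UNK")
            chain_id, resseq, icode = res.residue_key
            for atom in res.atoms:
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                x, y, z = atom.coords
                fh.write(
                    f"ATOM  {atom.serial:>5d} {name}{atom.alt_loc or ' '}"
                    f"{resname:>3s} {chain_id}{resseq:>4d}{icode or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {atom.element:>2s}\n")
        fh.write("END\n")
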