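"""Shared fixture builders: tiny hand-made structures and PDB text."""

from __future__ import annotations

import numpy as np
import pytest

from pocketcons.structure_io import Atom, Residue, Structure
from pocketcons.synthetic import SIDE_CHAIN_ATOMS


def pdb_line(serial, name, resname, chain, resseq, x=0.0, y=0.0, z=0.0,
             altloc=" ", icode=" ", element=None, record="ATOM"):
    """One fixed-column ATOM/HETATM record."""
    element = element if element is not None else name.lstrip("0123456789")[0]
    nm = name if len(name) == 4 else f" {name:<3s}"
    return (f"{record:<6s}{serial:>5d} {nm}{altloc}{resname:>3s} {chain}"
            f"{resseq:>4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}"
            f"  1.00  0.00          {element:>2s}")


def build_structure(residue_specs, name="fixture") -> Structure:
    """Structure from (chain, resseq, aa, center) specs.

    Each residue gets its full standard heavy-atom complement, with atoms
    spread within ~0.5 A of *center* so inter-residue distances are
    controlled by the centers.
    """
    chains: dict[str, list[Residue]] = {}
    serial = 1
    for chain, resseq, aa, center in residue_specs:
        key = (chain, resseq, "")
        atoms = []
        names = ("N", "CA", "C", "O") + SIDE_CHAIN_ATOMS[aa]
        for k, atom_name in enumerate(names):
            offset = 0.1 * np.array([k % 3, (k // 3) % 3, k // 9])
            coords = tuple(float(c) for c in (np.asarray(center, float) + offset))
            element = atom_name[0] if atom_name[0] in "NCOS" else "C"
            atoms.append(Atom(serial=serial, name=atom_name, element=element,
                              residue_key=key, alt_loc="", coords=coords))
            serial += 1
        chains.setdefault(chain, []).append(
            Residue(residue_key=key, aa=aa, atoms=atoms))
    return Structure(chains, name=name)


def chain_of(seq, chain="A", start=1, spacing=5.0):
    """Residue specs for one chain laid out along the x axis."""
    return [(chain, start + i, aa, (spacing * i, 0.0, 0.0))
            for i, aa in enumerate(seq)]


@pytest.fixture
def homodimer():
    """Two identical 'GAW' chains, far apart."""
    specs = chain_of("GAW", chain="A") + [
        ("B", i + 1, aa, (5.0 * i, 100.0, 0.0)) for i, aa in enumerate("GAW")]
    return build_structure(specs, name="homodimer")
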