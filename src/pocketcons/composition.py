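"""Amino-acid and atom-type composition of pocket groups.

Composition is atom-based: for a group of pockets, the count of atoms
belonging to each amino-acid type (or each atom type) divided by the total
atom count of the group.  Pockets are grouped as *all*, *conserved*
(enriched with p < alpha) and *non-conserved*; by default the latter two
partition the pockets, with in-between cases (enriched but not significant)
assigned to the non-conserved group.  A strict mode reproduces the literal
definitions and leaves the in-between pockets out of both groups.

Atom types distinguish side-chain chemistry: main-chain atoms (N, CA, C, O,
OXT) are keyed by bare name, side-chain atoms by ``<aa>:<name>`` so that for
example the tryptophan ring nitrogen (W:NE1) and the tyrosine hydroxyl
(Y:OH) are tracked separately.

The PROSITE baseline tallies residues at completely conserved (literal)
pattern positions, excluding patterns whose only conserved residues are
cysteines, since disulfide scaffolding patterns would otherwise dominate.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

from scipy.stats import f_oneway

from .errors import ParseError, ValidationError
from .pockets import PocketSet
from .scoring import PocketScore
from .structure_io import Structure

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_MAIN_CHAIN = {"N", "CA", "C", "O", "OXT"}


@dataclass
class CompositionTable:
    """Per-amino-acid and per-atom-type fractions for one pocket group."""

    label: str
    aa_fractions: dict[str, float] = field(default_factory=dict)
    atom_fractions: dict[str, float] = field(default_factory=dict)
    total_atoms: int = 0


def _classify(score: PocketScore, strict: bool) -> str | None:
    """Group label for one pocket; None = outside both groups (strict mode)."""
    if score.conserved:
        return "conserved"
    if strict and score.enriched:  # enriched but p >= alpha
        return None
    return "non_conserved"


def _count_pocket(pocket, structure: Structure,
                  aa_counts: Counter, atom_counts: Counter) -> int:
    n = 0
    for serial in pocket.atom_serials:
        atom = structure.atom_by_serial(serial)
        aa = structure.residue_by_key(atom.residue_key).aa
        aa_counts[aa] += 1
        key = atom.name if atom.name in _MAIN_CHAIN else f"{aa}:{atom.name}"
        atom_counts[key] += 1
        n += 1
    return n


def _table(label: str, aa_counts: Counter, atom_counts: Counter,
           total: int) -> CompositionTable:
    if total == 0:
        return CompositionTable(label=label, total_atoms=0)
    return CompositionTable(
        label=label,
        aa_fractions={aa: c / total for aa, c in sorted(aa_counts.items())},
        atom_fractions={k: c / total for k, c in sorted(atom_counts.items())},
        total_atoms=total)


def group_composition(runs: list[tuple[Structure, PocketSet, list[PocketScore]]],
                      strict: bool = False) -> dict[str, CompositionTable]:
    """Pooled composition tables for the all/conserved/non-conserved groups.

    *runs* are scored proteins: ``(structure, pocket_set, scores)`` triples.
    Counts are pooled over every pocket of every run; each pocket contributes
    independently, so atoms shared between overlapping pockets are counted
    once per pocket.
    """
    counters = {g: (Counter(), Counter(), 0)
                for g in ("all", "conserved", "non_conserved")}
    totals = {g: 0 for g in counters}
    for structure, pocket_set, scores in runs:
        by_id = {s.pocket_id: s for s in scores}
        for pocket in pocket_set:
            groups = ["all"]
            sub = _classify(by_id[pocket.pocket_id], strict)
            if sub is not None:
                groups.append(sub)
            for g in groups:
                aa_c, atom_c, _ = counters[g]
                totals[g] += _count_pocket(pocket, structure, aa_c, atom_c)
    return {g: _table(g, counters[g][0], counters[g][1], totals[g])
            for g in counters}


def per_protein_fractions(runs, group: str, strict: bool = False) -> list[dict[str, float]]:
    """Amino-acid fraction vectors, one per protein, for one group.

    These are the independent observations fed to the ANOVA: each protein
    contributes one composition vector per group.
    """
    out = []
    for structure, pocket_set, scores in runs:
        by_id = {s.pocket_id: s for s in scores}
        aa_c: Counter = Counter()
        atom_c: Counter = Counter()
        total = 0
        for pocket in pocket_set:
            label = ("all" if group == "all"
                     else _classify(by_id[pocket.pocket_id], strict))
            if label == group:
                total += _count_pocket(pocket, structure, aa_c, atom_c)
        if total:
            out.append({aa: aa_c.get(aa, 0) / total for aa in AMINO_ACIDS})
    return out


def anova_one_way(groups: list[list[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA over independent per-protein observations."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("ANOVA needs >=2 groups with >=2 observations each")
    if all(len(set(g)) == 1 for g in groups) and len({g[0] for g in groups}) == 1:
        return 0.0, 1.0  # identical constant groups: no variance anywhere
    f, p = f_oneway(*groups)
    return float(f), float(p)


# ---------------------------------------------------------------------------
# PROSITE patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrositeElement:
    kind: str        # 'literal' | 'any' | 'class' | 'negated'
    residues: str    # the literal letter or class members; '' for 'any'
    min_repeat: int
    max_repeat: int


@dataclass(frozen=True)
class PrositePattern:
    accession: str
    pattern: str
    elements: tuple[PrositeElement, ...]

    @property
    def conserved_residues(self) -> Counter:
        """Multiset of completely conserved (single-literal) positions.

        Repeats expand by their minimum count — the guaranteed occurrences.
        """
        pool: Counter = Counter()
        for el in self.elements:
            if el.kind == "literal":
                pool[el.residues] += el.min_repeat
        return pool


_TOKEN_RE = re.compile(
    r"^(?:(?P<any>[xX])|(?P<lit>[A-Za-z])|\[(?P<cls>[A-Za-z<>]+)\]|\{(?P<neg>[A-Za-z]+)\})"
    r"(?:\((?P<lo>\d+)(?:,(?P<hi>\d+))?\))?$")


def _parse_pattern(pattern: str, accession: str) -> PrositePattern:
    body = pattern.strip().rstrip(".")
    elements = []
    for raw in body.split("-"):
        token = raw.strip().lstrip("<").rstrip(">")
        if not token:
            continue
        m = _TOKEN_RE.match(token)
        if m is None:
            raise ParseError(f"pattern {accession}: cannot parse element {raw!r}")
        lo = int(m.group("lo") or 1)
        hi = int(m.group("hi") or lo)
        if m.group("any"):
            el = PrositeElement("any", "", lo, hi)
        elif m.group("lit"):
            el = PrositeElement("literal", m.group("lit").upper(), lo, hi)
        elif m.group("cls"):
            el = PrositeElement("class", m.group("cls").strip("<>").upper(), lo, hi)
        else:
            el = PrositeElement("negated", m.group("neg").upper(), lo, hi)
        elements.append(el)
    return PrositePattern(accession=accession, pattern=body, elements=tuple(elements))


def parse_prosite(path) -> list[PrositePattern]:
    """Parse a PROSITE flat file, or a file of bare pattern lines.

    Flat-file records use ``ID``/``AC``/``PA`` lines (PA may span several
    lines, terminated by '.').  Any other file is treated as one pattern per
    non-empty, non-comment line.
    """
    with open(path) as fh:
        lines = fh.readlines()
    patterns: list[PrositePattern] = []
    if any(line.startswith("PA ") for line in lines):
        accession = ""
        buffer = ""
        for line in lines:
            if line.startswith("AC "):
                accession = line[3:].strip().rstrip(";")
            elif line.startswith("ID ") and not accession:
                accession = line[3:].split(";")[0].strip()
            elif line.startswith("PA "):
                buffer += line[3:].strip()
                if buffer.endswith("."):
                    patterns.append(_parse_pattern(buffer, accession or f"pattern_{len(patterns) + 1}"))
                    buffer = ""
            elif line.startswith("//"):
                accession, buffer = "", ""
    else:
        for i, line in enumerate(lines, 1):
            text = line.strip()
            if text and not text.startswith("#"):
                patterns.append(_parse_pattern(text, f"pattern_{i}"))
    return patterns


def prosite_conserved_composition(patterns: list[PrositePattern]) -> dict[str, float]:
    """Amino-acid fractions over conserved PROSITE positions.

    Patterns whose conserved residues are all cysteine are excluded; the
    remaining conserved residues are pooled at residue level.
    """
    pool: Counter = Counter()
    for pat in patterns:
        conserved = pat.conserved_residues
        if conserved and set(conserved) == {"C"}:
            continue
        pool.update(conserved)
    total = sum(pool.values())
    if total == 0:
        raise ValidationError("no conserved residues left after Cys-only exclusion")
    return {aa: c / total for aa, c in sorted(pool.items())}
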