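"""Poisson enrichment scoring of pockets and alignment-depth optimization.

For pocket *i* and alignment depth *j*:

* ``OPC`` — observed pocket conservation: lining atoms whose residue is
  conserved at depth *j*;
* ``EPC = TCA_j * PA_i / TA`` — atoms expected conserved if conserved atoms
  were spread uniformly over the protein;
* the significance of the observation is the Poisson point probability
  ``p = e^-EPC * EPC^OPC / OPC!``.

The depth optimizer scans prefixes of the e-value-ordered alignment and
keeps the depth whose best enriched pocket attains the lowest p-value; the
enriched pocket with the lowest p-value at that depth is the predicted
active-site pocket.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.special import gammaln
from scipy.stats import poisson as _poisson

from .conservation import ConservationProfile, build_profile
from .errors import ValidationError
from .msa import OrderedAlignment, prefix
from .pockets import PocketSet
from .structure_io import Structure


@dataclass(frozen=True)
class PocketScore:
    """Conservation enrichment of one pocket at one alignment depth."""

    pocket_id: str
    pa: int
    volume: float | None
    opc: int
    epc: float
    ratio: float  # OPC/EPC; nan when EPC == 0
    p_value: float
    enriched: bool  # ratio > 1
    conserved: bool  # enriched and p < alpha


@dataclass(frozen=True)
class OptimizationResult:
    """Outcome of the alignment-depth scan."""

    best_j: int
    profile: ConservationProfile
    scores: tuple[PocketScore, ...]
    active_site_pocket: str | None
    conserved_pockets: tuple[str, ...]  # ordered by increasing p-value
    trace: tuple[tuple[int, float], ...]  # (j, objective) per depth scanned


def poisson_point_probability(epc: float, opc: int, tail: bool = False) -> float:
    """Poisson probability of observing *opc* conserved atoms given mean *epc*.

    By default this is the point probability (pmf) ``e^-epc epc^opc / opc!``,
    evaluated in log-space for stability.  With ``tail=True`` the upper-tail
    probability ``P(X >= opc)`` is returned instead.
    """
    if epc < 0:
        raise ValidationError(f"expected conservation must be >= 0, got {epc}")
    if opc < 0 or int(opc) != opc:
        raise ValidationError(f"observed count must be a non-negative integer, got {opc}")
    opc = int(opc)
    if tail:
        return float(_poisson.sf(opc - 1, epc)) if epc > 0 else (1.0 if opc == 0 else 0.0)
    if epc == 0:
        return 1.0 if opc == 0 else 0.0
    log_p = -epc + opc * math.log(epc) - float(gammaln(opc + 1))
    return math.exp(log_p)


def score_pockets(pocket_set: PocketSet,
                  profile: ConservationProfile,
                  structure: Structure,
                  alpha: float = 0.05,
                  tail: bool = False) -> list[PocketScore]:
    """Score every pocket against a conservation profile."""
    ta = structure.total_atoms
    if ta == 0:
        raise ValidationError("structure has no atoms (TA = 0)")
    conserved_keys = profile.conserved_residues
    scores = []
    for pocket in pocket_set:
        opc = sum(
            1 for s in pocket.atom_serials
            if structure.atom_by_serial(s).residue_key in conserved_keys)
        epc = profile.tca * pocket.n_atoms / ta
        ratio = opc / epc if epc > 0 else float("nan")
        p = poisson_point_probability(epc, opc, tail=tail)
        enriched = epc > 0 and ratio > 1
        scores.append(PocketScore(
            pocket_id=pocket.pocket_id, pa=pocket.n_atoms, volume=pocket.volume,
            opc=opc, epc=epc, ratio=ratio, p_value=p,
            enriched=enriched, conserved=enriched and p < alpha))
    return scores


def _objective(scores: list[PocketScore], mode: str) -> float:
    pool = [s for s in scores if s.enriched] if mode == "enriched" else list(scores)
    return min((s.p_value for s in pool), default=math.inf)


def optimize_depth(structure: Structure,
                   pocket_set: PocketSet,
                   alignment: OrderedAlignment,
                   alpha: float = 0.05,
                   j_min: int = 2,
                   strict_range: bool = False,
                   objective_mode: str = "enriched",
                   tail: bool = False,
                   start_threshold: float = 1.0,
                   step: float = 0.05,
                   floor: float = 0.50) -> OptimizationResult:
    """Scan alignment prefixes and keep the depth with the lowest p-value.

    The objective at depth *j* is the minimum p-value over enriched pockets
    (``objective_mode='all'`` drops the enrichment restriction); ties are
    broken toward the smallest *j*.  ``strict_range=True`` scans ``[2, N-2]``
    instead of the default ``[2, N]``.
    """
    n = alignment.n_homologs
    j_max = n - 2 if strict_range else n
    if j_max < j_min:
        raise ValidationError(
            f"alignment has {n} homolog rows; depth range [{j_min}, {j_max}] empty")
    if objective_mode not in ("enriched", "all"):
        raise ValidationError(f"unknown objective mode {objective_mode!r}")

    best_j = None
    best_obj = math.inf
    best_state: tuple[ConservationProfile, list[PocketScore]] | None = None
    trace = []
    for j in range(j_min, j_max + 1):
        profile = build_profile(prefix(alignment, j), structure,
                                start_threshold, step, floor)
        scores = score_pockets(pocket_set, profile, structure, alpha=alpha, tail=tail)
        obj = _objective(scores, objective_mode)
        trace.append((j, obj))
        if obj < best_obj:  # strict: ties keep the smallest j
            best_obj, best_j, best_state = obj, j, (profile, scores)

    if best_j is None:
        # no depth produced an enriched pocket: report the shallowest depth
        best_j = j_min
        profile = build_profile(prefix(alignment, j_min), structure,
                                start_threshold, step, floor)
        best_state = (profile,
                      score_pockets(pocket_set, profile, structure,
                                    alpha=alpha, tail=tail))
        warnings.warn("no alignment depth yields an enriched pocket; "
                      "no active site predicted", stacklevel=2)

    profile, scores = best_state
    conserved = tuple(
        s.pocket_id
        for s in sorted((s for s in scores if s.conserved),
                        key=lambda s: (s.p_value, s.pocket_id)))
    return OptimizationResult(
        best_j=best_j, profile=profile, scores=tuple(scores),
        active_site_pocket=conserved[0] if conserved else None,
        conserved_pockets=conserved, trace=tuple(trace))


def predict_largest_conserved(scores: list[PocketScore],
                              pocket_set: PocketSet) -> str | None:
    """Largest conserved pocket (volume if known, else PA); ties -> lowest p."""
    conserved = [s for s in scores if s.conserved]
    if not conserved:
        return None
    best = min(conserved, key=lambda s: (-pocket_set[s.pocket_id].size(), s.p_value))
    return best.pocket_id


def predict_largest(pocket_set: PocketSet) -> str:
    """Largest pocket outright — the geometry-only baseline predictor."""
    if len(pocket_set) == 0:
        raise ValidationError("empty pocket set")
    return min(pocket_set, key=lambda p: (-p.size(), p.pocket_id)).pocket_id
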