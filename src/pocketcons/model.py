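"""Model/results interface over the pocket-conservation pipeline.

:class:`PocketConservation` bundles the three inputs — structure, pockets
and e-value-ordered alignment — together with the tunable parameters, and
``fit()`` runs the alignment-depth optimization, returning a
:class:`PocketConservationResults` that carries per-pocket scores,
predictions, the optimization trace and a printable summary.

Example
-------
>>> from pocketcons import PocketConservation
>>> model = PocketConservation.from_files("prot.pdb", "pockets.tsv", "family.fasta")
>>> res = model.fit()
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import msa as _msa
from .conservation import ConservationProfile
from .errors import ValidationError
from .extension import (CompositeSite, extend_active_site, pocket_adjacency,
                        pymol_selection)
from .msa import OrderedAlignment
from .pockets import PocketSet, parse_castp_poc, parse_pocket_tsv
from .scoring import (OptimizationResult, PocketScore, optimize_depth,
                      predict_largest, predict_largest_conserved)
from .structure_io import Structure, read_pdb


@dataclass
class PocketConservation:
    """Poisson enrichment model of pocket conservation.

    Parameters
    ----------
    structure, pockets, alignment
        The protein, its surface pockets and the homolog family.
    alpha
        Significance level for calling a pocket conserved.
    max_seqs
        Truncate the alignment to this many homologs before optimizing
        (the optimizer then searches depths within the truncated family).
    redundancy_cutoff
        If set, greedily drop homologs with pairwise identity at or above
        this fraction to any kept row before optimizing.
    threshold_schedule
        ``(start, step, floor)`` of the adaptive conservation threshold.
    objective_mode
        'enriched' restricts the depth objective to enriched pockets;
        'all' minimizes over every pocket.
    strict_depth_range
        Search depths in [2, N-2] instead of [2, N].
    tail
        Use the upper-tail Poisson probability instead of the point
        probability.
    """

    structure: Structure
    pockets: PocketSet
    alignment: OrderedAlignment
    alpha: float = 0.05
    max_seqs: int | None = 50
    redundancy_cutoff: float | None = None
    threshold_schedule: tuple[float, float, float] = (1.0, 0.05, 0.50)
    j_min: int = 2
    objective_mode: str = "enriched"
    strict_depth_range: bool = False
    tail: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        aln = self.alignment
        if self.redundancy_cutoff is not None:
            aln = _msa.filter_redundant(aln, self.redundancy_cutoff)
        if self.max_seqs is not None and aln.n_homologs > self.max_seqs:
            aln = _msa.prefix(aln, self.max_seqs)
        self.alignment_ = aln  # the alignment actually scored

    @classmethod
    def from_files(cls, structure_path, pockets_path, msa_path, **kwargs
                   ) -> "PocketConservation":
        """Build the model from a PDB file, a pocket file and an aligned FASTA.

        Pocket files ending in ``.poc`` are read as the annotated-PDB
        dialect, anything else as the TSV dialect.
        """
        structure = read_pdb(structure_path)
        if str(pockets_path).endswith(".poc"):
            pockets = parse_castp_poc(pockets_path, structure)
        else:
            pockets = parse_pocket_tsv(pockets_path, structure)
        alignment = _msa.read_ordered_msa(msa_path)
        return cls(structure, pockets, alignment, **kwargs)

    def fit(self) -> "PocketConservationResults":
        start, step, floor = self.threshold_schedule
        result = optimize_depth(
            self.structure, self.pockets, self.alignment_,
            alpha=self.alpha, j_min=self.j_min,
            strict_range=self.strict_depth_range,
            objective_mode=self.objective_mode, tail=self.tail,
            start_threshold=start, step=step, floor=floor)
        return PocketConservationResults(model=self, optimization=result)


@dataclass
class PocketConservationResults:
    """Fitted pocket-conservation scores and predictions."""

    model: PocketConservation
    optimization: OptimizationResult
    _adjacency: dict | None = field(default=None, repr=False)

    # -- convenience accessors --------------------------------------------
    @property
    def best_depth(self) -> int:
        return self.optimization.best_j

    @property
    def profile(self) -> ConservationProfile:
        return self.optimization.profile

    @property
    def scores(self) -> tuple[PocketScore, ...]:
        return self.optimization.scores

    @property
    def active_site_pocket(self) -> str | None:
        return self.optimization.active_site_pocket

    @property
    def conserved_pockets(self) -> tuple[str, ...]:
        return self.optimization.conserved_pockets

    @property
    def largest_pocket(self) -> str:
        return predict_largest(self.model.pockets)

    @property
    def largest_conserved_pocket(self) -> str | None:
        return predict_largest_conserved(list(self.scores), self.model.pockets)

    # -- tabular views -----------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        """Per-pocket score table, ranked by p-value."""
        rows = []
        for s in sorted(self.scores, key=lambda s: (s.p_value, s.pocket_id)):
            rows.append({
                "pocket_id": s.pocket_id, "PA": s.pa, "volume": s.volume,
                "OPC": s.opc, "EPC": s.epc, "ratio": s.ratio,
                "p_value": s.p_value, "enriched": s.enriched,
                "conserved": s.conserved})
        df = pd.DataFrame(rows)
        df.index = range(1, len(df) + 1)
        df.index.name = "rank"
        return df

    @property
    def trace_frame(self) -> pd.DataFrame:
        """Objective (lowest enriched-pocket p-value) per depth scanned."""
        return pd.DataFrame(self.optimization.trace, columns=["j", "objective"])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t")

    # -- composite site ----------------------------------------------------
    def extend_active_site(self, distance_cutoff: float = 4.5) -> CompositeSite:
        """Merge contiguous conserved pockets into the composite site."""
        adjacency = pocket_adjacency(self.model.pockets, self.model.structure,
                                     distance_cutoff)
        return extend_active_site(self.optimization, adjacency,
                                  self.model.pockets, self.model.structure)

    def composite_selection(self, distance_cutoff: float = 4.5) -> str:
        return pymol_selection(self.extend_active_site(distance_cutoff))

    # -- report ------------------------------------------------------------
    def summary(self) -> str:
        m = self.model
        prof = self.profile
        lines = [
            "Pocket conservation enrichment",
            "=" * 62,
            f"structure:           {m.structure.name}"
            f"  (TA = {m.structure.total_atoms} heavy atoms)",
            f"pockets:             {len(m.pockets)}",
            f"homologs scored:     {m.alignment_.n_homologs}"
            f"  (alpha = {m.alpha}, objective = {m.objective_mode})",
            f"optimal depth j*:    {self.best_depth}",
            f"identity threshold:  {prof.threshold_used:.2f}"
            f"  ({len(prof.conserved_residues)} conserved residues,"
            f" TCA = {prof.tca})",
            f"active-site pocket:  {self.active_site_pocket or 'none'}",
            f"conserved pockets:   {', '.join(self.conserved_pockets) or 'none'}",
            "",
            self.frame.to_string(
                float_format=lambda v: f"{v:.4g}", na_rep="-"),
        ]
        return "\n".join(lines)
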