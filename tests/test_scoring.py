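"""Poisson statistic, pocket scoring, depth optimization, predictors."""

import math
import warnings

import mpmath
import pytest
from scipy.stats import poisson as scipy_poisson

from pocketcons import (ConservationProfile, OrderedAlignment, ValidationError,
                        build_profile, optimize_depth,
                        poisson_point_probability, predict_largest,
                        predict_largest_conserved, prefix, score_pockets)
from pocketcons.pockets import Pocket, PocketSet
from pocketcons.synthetic import (SyntheticSpec, evolve_homologs,
                                  generate_structure, generate_triple,
                                  planted_pocket_id)

from conftest import build_structure, chain_of


def mp_pmf(epc, opc):
    with mpmath.workdps(50):
        return float(mpmath.e ** (-epc) * mpmath.mpf(epc) ** opc /
                     mpmath.factorial(opc))


class TestPoissonPointProbability:
    def test_zero_count_closed_form(self):
        assert poisson_point_probability(1.0, 0) == pytest.approx(math.exp(-1))

    def test_degenerate_cases(self):
        assert poisson_point_probability(0.0, 0) == 1.0
        assert poisson_point_probability(0.0, 3) == 0.0

    def test_matches_arbitrary_precision(self):
        assert poisson_point_probability(2.0, 2) == pytest.approx(
            mp_pmf(2.0, 2), abs=1e-12)

    @pytest.mark.parametrize("epc, opc", [(0.5, 1), (5.0, 20), (80.0, 3)])
    def test_log_space_stability(self, epc, opc):
        assert poisson_point_probability(epc, opc) == pytest.approx(
            mp_pmf(epc, opc), rel=1e-10, abs=1e-300)

    @pytest.mark.parametrize("epc, opc", [(-1.0, 0), (1.0, -2), (1.0, 1.5)])
    def test_invalid_inputs(self, epc, opc):
        with pytest.raises(ValidationError):
            poisson_point_probability(epc, opc)

    def test_tail_matches_scipy_survival(self):
        for opc in (0, 1, 5):
            assert poisson_point_probability(3.0, opc, tail=True) == \
                pytest.approx(float(scipy_poisson.sf(opc - 1, 3.0)))


def profile_for(structure, keys):
    keys = frozenset(keys)
    tca = sum(structure.residue_by_key(k).n_atoms for k in keys)
    return ConservationProfile(j=2, threshold_used=1.0,
                               conserved_columns=frozenset(),
                               conserved_residues=keys, tca=tca)


class TestScorePockets:
    def test_fully_conserved_pocket(self):
        # 20 ALA residues = 100 atoms; pocket = 2 residues = 10 atoms,
        # both conserved: OPC=10, EPC=10*10/100=1, p = e^-1/10!
        s = build_structure(chain_of("A" * 20))
        conserved = {("A", 1, ""), ("A", 2, "")}
        pocket = PocketSet([Pocket("p", frozenset(range(1, 11)))], s)
        (score,) = score_pockets(pocket, profile_for(s, conserved), s)
        assert score.opc == 10
        assert score.epc == pytest.approx(1.0)
        assert score.ratio == pytest.approx(10.0)
        assert score.p_value == pytest.approx(math.exp(-1) / math.factorial(10))
        assert score.p_value == pytest.approx(mp_pmf(1.0, 10), abs=1e-15)
        assert score.enriched and score.conserved

    def test_unconserved_pocket_not_enriched(self):
        s = build_structure(chain_of("A" * 20))
        conserved = {("A", k, "") for k in range(11, 21)}  # TCA = 50
        pocket = PocketSet([Pocket("p", frozenset(range(1, 11)))], s)
        (score,) = score_pockets(pocket, profile_for(s, conserved), s)
        assert score.opc == 0 and score.ratio == 0.0
        assert not score.enriched and not score.conserved

    def test_saturation_everything_conserved(self):
        s = build_structure(chain_of("A" * 10))
        conserved = {("A", k, "") for k in range(1, 11)}
        pockets = PocketSet([Pocket("p1", frozenset(range(1, 11))),
                             Pocket("p2", frozenset(range(11, 31)))], s)
        for score in score_pockets(pockets, profile_for(s, conserved), s):
            assert score.opc == score.pa
            assert score.epc == pytest.approx(score.pa)
            assert score.ratio == pytest.approx(1.0)
            assert not score.enriched

    def test_expectation_linearity(self):
        spec = SyntheticSpec(n_residues=80, n_homologs=10, seed=21)
        structure, pockets, alignment = generate_triple(spec)
        profile = build_profile(prefix(alignment, 5), structure)
        scores = score_pockets(pockets, profile, structure)
        total_pa = sum(p.n_atoms for p in pockets)
        assert sum(s.epc for s in scores) == pytest.approx(
            profile.tca * total_pa / structure.total_atoms, abs=1e-9)


def exhaustive_best(structure, pockets, alignment, alpha=0.05):
    """Independent exhaustive depth scan (test oracle)."""
    best = None
    for j in range(2, alignment.n_homologs + 1):
        profile = build_profile(prefix(alignment, j), structure)
        scores = score_pockets(pockets, profile, structure, alpha=alpha)
        enriched = [s for s in scores if s.enriched]
        obj = min((s.p_value for s in enriched), default=math.inf)
        if best is None or obj < best[0]:
            candidates = sorted((s for s in scores if s.conserved),
                                key=lambda s: (s.p_value, s.pocket_id))
            best = (obj, j, candidates[0].pocket_id if candidates else None)
    return best[1], best[2]


class TestOptimizeDepth:
    def test_constant_conservation_ties_to_j_min(self):
        # homologs all identical: the conserved set (the W block) is the same
        # at every depth, so the tie resolves to the smallest j
        s = build_structure(chain_of("GGGGWWWW"))
        alignment = OrderedAlignment(
            (("q", "GGGGWWWW"),) + tuple((f"h{k}", "AAAAWWWW") for k in range(5)))
        w_serials = frozenset(a.serial for r in s.residues()
                              for a in r.atoms if r.aa == "W")
        g_serials = frozenset(a.serial for r in s.residues()
                              for a in r.atoms if r.aa == "G")
        pockets = PocketSet([Pocket("pw", w_serials), Pocket("pg", g_serials)], s)
        result = optimize_depth(s, pockets, alignment)
        assert result.best_j == 2
        assert result.active_site_pocket == "pw"
        assert {obj for _, obj in result.trace} == {result.trace[0][1]}

    def test_planted_pocket_recovered(self):
        spec = SyntheticSpec(seed=42)
        structure, pockets, alignment = generate_triple(spec)
        result = optimize_depth(structure, pockets, alignment)
        assert result.active_site_pocket == planted_pocket_id(spec)
        assert result.conserved_pockets[0] == result.active_site_pocket

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle(self, seed):
        spec = SyntheticSpec(n_residues=100, n_homologs=15, seed=seed,
                             divergence_breakpoint=6, rate=0.05)
        structure, pockets, alignment = generate_triple(spec)
        result = optimize_depth(structure, pockets, alignment)
        assert (result.best_j, result.active_site_pocket) == \
            exhaustive_best(structure, pockets, alignment)

    def test_no_enrichment_warns_and_predicts_nothing(self):
        spec = SyntheticSpec(n_residues=40, n_homologs=5, rate=0.0,
                             divergence_breakpoint=5, seed=3)
        structure, pockets, alignment = generate_triple(spec)
        # rate 0 everywhere: every residue conserved, no pocket enriched
        with pytest.warns(UserWarning, match="no alignment depth"):
            result = optimize_depth(structure, pockets, alignment)
        assert result.active_site_pocket is None
        assert result.conserved_pockets == ()

    def test_strict_range_excludes_deep_prefixes(self):
        spec = SyntheticSpec(n_residues=60, n_homologs=10, seed=5)
        structure, pockets, alignment = generate_triple(spec)
        result = optimize_depth(structure, pockets, alignment, strict_range=True)
        assert 2 <= result.best_j <= 8
        assert [j for j, _ in result.trace] == list(range(2, 9))


class TestSizePredictors:
    def make(self, sizes_volumes):
        total = sum(n_atoms for n_atoms, _, _ in sizes_volumes)
        s = build_structure(chain_of("G" * ((total + 3) // 4)))
        pockets, scores = [], []
        serial = 1
        from pocketcons.scoring import PocketScore
        for i, (n_atoms, volume, conserved) in enumerate(sizes_volumes):
            serials = frozenset(range(serial, serial + n_atoms))
            serial += n_atoms
            pockets.append(Pocket(f"p{i + 1}", serials, volume=volume))
            scores.append(PocketScore(
                pocket_id=f"p{i + 1}", pa=n_atoms, volume=volume, opc=n_atoms,
                epc=1.0, ratio=float(n_atoms), p_value=0.01 * (i + 1),
                enriched=conserved, conserved=conserved))
        return PocketSet(pockets, s), scores

    def test_largest_uses_volume_then_pa(self):
        ps, _ = self.make([(10, None, True), (25, None, True), (7, None, True)])
        assert predict_largest(ps) == "p2"
        ps2, _ = self.make([(10, 300.0, True), (25, 120.0, True)])
        assert predict_largest(ps2) == "p1"

    def test_largest_tie_breaks_on_id(self):
        ps, _ = self.make([(10, None, True), (10, None, True)])
        assert predict_largest(ps) == "p1"

    def test_largest_conserved(self):
        ps, scores = self.make([(10, 120.0, True), (8, 300.0, True),
                                (30, 500.0, False)])
        assert predict_largest_conserved(scores, ps) == "p2"

    def test_largest_conserved_none_when_no_conserved(self):
        ps, scores = self.make([(10, None, False)])
        assert predict_largest_conserved(scores, ps) is None

    def test_largest_empty_set_errors(self):
        s = build_structure(chain_of("G"))
        with pytest.raises(ValidationError):
            predict_largest(PocketSet([], s))
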