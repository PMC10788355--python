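"""Sex-conformity screen: counting oracles, threshold bounds, nesting,
symmetry, and the chance-linkage expectation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from dartsex.panel import MISSING, MarkerType, Sex
from dartsex.screen import (
    Classification,
    Direction,
    ScreenCriterion,
    System,
    admissible_directions,
    conformity,
    infer_system,
    screen,
    spurious_linkage,
)

from conftest import make_panel, make_registry, random_panel


def brute_force_conformity(calls, male_idx, female_idx, marker_type, system, direction):
    """Per-individual tally, written independently of the implementation."""
    if marker_type is MarkerType.SNP:
        het_state = lambda c: c == 1
        hom_state = lambda c: c in (0, 2)
    elif direction is Direction.PRESENT_IN_HETEROGAMETIC:
        het_state = lambda c: c == 1
        hom_state = lambda c: c == 0
    else:
        het_state = lambda c: c == 0
        hom_state = lambda c: c == 1
    het_idx, hom_idx = (
        (male_idx, female_idx) if system is System.XY else (female_idx, male_idx)
    )

    def frac(idx, pred):
        vals = [calls[j] for j in idx if calls[j] != MISSING]
        return sum(pred(c) for c in vals) / len(vals) if vals else float("nan")

    het_c, hom_c = frac(het_idx, het_state), frac(hom_idx, hom_state)
    return (het_c, hom_c) if system is System.XY else (hom_c, het_c)


def brute_force_screen(panel, sexes, system, t, min_calls=8, include_absent=False):
    """Exhaustive per-locus, per-direction evaluation of the bounds."""
    males, females = sexes.indices(panel.individuals)
    out = set()
    for locus in panel.loci:
        calls = panel.locus_calls(locus)
        n_m = sum(calls[j] != MISSING for j in males)
        n_f = sum(calls[j] != MISSING for j in females)
        if n_m < min_calls or n_f < min_calls:
            continue
        for d in admissible_directions(panel.marker_type, include_absent):
            mc, fc = brute_force_conformity(
                calls, males, females, panel.marker_type, system, d
            )
            het_c, hom_c = (mc, fc) if system is System.XY else (fc, mc)
            if het_c >= t / 100 and (1 - hom_c) <= (100 - t) / 100:
                out.add(locus)
                break
    return out


class TestConformity:
    def test_perfect_xy_locus(self):
        calls = [1] * 16 + [0] * 16
        panel = make_panel(MarkerType.SNP, [calls])
        sexes = make_registry(panel.individuals, 16)
        assert conformity(panel, sexes, "L000", System.XY) == (1.0, 1.0)

    def test_partial_male_heterozygosity(self):
        # 12/16 males het (4 hom), all females hom
        calls = [1] * 12 + [0] * 4 + [2] * 8 + [0] * 8
        panel = make_panel(MarkerType.SNP, [calls])
        sexes = make_registry(panel.individuals, 16)
        assert conformity(panel, sexes, "L000", System.XY) == (0.75, 1.0)

    def test_unknown_locus_raises(self):
        panel = make_panel(MarkerType.SNP, [[0, 1]])
        sexes = make_registry(panel.individuals, 1)
        with pytest.raises(KeyError):
            conformity(panel, sexes, "nope", System.XY)

    def test_zero_call_sex_is_nan(self):
        panel = make_panel(MarkerType.SNP, [[MISSING, 0, 2, 0]])
        sexes = make_registry(panel.individuals, 1)
        mc, fc = conformity(panel, sexes, "L000", System.XY)
        assert np.isnan(mc) and fc == 1.0

    @pytest.mark.parametrize("marker", [MarkerType.SNP, MarkerType.PA])
    @pytest.mark.parametrize("system", [System.XY, System.ZW])
    def test_matches_counting_oracle(self, marker, system):
        rng = np.random.default_rng(11)
        panel = random_panel(rng, marker, n_loci=30, n_ind=32, missing_rate=0.15)
        sexes = make_registry(panel.individuals, 16)
        males, females = sexes.indices(panel.individuals)
        for locus in panel.loci:
            for d in admissible_directions(marker, include_absent=True):
                got = conformity(panel, sexes, locus, system, d)
                want = brute_force_conformity(
                    panel.locus_calls(locus), males, females, marker, system, d
                )
                np.testing.assert_allclose(got, want, equal_nan=True)


class TestScreen:
    def test_perfect_locus_is_sex_specific_at_100(self):
        calls = [1] * 16 + [0] * 16
        panel = make_panel(MarkerType.SNP, [calls])
        sexes = make_registry(panel.individuals, 16)
        for t in (70, 80, 90, 100):
            res = screen(panel, sexes, ScreenCriterion(System.XY, t, MarkerType.SNP))
            assert res.locus_ids == {"L000"}
        assert res.classification is Classification.SEX_SPECIFIC

    def test_bounds_at_70_but_not_80(self):
        # 12/16 males het (0.75 >= 0.70), 4/16 females het (0.25 <= 0.30)
        calls = [1] * 12 + [0] * 4 + [1] * 4 + [0] * 12
        panel = make_panel(MarkerType.SNP, [calls])
        sexes = make_registry(panel.individuals, 16)
        r70 = screen(panel, sexes, ScreenCriterion(System.XY, 70, MarkerType.SNP))
        r80 = screen(panel, sexes, ScreenCriterion(System.XY, 80, MarkerType.SNP))
        assert r70.locus_ids == {"L000"}
        assert r80.locus_ids == set()
        assert r70.classification is Classification.SEX_LINKED

    @pytest.mark.parametrize("marker", [MarkerType.SNP, MarkerType.PA])
    @pytest.mark.parametrize("system", [System.XY, System.ZW])
    @pytest.mark.parametrize("t", [70, 80, 90, 100])
    def test_matches_exhaustive_oracle(self, marker, system, t):
        rng = np.random.default_rng(5)
        panel = random_panel(rng, marker, n_loci=120, n_ind=32, missing_rate=0.2)
        sexes = make_registry(panel.individuals, 16)
        res = screen(panel, sexes, ScreenCriterion(system, t, marker))
        assert res.locus_ids == brute_force_screen(panel, sexes, system, t)

    def test_planted_loci_recovered_per_oracle(self, small_family):
        snp, pa, sexes, truth = small_family
        for panel in (snp, pa):
            res = screen(
                panel, sexes, ScreenCriterion(System.XY, 70, panel.marker_type)
            )
            assert res.locus_ids == brute_force_screen(panel, sexes, System.XY, 70)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=hst.integers(0, 2**31 - 1))
    def test_candidate_sets_nest_across_thresholds(self, seed):
        rng = np.random.default_rng(seed)
        marker = MarkerType.SNP if seed % 2 else MarkerType.PA
        panel = random_panel(rng, marker, n_loci=60, n_ind=32, missing_rate=0.2)
        sexes = make_registry(panel.individuals, 16)
        for system in (System.XY, System.ZW):
            sets = [
                screen(panel, sexes, ScreenCriterion(system, t, marker)).locus_ids
                for t in (70, 80, 90, 100)
            ]
            for lo, hi in zip(sets, sets[1:]):
                assert hi <= lo

    def test_sex_relabeling_swaps_systems_exactly(self):
        rng = np.random.default_rng(3)
        panel = random_panel(rng, MarkerType.SNP, 80, 32, missing_rate=0.1)
        sexes = make_registry(panel.individuals, 16)
        flipped = sexes.swapped()
        for t in (70, 90):
            xy = screen(panel, sexes, ScreenCriterion(System.XY, t, MarkerType.SNP))
            zw_flip = screen(
                panel, flipped, ScreenCriterion(System.ZW, t, MarkerType.SNP)
            )
            assert xy.locus_ids == zw_flip.locus_ids

    def test_low_call_loci_are_skipped(self):
        calls = [[1] * 4 + [MISSING] * 12 + [0] * 16]
        panel = make_panel(MarkerType.SNP, calls)
        sexes = make_registry(panel.individuals, 16)
        res = screen(panel, sexes, ScreenCriterion(System.XY, 70, MarkerType.SNP))
        assert res.locus_ids == set()
        assert res.skipped_loci == ["L000"]


class TestSpuriousLinkage:
    def test_probability_for_32_individuals(self):
        sp = spurious_linkage(n=32, L=37_154)
        assert sp.P_i == pytest.approx(2.33e-10, rel=5e-3)
        assert sp.expected_count == pytest.approx(8.65e-6, rel=5e-3)
        assert sp.P_i == 0.5**32  # exact by definition

    def test_base_case(self):
        assert spurious_linkage(1, 1).P_i == 0.5

    @pytest.mark.parametrize("n,L", [(0, 10), (10, 0), (-1, 5)])
    def test_nonpositive_inputs_rejected(self, n, L):
        with pytest.raises(ValueError):
            spurious_linkage(n, L)


class TestInferSystem:
    def _result(self, system, t, n, marker=MarkerType.SNP):
        row = [1] * 16 + [0] * 16 if system is System.XY else [0] * 16 + [1] * 16
        calls = np.tile(row, (n, 1)).astype(np.int8)
        panel = make_panel(marker, calls,
                           loci=[f"{system.value}{t}_{i}" for i in range(n)])
        sexes = make_registry(panel.individuals, 16)
        res = screen(panel, sexes, ScreenCriterion(system, t, marker))
        assert len(res.candidates) == n
        return res

    def test_xy_called_when_xy_dominates(self):
        results = [
            self._result(System.XY, 70, 5),
            self._result(System.ZW, 70, 2),
        ]
        call = infer_system(results)
        assert call.system == "XY"
        assert call.xy_linked_total == 5
        assert call.zw_linked_total == 2

    def test_all_zero_is_inconclusive(self):
        panel = make_panel(MarkerType.SNP, np.zeros((3, 32), dtype=np.int8))
        sexes = make_registry(panel.individuals, 16)
        results = [
            screen(panel, sexes, ScreenCriterion(s, 70, MarkerType.SNP))
            for s in (System.XY, System.ZW)
        ]
        assert infer_system(results).system == "inconclusive"

    def test_tie_is_inconclusive_with_tallies(self):
        results = [
            self._result(System.XY, 70, 3),
            self._result(System.ZW, 70, 3),
        ]
        call = infer_system(results)
        assert call.system == "inconclusive"
        assert call.counts.loc["XY", 70] == call.counts.loc["ZW", 70] == 3
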