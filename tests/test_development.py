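"""Index development: statistics, SD-sum screening, templates, overlap."""

import numpy as np
import pandas as pd
import pytest

from vegindex import (BandCombination, DataError, FormulaTemplate,
                      MultiTemporalStack, class_spectral_stats,
                      default_profiles, instantiate_index,
                      modified_index_definitions, operand, overlap_fraction,
                      sd_sum_score, select_combination, select_from_scores,
                      simulate_sample_table, standard_candidates)
from vegindex import indices as idx
from vegindex.development import IndexDefinition, enumerate_combinations
from vegindex.reference import SCREENING_CANDIDATES, SCREENING_WINNERS


def _table(rows):
    """rows: (class, phase, band, values) -> long sample table."""
    frames = []
    for cls, phase, band, values in rows:
        frames.append(pd.DataFrame({
            "class": cls, "phase": phase, "band": band,
            "reflectance": np.asarray(values, dtype=float)}))
    return pd.concat(frames, ignore_index=True)


class TestClassStats:
    def test_hand_values(self):
        t = _table([("a", "JUN", "RE2", [0.2, 0.4])])
        out = class_spectral_stats(t)
        assert out.loc[0, "mean"] == pytest.approx(0.3)
        assert out.loc[0, "sd"] == pytest.approx(np.sqrt(0.02), abs=1e-12)

    def test_constant_class_sd_zero(self):
        t = _table([("a", "JUN", "RE2", [0.3, 0.3, 0.3])])
        assert class_spectral_stats(t).loc[0, "sd"] == 0.0

    def test_full_synthetic_cell_count(self, profiles):
        t = simulate_sample_table(profiles, n_per_class=5, seed=0)
        out = class_spectral_stats(t)
        assert len(out) == 7 * 6 * 10

    def test_single_pixel_cell_rejected(self):
        t = _table([("a", "JUN", "RE2", [0.2])])
        with pytest.raises(DataError):
            class_spectral_stats(t)


class TestSdSumScore:
    def test_zero_noise_scores_zero(self, profiles):
        zero = default_profiles(noise_sd=0.0)
        t = simulate_sample_table(zero, n_per_class=10, seed=0)
        for cands in standard_candidates().values():
            for c in cands:
                assert sd_sum_score(c, t) == pytest.approx(0.0, abs=1e-9)

    def test_single_class_scope_arithmetic(self):
        # two operands with sd 0.01 each, one class in scope -> 2*0.01*1e4
        vals = [0.29, 0.30, 0.31]  # sd = 0.01
        t = _table([("q", "JUN", "RE4", vals), ("q", "OCT", "RE4", vals)])
        comb = BandCombination(operand("RE4", "JUN"), operand("RE4", "OCT"),
                               "q", ("q",))
        assert sd_sum_score(comb, t, scope="target") == pytest.approx(200.0)

    def test_multi_class_scope_arithmetic(self):
        # four classes, each operand sd 0.005 -> 4 * 2 * 0.005 * 1e4 = 400
        vals = np.array([0.3, 0.3, 0.3]) + np.array([-1, 0, 1]) * 0.005
        t = _table([(c, ph, "RE4", vals)
                    for c in "abcd" for ph in ("JUN", "OCT")])
        comb = BandCombination(operand("RE4", "JUN"), operand("RE4", "OCT"),
                               "a", tuple("abcd"))
        assert sd_sum_score(comb, t) == pytest.approx(400.0)

    def test_scale_equivariance(self, profiles, rng):
        t = simulate_sample_table(profiles, n_per_class=8, seed=3)
        comb = standard_candidates()["quercus"][1]
        s1 = sd_sum_score(comb, t)
        t2 = t.copy()
        t2["reflectance"] *= 0.5
        assert sd_sum_score(comb, t2) == pytest.approx(0.5 * s1, rel=1e-12)


class TestSelectCombination:
    @pytest.mark.parametrize("target", sorted(SCREENING_CANDIDATES))
    def test_published_scores_select_published_winner(self, target):
        cands = standard_candidates()[target]
        scores = [s for _, s in SCREENING_CANDIDATES[target]]
        report = select_from_scores(cands, scores)
        assert report.selected.label == SCREENING_WINNERS[target]
        assert report.selected_score == min(scores)

    def test_single_candidate_always_selected(self):
        c = standard_candidates()["shaw"][:1]
        assert select_from_scores(c, [999.0]).selected is c[0]

    def test_tie_breaks_to_first(self):
        cands = standard_candidates()["scrub_grass"][:2]
        report = select_from_scores(cands, [5.0, 5.0])
        assert report.selected_index == 0

    def test_permutation_stable_selected_score(self, profiles, rng):
        t = simulate_sample_table(profiles, n_per_class=6, seed=9)
        cands = standard_candidates()["shaw"]
        base = select_combination(cands, t).selected_score
        for _ in range(5):
            perm = [cands[i] for i in rng.permutation(len(cands))]
            assert select_combination(perm, t).selected_score == base

    def test_zero_noise_selects_first_candidate(self):
        zero = default_profiles(noise_sd=0.0)
        t = simulate_sample_table(zero, n_per_class=5, seed=0)
        report = select_combination(standard_candidates()["shaw"], t)
        assert report.selected_index == 0

    def test_empty_candidates_rejected(self):
        with pytest.raises(DataError):
            select_from_scores([], [])


class TestInstantiate:
    def test_template_patterns(self):
        a, b = 0.37, 0.22
        comb = BandCombination(operand("RE4", "JUN"), operand("RE4", "OCT"))
        diff = instantiate_index(comb, FormulaTemplate.DIFFERENCE, "d")
        nc = instantiate_index(comb, FormulaTemplate.NORMALIZED_COMPLEMENT, "n")
        rc = instantiate_index(comb, FormulaTemplate.RELATIVE_CHANGE, "r")
        assert float(diff.evaluate_operands(a, b)) == pytest.approx(a - b)
        assert float(nc.evaluate_operands(a, b)) == pytest.approx(
            (1 - a - b) / (a + b))
        assert float(rc.evaluate_operands(a, b)) == pytest.approx((a - b) / b)

    def test_definitions_bit_identical_to_direct_operations(self, rng):
        """Instantiated definitions reproduce the direct index functions
        bit-for-bit on random stacks."""
        data = rng.random((6, 10, 8, 8)) * 0.6 + 0.05
        stack = MultiTemporalStack(data=np.ma.asarray(data))
        direct = {
            "UTM-DMI": idx.utm_dmi(stack.band("FEB", "RE4"),
                                   stack.band("FEB", "SWIR1")),
            "MTM-NDQI": idx.mtm_ndqi(stack.band("JUN", "RE4"),
                                     stack.band("OCT", "RE4")),
            "MTM-DSI": idx.mtm_dsi(stack.band("JUN", "RE2"),
                                   stack.band("AUG", "RE2")),
            "MTM-RSI": idx.mtm_rsi(stack.band("JUN", "RE2"),
                                   stack.band("OCT", "RE2")),
        }
        for name, definition in modified_index_definitions().items():
            got = definition.evaluate(stack)
            assert np.array_equal(np.ma.getdata(got),
                                  np.ma.getdata(direct[name]))

    def test_json_roundtrip(self):
        for definition in modified_index_definitions().values():
            back = IndexDefinition.from_dict(definition.to_dict())
            assert back == definition


class TestOverlap:
    def test_identical_distributions(self, rng):
        x = rng.random(50)
        assert overlap_fraction(x, x) == 1.0

    def test_disjoint_ranges(self):
        assert overlap_fraction([1, 2], [5, 6]) == 0.0

    def test_partial_range_overlap_brute_force(self):
        a = np.array([1, 2, 3, 4])
        b = np.array([3, 4, 5, 6])
        assert overlap_fraction(a, b) == pytest.approx(0.5)

    def test_iqr_variant_narrower_than_range(self, rng):
        a = rng.normal(0, 1, 200)
        b = rng.normal(1, 1, 200)
        assert (overlap_fraction(a, b, method="iqr")
                <= overlap_fraction(a, b, method="range"))

    def test_empty_vector_rejected(self):
        with pytest.raises(DataError):
            overlap_fraction([], [1.0])


def test_enumerate_combinations_counts():
    combos = enumerate_combinations(["RE2", "RE4"], ["JUN", "OCT"], "shaw",
                                    ["larix"])
    assert len(combos) == 6  # C(4, 2) operand pairs
    cross = enumerate_combinations(["RE2", "RE4"], ["JUN", "OCT"], "shaw",
                                   ["larix"], cross_phase_only=True)
    assert all(c.a.phase != c.b.phase for c in cross)


class TestOverlapProperties:
    """Distribution-overlap invariants over arbitrary sample vectors."""

    from hypothesis import given, settings, strategies as st

    _vec = st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=50)

    @given(a=_vec, b=_vec)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounded_and_symmetric(self, a, b):
        f = overlap_fraction(a, b)
        assert 0.0 <= f <= 1.0
        assert f == overlap_fraction(b, a)

    @given(a=_vec)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_self_overlap_is_total(self, a):
        assert overlap_fraction(a, a) == 1.0
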