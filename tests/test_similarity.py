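import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaprofiler.similarity import (
    classify_effect,
    compute_all,
    diff_pos_max,
    ratio_area,
    ratio_intersect,
    ratio_max_max,
    ratio_normalized_intersect,
    spearman_correlation,
)

from oracles import BRUTE_FORCE

curve = st.lists(
    st.floats(0, 100, allow_nan=False, allow_infinity=False), min_size=2, max_size=40
)


class TestRatioArea:
    def test_basic_and_identity(self):
        assert ratio_area([2, 2, 2], [1, 1, 1]).value == pytest.approx(2.0)
        assert ratio_area([1, 2], [1, 2]).value == pytest.approx(1.0)

    def test_zero_denominator_undefined(self):
        r = ratio_area([1, 1], [0, 0])
        assert not r.defined and "area" in r.undefined_reason


class TestDiffPosMax:
    def test_signed_difference(self):
        p1 = np.zeros(20); p1[10] = 5
        p2 = np.zeros(20); p2[12] = 5
        assert diff_pos_max(p1, p2).value == -2

    def test_identical_curves_zero(self):
        p = np.array([0, 1, 5, 1.0])
        assert diff_pos_max(p, p).value == 0

    def test_tied_argmax_uses_median(self):
        r = diff_pos_max([0, 5, 5, 0], [9, 0, 0, 0])
        assert r.value == pytest.approx(1.5)

    def test_low_peaks_undefined(self):
        assert not diff_pos_max([0.1, 0.2], [5, 0]).defined

    @given(curve, curve)
    @settings(max_examples=100)
    def test_antisymmetry(self, a, b):
        n = min(len(a), len(b))
        r1, r2 = diff_pos_max(a[:n], b[:n]), diff_pos_max(b[:n], a[:n])
        if r1.defined:
            assert r1.value == -r2.value


class TestRatioMaxMax:
    def test_basic(self):
        assert ratio_max_max([0, 8, 1], [4, 0, 0]).value == pytest.approx(2.0)
        p = [1, 3, 2.0]
        assert ratio_max_max(p, p).value == pytest.approx(1.0)

    def test_zero_second_curve_undefined(self):
        assert not ratio_max_max([1, 5], [0, 0]).defined


class TestRatioIntersect:
    def test_identical_is_one_disjoint_is_zero(self):
        assert ratio_intersect([1, 2], [1, 2]).value == pytest.approx(1.0)
        assert ratio_intersect([1, 0], [0, 1]).value == pytest.approx(0.0)

    def test_worked_example(self):
        assert ratio_intersect([2, 2], [1, 3]).value == 0.6

    def test_both_zero_undefined(self):
        assert not ratio_intersect([0, 0], [0, 0]).defined

    @given(curve, curve)
    @settings(max_examples=150)
    def test_symmetry_and_range(self, a, b):
        n = min(len(a), len(b))
        r1, r2 = ratio_intersect(a[:n], b[:n]), ratio_intersect(b[:n], a[:n])
        if r1.defined:
            assert r1.value == pytest.approx(r2.value)
            assert 0 <= r1.value <= 1

    @pytest.mark.parametrize("c", [0.25, 0.5, 2.0, 10.0])
    def test_scalar_multiple_closed_form(self, c):
        p = np.array([1.0, 4.0, 2.0, 0.5])
        expected = min(c, 1.0) / max(c, 1.0)
        assert ratio_intersect(p, c * p).value == pytest.approx(expected)
        assert ratio_normalized_intersect(p, c * p).value == pytest.approx(1.0)


class TestRatioNormalizedIntersect:
    def test_scale_invariance(self):
        p = np.array([0.0, 3.0, 1.0])
        assert ratio_normalized_intersect(p, 10 * p).value == pytest.approx(1.0)

    def test_disjoint_supports(self):
        assert ratio_normalized_intersect([2, 0], [0, 2]).value == pytest.approx(0.0)

    def test_worked_example_equal_means(self):
        # means are both 2, so normalisation rescales the curves identically
        assert ratio_normalized_intersect([2, 2], [1, 3]).value == pytest.approx(0.6)

    def test_zero_mean_undefined(self):
        assert not ratio_normalized_intersect([0, 0], [1, 2]).defined


class TestSpearman:
    def test_monotone_curves(self):
        assert spearman_correlation([1, 2, 3], [10, 20, 80]).value == pytest.approx(1.0)
        assert spearman_correlation([1, 2, 3], [9, 5, 2]).value == pytest.approx(-1.0)

    def test_constant_curve_undefined(self):
        r = spearman_correlation([1, 2, 3], [4, 4, 4])
        assert not r.defined and "constant" in r.undefined_reason


class TestBruteForceAgreement:
    def test_all_metrics_match_oracle_on_random_pairs(self):
        """Package pseudometrics vs independent plain-loop implementations."""
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = rng.integers(2, 30)
            p1 = rng.random(n) * rng.choice([0.5, 10, 100])
            p2 = rng.random(n) * rng.choice([0.5, 10, 100])
            if rng.random() < 0.1:
                p1 = np.round(p1)  # force ties
                p2 = np.round(p2)
            results = compute_all(p1, p2)
            for name, res in results.items():
                expected = BRUTE_FORCE[name](list(p1), list(p2))
                if expected is None:
                    assert not res.defined, name
                else:
                    assert res.defined, name
                    assert res.value == pytest.approx(expected, abs=1e-12), name


class TestClassifyEffect:
    @pytest.mark.parametrize(
        "ri,label",
        [(0.66, "gradient"), (0.85, "threshold"), (0.88, "threshold")],
    )
    def test_cutoff_rule(self, ri, label):
        # curves constructed to hit the requested RATIO_INTERSECT exactly:
        # [1, 1] vs [ri, 1/... ] -- use proportional curves min/max closed form
        p = np.array([1.0, 1.0])
        q = p * ri  # ratio_intersect(p, ri*p) == ri for ri <= 1
        result = classify_effect(q, p)
        assert result.ratio_intersect == pytest.approx(ri)
        assert result.label == label

    def test_undefined_is_unclassifiable(self):
        r = classify_effect([0, 0], [0, 0])
        assert r.label == "unclassifiable" and r.ratio_intersect is None

    def test_custom_cutoff(self):
        p = np.array([1.0, 2.0])
        assert classify_effect(0.7 * p, p, cutoff=0.6).label == "threshold"


def test_length_mismatch_rejected_everywhere():
    for fn in (ratio_area, diff_pos_max, ratio_max_max, ratio_intersect,
               ratio_normalized_intersect, spearman_correlation):
        with pytest.raises(ValueError, match="equal length"):
            fn([1, 2], [1, 2, 3])
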