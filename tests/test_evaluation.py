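from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpdr.evaluation import (
    assign_main_function,
    complex_overlap_network,
    f_measure,
    hypergeom_pvalue,
    load_annotations,
    load_catalog,
    match_complexes,
    overlap_score,
    overlapping_rate,
    sensitivity,
    specificity,
)

from _oracles import brute_hypergeom_tail


class TestOverlapScore:
    def test_identical_sets_score_one(self):
        assert overlap_score({"A", "B", "C"}, {"A", "B", "C"}) == 1.0

    def test_disjoint_sets_score_zero(self):
        assert overlap_score({"A", "B"}, {"C", "D"}) == 0.0

    def test_formula(self):
        pc = set("ABCDEF")
        kc = set("ABCDEZ")
        assert overlap_score(pc, kc) == pytest.approx(25 / 36)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            overlap_score(set(), {"A"})

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.sets(st.sampled_from("ABCDEFGH"), min_size=1),
        st.sets(st.sampled_from("ABCDEFGH"), min_size=1),
    )
    def test_symmetric_and_bounded(self, pc, kc):
        s = overlap_score(pc, kc)
        assert s == overlap_score(kc, pc)
        assert 0 <= s <= 1
        assert (s == 1) == (pc == kc)


class TestMatchComplexes:
    def test_perfect_match(self):
        r = match_complexes([{"A", "B", "C"}], {"c1": {"A", "B", "C"}})
        assert (r.tp, r.fp, r.matched_known, r.fn) == (1, 0, 1, 0)

    def test_total_miss(self):
        r = match_complexes([{"A", "B", "C"}], {"c1": {"D", "E", "F"}})
        assert (r.tp, r.fp, r.fn) == (0, 1, 1)

    def test_threshold_boundary_inclusive(self):
        # OS = 4/16 = 0.25 >= 0.2
        r = match_complexes([{"A", "B", "C", "D"}], {"c1": {"A", "B", "X", "Y"}})
        assert r.tp == 1

    def test_count_invariants(self):
        predicted = [{"A", "B", "C"}, {"D", "E"}, {"A", "X"}]
        known = {"c1": {"A", "B", "C"}, "c2": {"P", "Q"}}
        r = match_complexes(predicted, known)
        assert r.tp + r.fp == len(predicted)
        assert r.matched_known + r.fn == len(known)

    def test_min_known_size_filters_denominator(self):
        known = {"small": {"A", "B"}, "big": {"A", "B", "C", "D", "E"}}
        r_all = match_complexes([{"A", "B"}], known)
        r_big = match_complexes([{"A", "B"}], known, min_known_size=3)
        assert r_all.matched_known + r_all.fn == 2
        assert r_big.matched_known + r_big.fn == 1

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            match_complexes([{"A"}], {})


class TestRatesAndFMeasure:
    def test_sensitivity_specificity_basic(self):
        assert sensitivity(1, 1) == 0.5
        assert sensitivity(0, 5) == 0.0
        assert specificity(0, 1) == 0.0
        with pytest.raises(ValueError):
            sensitivity(0, 0)
        with pytest.raises(ValueError):
            specificity(0, 0)

    def test_rational_reconstructions(self):
        # printed nine-digit rates arise from small integer ratios
        assert sensitivity(44, 162) == pytest.approx(0.213592233, abs=5e-10)
        assert specificity(44, 134) == pytest.approx(0.247191011, abs=5e-10)
        assert specificity(13, 5) == pytest.approx(0.722222222, abs=5e-10)

    def test_f_measure_exact_rational_identity(self):
        # with one matched count a over denominators x (known) and y
        # (predicted), F = 2a/(x+y) exactly
        for a, x, y in [(44, 206, 178), (32, 206, 61)]:
            sn, sp = Fraction(a, x), Fraction(a, y)
            f = 2 * sn * sp / (sn + sp)
            assert f == Fraction(2 * a, x + y)
            assert f_measure(float(sn), float(sp)) == pytest.approx(float(f))
        assert Fraction(88, 384) == Fraction(2 * 44, 206 + 178)

    def test_f_measure_idempotent_on_equal_rates(self):
        assert f_measure(0.37, 0.37) == pytest.approx(0.37)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.floats(0.001, 1.0, allow_nan=False),
        st.floats(0.001, 1.0, allow_nan=False),
    )
    def test_f_measure_sandwiched_by_inputs(self, sn, sp):
        f = f_measure(sn, sp)
        assert min(sn, sp) - 1e-12 <= f <= max(sn, sp) + 1e-12

    def test_overlapping_rate(self):
        assert overlapping_rate([{"A", "B", "C"}, {"D", "E", "F"}]) == (1.0, 0.0)
        rate = overlapping_rate([{"A", "B", "C"}, {"A", "D", "E"}])
        assert rate.rate == pytest.approx(6 / 5)
        assert rate.fraction_multi == pytest.approx(1 / 5)
        assert overlapping_rate([{"A", "B"}, {"A", "B"}]).rate == 2.0
        with pytest.raises(ValueError):
            overlapping_rate([])


class TestHypergeometric:
    def test_single_tail_term(self):
        assert hypergeom_pvalue(10, 5, 5, 5) == pytest.approx(1 / 252)

    def test_zero_hits_gives_one(self):
        assert hypergeom_pvalue(30, 4, 7, 0) == 1.0

    def test_bounds_validation(self):
        with pytest.raises(ValueError):
            hypergeom_pvalue(10, 5, 5, 6)

    def test_matches_brute_force_sum(self):
        for n, c, f, k in [(20, 6, 8, 4), (25, 10, 5, 3), (15, 7, 7, 7), (18, 4, 9, 1)]:
            assert hypergeom_pvalue(n, c, f, k) == pytest.approx(
                brute_hypergeom_tail(n, c, f, k), rel=1e-12
            )

    def test_monotone_nonincreasing_in_k(self):
        for n, c, f in [(20, 6, 8), (25, 12, 10)]:
            values = [hypergeom_pvalue(n, c, f, k) for k in range(min(c, f) + 1)]
            assert all(a >= b - 1e-15 for a, b in zip(values, values[1:]))


class TestMainFunction:
    def test_exclusive_shared_category(self):
        members = {f"P{i}" for i in range(5)}
        annotations = {p: {"10.01"} for p in members}
        r = assign_main_function(members, annotations, n_total=50)
        assert r.best_category == "10.01"
        assert r.k_in == 5
        assert r.p_value == pytest.approx(brute_hypergeom_tail(50, 5, 5, 5), rel=1e-9)

    def test_unassigned_when_no_annotation(self):
        r = assign_main_function({"A", "B"}, {"Z": {"1.1"}}, n_total=10)
        assert r.best_category is None and not r.assigned

    def test_tie_broken_lexicographically(self):
        members = {"A", "B", "C"}
        annotations = {p: {"20.09", "14.07"} for p in members}
        r = assign_main_function(members, annotations, n_total=30)
        assert r.best_category == "14.07"


class TestOverlapNetwork:
    def test_examples(self):
        assert complex_overlap_network(
            [{"A", "B", "C"}, {"C", "D", "E"}, {"F", "G", "H"}]
        ) == [(0, 1)]
        assert complex_overlap_network([{"A"}, {"B"}, {"C"}]) == []
        assert complex_overlap_network(
            [{"A", "B"}, {"A", "C"}, {"A", "D"}]
        ) == [(0, 1), (0, 2), (1, 2)]


class TestLoaders:
    def test_catalog_discards_singletons(self, tmp_path):
        p = tmp_path / "known.tsv"
        p.write_text("c1\tA\tB\tC\nsingleton\tX\nc2\tD\tE\n")
        catalog = load_catalog(p)
        assert set(catalog) == {"c1", "c2"}
        assert catalog["c1"] == frozenset("ABC")

    def test_catalog_duplicate_name_rejected(self, tmp_path):
        p = tmp_path / "known.tsv"
        p.write_text("c1\tA\tB\nc1\tC\tD\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_catalog(p)

    def test_annotations(self, tmp_path):
        p = tmp_path / "funcat.tsv"
        p.write_text("YAL001C\t20.09.07.03\nYAL001C\t14.07\nYBR002W\t20.09.07.03\n")
        ann = load_annotations(p)
        assert ann["YAL001C"] == frozenset({"20.09.07.03", "14.07"})
        assert ann["YBR002W"] == frozenset({"20.09.07.03"})
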