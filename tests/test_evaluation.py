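import math
from itertools import combinations

import pytest
from hypothesis import given, settings, strategies as st

from oiip import (
    EvaluationError,
    build_overlap_matrix,
    evaluate_predictions,
    functional_homogeneity,
    hypergeometric_pvalue,
    match_complexes,
    na_score,
    precision_recall_f,
    read_benchmark,
    significant_fraction,
    sn_ppv_acc,
)


def brute_force_tail(n, group, draw, k):
    """P(X >= k) by exhaustive enumeration of all draw-subsets of an n-set."""
    universe = range(n)
    in_group = set(range(group))
    hits = total = 0
    for subset in combinations(universe, draw):
        total += 1
        if len(in_group.intersection(subset)) >= k:
            hits += 1
    return hits / total


class TestNAScore:
    @pytest.mark.parametrize("np_, nb, inter, expected", [
        (13, 12, 12, 144 / 156),
        (7, 6, 6, 36 / 42),
        (18, 20, 17, 289 / 360),
    ])
    def test_published_worked_values(self, np_, nb, inter, expected):
        p = {f"p{i}" for i in range(np_)}
        b = {f"p{i}" for i in range(inter)} | {f"b{i}" for i in range(nb - inter)}
        assert na_score(p, b) == pytest.approx(expected, abs=1e-12)

    def test_boundaries(self):
        assert na_score({"a", "b"}, {"a", "b"}) == 1.0
        assert na_score({"a"}, {"b"}) == 0.0

    def test_empty_set_is_error(self):
        with pytest.raises(EvaluationError):
            na_score(set(), {"a"})

    @given(st.sets(st.integers(0, 20), min_size=1), st.sets(st.integers(0, 20), min_size=1))
    @settings(derandomize=True, max_examples=60)
    def test_symmetric_and_identity_iff_equal(self, a, b):
        a = {str(x) for x in a}
        b = {str(x) for x in b}
        assert na_score(a, b) == pytest.approx(na_score(b, a))
        assert (na_score(a, b) == 1.0) == (a == b)


class TestMatching:
    def test_identical_lists(self):
        cx = [frozenset({"a", "b", "c"}), frozenset({"d", "e"})]
        n_cp, n_cb, _ = match_complexes(cx, cx, 0.25)
        assert (n_cp, n_cb) == (2, 2)

    def test_disjoint_lists(self):
        p = [frozenset({"a", "b"})]
        b = [frozenset({"x", "y"}), frozenset({"z", "w"})]
        assert match_complexes(p, b, 0.25)[:2] == (0, 0)

    def test_hand_enumerated_toy(self):
        # NA(p1,b1) = 4/6 >= 0.25 is the only pair at or above threshold
        p = [frozenset({"a", "b", "c"}), frozenset({"q", "r"})]
        b = [frozenset({"a", "b"}), frozenset({"x", "y", "z"}), frozenset({"w"})]
        n_cp, n_cb, pairs = match_complexes(p, b, 0.25)
        assert (n_cp, n_cb) == (1, 1)
        assert [(j, i) for j, i, _ in pairs] == [(0, 0)]


class TestPrecisionRecallF:
    @pytest.mark.parametrize("args,expected", [
        ((1, 1, 2, 2), (0.5, 0.5, 0.5)),
        ((2, 3, 2, 3), (1.0, 1.0, 1.0)),
        ((0, 0, 5, 4), (0.0, 0.0, 0.0)),
    ])
    def test_arithmetic(self, args, expected):
        assert precision_recall_f(*args) == pytest.approx(expected)

    @given(st.integers(1, 30), st.integers(1, 30), st.data())
    @settings(derandomize=True, max_examples=60)
    def test_f_between_min_and_max(self, n_pred, n_bench, data):
        n_cp = data.draw(st.integers(0, n_pred))
        n_cb = data.draw(st.integers(0, n_bench))
        p, r, f = precision_recall_f(n_cp, n_cb, n_pred, n_bench)
        assert min(p, r) - 1e-12 <= f <= max(p, r) + 1e-12


class TestSnPpvAcc:
    def test_hand_arithmetic(self):
        bench = [frozenset({"a", "b", "c", "d"}), frozenset({"e", "f", "g"})]
        pred = [frozenset({"a", "b", "c", "e"}), frozenset({"e", "x", "f"})]
        # T = [[3, 0], [1, 2]], N = [4, 3]
        om = build_overlap_matrix(bench, pred)
        sn, ppv, acc = sn_ppv_acc(om)
        assert sn == pytest.approx(5 / 7)
        assert ppv == pytest.approx(5 / 6)
        assert acc == pytest.approx(math.sqrt((5 / 7) * (5 / 6)))

    def test_perfect_prediction(self):
        bench = [frozenset({"a", "b"}), frozenset({"c", "d", "e"})]
        sn, ppv, acc = sn_ppv_acc(build_overlap_matrix(bench, bench))
        assert (sn, ppv, acc) == (1.0, 1.0, 1.0)

    def test_no_overlap_zero_ppv(self):
        bench = [frozenset({"a", "b"})]
        pred = [frozenset({"x", "y"})]
        sn, ppv, acc = sn_ppv_acc(build_overlap_matrix(bench, pred))
        assert (ppv, acc) == (0.0, 0.0)

    def test_acc_bounded_by_components(self):
        bench = [frozenset({"a", "b", "c"}), frozenset({"d", "e"})]
        pred = [frozenset({"a", "b"}), frozenset({"d", "x"})]
        sn, ppv, acc = sn_ppv_acc(build_overlap_matrix(bench, pred))
        assert acc <= max(sn, ppv) + 1e-12

    def test_order_invariance(self):
        bench = [frozenset({"a", "b", "c"}), frozenset({"d", "e"})]
        pred = [frozenset({"a", "b"}), frozenset({"d", "x"}), frozenset({"c"})]
        fwd = sn_ppv_acc(build_overlap_matrix(bench, pred))
        rev = sn_ppv_acc(build_overlap_matrix(bench[::-1], pred[::-1]))
        assert fwd == pytest.approx(rev)


class TestHypergeometric:
    def test_hand_enumerated_example(self):
        assert hypergeometric_pvalue(10, 4, 3, 3) == pytest.approx(4 / 120, abs=1e-12)

    def test_group_is_whole_network(self):
        assert hypergeometric_pvalue(8, 8, 3, 3) == pytest.approx(1.0)

    def test_vacuous_tail(self):
        assert hypergeometric_pvalue(10, 4, 3, 0) == 1.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(EvaluationError):
            hypergeometric_pvalue(10, 4, 3, 4)
        with pytest.raises(EvaluationError):
            hypergeometric_pvalue(5, 8, 3, 2)

    def test_matches_exhaustive_enumeration(self):
        """Tail mass equals brute-force subset counting for all small cases."""
        for n in range(2, 13):
            for group in range(1, n + 1):
                for draw in range(1, n + 1):
                    for k in range(0, min(group, draw) + 1):
                        expected = brute_force_tail(n, group, draw, k)
                        got = hypergeometric_pvalue(n, group, draw, k)
                        assert got == pytest.approx(expected, abs=1e-12), (n, group, draw, k)


class TestFunctionalHomogeneity:
    GROUPS = {
        "G:small": frozenset({"a", "b", "c"}),
        "G:large": frozenset({"a", "b", "c", "d", "e", "f", "g", "h"}),
    }

    def test_cluster_inside_small_group_wins(self):
        p, gid = functional_homogeneity({"a", "b", "c"}, self.GROUPS, 12)
        assert gid == "G:small"
        assert p == pytest.approx(brute_force_tail(12, 3, 3, 3), abs=1e-12)

    def test_two_group_minimum_matches_enumeration(self):
        cluster = {"a", "b", "d"}
        p, gid = functional_homogeneity(cluster, self.GROUPS, 12)
        p_small = brute_force_tail(12, 3, 3, 2)
        p_large = brute_force_tail(12, 8, 3, 3)
        assert p == pytest.approx(min(p_small, p_large), abs=1e-12)
        assert gid == ("G:small" if p_small <= p_large else "G:large")

    def test_no_overlap_returns_one(self):
        p, gid = functional_homogeneity({"x", "y"}, self.GROUPS, 12)
        assert (p, gid) == (1.0, None)

    def test_empty_group_list_is_error(self):
        with pytest.raises(EvaluationError):
            functional_homogeneity({"a"}, {}, 12)


class TestSignificantFraction:
    def test_mixed_clusters_hand_fraction(self):
        groups = {"G:f": frozenset({"a", "b", "c"})}
        clusters = [{"a", "b", "c"}, {"a", "x", "y"}, {"x", "y", "z"}, {"b", "c", "q"}]
        n = 30
        per_cluster = [functional_homogeneity(c, groups, n)[0] for c in clusters]
        expected = sum(1 for p in per_cluster if p < 0.01) / 4
        assert significant_fraction(clusters, groups, n, alpha=0.01) == pytest.approx(expected)

    def test_no_overlap_is_zero(self):
        assert significant_fraction([{"x"}], {"G": frozenset({"a"})}, 10) == 0.0


class TestReaders:
    def test_benchmark_roundtrip_and_dedup(self):
        text = "a b c\nd\te\na c b\n# comment\n\n"
        bs = read_benchmark(text)
        assert bs.complexes == [frozenset({"a", "b", "c"}), frozenset({"d", "e"})]

    def test_empty_benchmark_is_error(self):
        with pytest.raises(EvaluationError):
            read_benchmark("# nothing\n")

    def test_evaluate_min_benchmark_size_filter(self):
        pred = [frozenset({"a", "b", "c"})]
        bench = read_benchmark("a b c\nx y\n")
        full = evaluate_predictions(pred, bench)
        filtered = evaluate_predictions(pred, bench, min_benchmark_size=3)
        assert full.recall == pytest.approx(0.5)
        assert filtered.recall == pytest.approx(1.0)
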