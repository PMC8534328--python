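import random

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gecluster.evaluation import (
    average_fscore,
    average_precision,
    best_matches,
    evaluate,
    filter_for_evaluation,
    homogeneity_proportion,
    overlap_statistics,
    pair_scores,
    propose_novel_members,
    read_gmt,
    write_gmt,
)

from conftest import make_graph


def _exhaustive_mean_best(clusters, refs, metric):
    """Independent double-loop oracle for the averaged best scores."""
    total = 0.0
    for members in clusters.values():
        best = 0.0
        for rmembers in refs.values():
            inter = len(set(members) & set(rmembers))
            p = inter / len(members)
            r = inter / len(rmembers)
            f = 2 * p * r / (p + r) if p + r else 0.0
            best = max(best, f if metric == "f" else p)
        total += best
    return total / len(clusters)


class TestPairScores:
    def test_partial_overlap(self):
        p, r, f = pair_scores({"a", "b", "c"}, {"b", "c", "d"})
        assert (p, r, f) == (pytest.approx(2 / 3), pytest.approx(2 / 3), pytest.approx(2 / 3))

    def test_identical(self):
        assert pair_scores({"x", "y"}, {"x", "y"}) == (1.0, 1.0, 1.0)

    def test_disjoint_f_convention(self):
        assert pair_scores({"a"}, {"b"}) == (0.0, 0.0, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pair_scores(set(), {"a"})

    @settings(max_examples=100, derandomize=True)
    @given(
        c=st.frozensets(st.integers(0, 15), min_size=1, max_size=10),
        r=st.frozensets(st.integers(0, 15), min_size=1, max_size=10),
    )
    def test_score_bounds_and_extremes(self, c, r):
        p, rec, f = pair_scores(c, r)
        assert 0.0 <= p <= 1.0 and 0.0 <= rec <= 1.0 and 0.0 <= f <= 1.0
        assert f <= (p + rec) / 2 + 1e-15  # harmonic <= arithmetic mean
        assert (f == 1.0) == (c == r)
        assert (f == 0.0) == (not c & r)


class TestFiltering:
    def test_reciprocal_exclusion(self):
        g = make_graph([("X", "Y"), ("A", "B")])
        refs = {"R1": frozenset({"X", "Y", "Z"}), "R2": frozenset({"Q"})}
        clusters = {"C1": frozenset({"A", "B"}), "C2": frozenset({"X", "A"})}
        fc, fr = filter_for_evaluation(clusters, g, refs)
        assert fr == {"R1": frozenset({"X", "Y"})}  # Z not in graph; R2 emptied
        assert fc == {"C2": frozenset({"X"})}  # A, B in no reference; C1 emptied

    def test_no_filtering_needed(self):
        g = make_graph([("A", "B"), ("B", "C")])
        refs = {"R": frozenset({"A", "B", "C"})}
        clusters = {"C1": frozenset({"A", "B"})}
        fc, fr = filter_for_evaluation(clusters, g, refs)
        assert (fc, fr) == (clusters, refs)


class TestAverages:
    def test_worked_micro_example(self):
        clusters = {"C1": frozenset({"a", "b"}), "C2": frozenset({"c", "d"})}
        refs = {"R1": frozenset({"a", "b"}), "R2": frozenset({"c", "e"})}
        assert average_fscore(clusters, refs) == pytest.approx(0.75)

    def test_identical_sets_give_one(self):
        clusters = {"C1": frozenset({"a", "b"}), "C2": frozenset({"c"})}
        refs = {"R1": frozenset({"a", "b"}), "R2": frozenset({"c"})}
        assert average_fscore(clusters, refs) == 1.0
        assert average_precision(clusters, refs) == 1.0

    def test_precision_examples(self):
        assert average_precision({"C1": frozenset({"a", "b"})}, {"R1": frozenset({"a"}), "R2": frozenset({"a", "b", "c"})}) == 1.0
        assert average_precision({"C1": frozenset({"a", "b", "c", "d"})}, {"R1": frozenset({"a", "b"})}) == 0.5

    def test_empty_inputs_error(self):
        with pytest.raises(ValueError):
            average_fscore({}, {"R": frozenset({"a"})})
        with pytest.raises(ValueError):
            average_fscore({"C1": frozenset({"a"})}, {})

    def test_matches_exhaustive_oracle(self):
        rng = random.Random(42)
        universe = [f"G{i:02d}" for i in range(20)]
        for _ in range(50):
            clusters = {
                f"C{i}": frozenset(rng.sample(universe, rng.randint(1, 8)))
                for i in range(rng.randint(1, 6))
            }
            refs = {
                f"R{i}": frozenset(rng.sample(universe, rng.randint(1, 8)))
                for i in range(rng.randint(1, 6))
            }
            assert average_fscore(clusters, refs) == pytest.approx(
                _exhaustive_mean_best(clusters, refs, "f"), abs=1e-12
            )
            assert average_precision(clusters, refs) == pytest.approx(
                _exhaustive_mean_best(clusters, refs, "p"), abs=1e-12
            )

    def test_monotone_under_reference_union(self):
        rng = random.Random(7)
        universe = [f"G{i:02d}" for i in range(15)]
        for _ in range(20):
            clusters = {f"C{i}": frozenset(rng.sample(universe, rng.randint(1, 6))) for i in range(3)}
            refs = {f"R{i}": frozenset(rng.sample(universe, rng.randint(1, 6))) for i in range(3)}
            extra = dict(refs)
            extra["R_NEW"] = frozenset(rng.sample(universe, 5))
            for metric, fn in (("f", average_fscore), ("p", average_precision)):
                assert fn(clusters, extra) >= fn(clusters, refs) - 1e-12


class TestHomogeneity:
    def test_two_of_three(self):
        clusters = {
            "C1": frozenset({"a", "b"}),      # subset of R1 -> precision 1.0
            "C2": frozenset({"a", "x"}),      # best precision 0.5
            "C3": frozenset({"a", "b", "x"}), # best precision 2/3 >= 0.6
        }
        refs = {"R1": frozenset({"a", "b", "c"})}
        assert homogeneity_proportion(clusters, refs) == pytest.approx(200 / 3)

    def test_all_subsets(self):
        clusters = {"C1": frozenset({"a"}), "C2": frozenset({"b", "c"})}
        refs = {"R1": frozenset({"a", "b", "c"})}
        assert homogeneity_proportion(clusters, refs) == 100.0

    def test_zero_threshold(self):
        clusters = {"C1": frozenset({"x"})}
        refs = {"R1": frozenset({"a"})}
        assert homogeneity_proportion(clusters, refs, threshold=0.0) == 100.0

    def test_inclusive_boundary(self):
        clusters = {"C1": frozenset({"a", "b", "c", "d", "e"})}
        refs = {"R1": frozenset({"a", "b", "c"})}  # precision exactly 0.6
        assert homogeneity_proportion(clusters, refs, threshold=0.6) == 100.0


class TestOverlapStatistics:
    def test_single_shared_node(self):
        clusters = [{"a", "b", "c"}, {"c", "d"}, {"e", "f"}]
        nodes, n, pct = overlap_statistics(clusters)
        assert nodes == frozenset({"c"})
        assert n == 2
        assert pct == pytest.approx(200 / 3)

    def test_disjoint(self):
        assert overlap_statistics([{"a"}, {"b"}]) == (frozenset(), 0, 0.0)

    def test_identical_clusters(self):
        nodes, n, pct = overlap_statistics({"C1": {"a", "b"}, "C2": {"a", "b"}})
        assert nodes == frozenset({"a", "b"}) and n == 2 and pct == 100.0

    def test_order_invariant(self):
        rng = random.Random(1)
        cl = [set(rng.sample(range(10), rng.randint(1, 5))) for _ in range(6)]
        a = overlap_statistics(cl)
        rng.shuffle(cl)
        assert overlap_statistics(cl) == a

    def test_empty(self):
        assert overlap_statistics([]) == (frozenset(), 0, 0.0)


class TestNovelMembers:
    def test_single_extra_member_reported(self):
        refs = {"GO:X": frozenset(f"K{i}" for i in range(1, 8))}
        clusters = {"C1": frozenset(f"K{i}" for i in range(1, 9))}
        out = propose_novel_members(clusters, refs)
        assert len(out) == 1
        cid, ref, novel, f = out[0]
        assert (cid, ref, novel) == ("C1", "GO:X", frozenset({"K8"}))
        assert f == pytest.approx(14 / 15)

    def test_strict_threshold_boundary(self):
        # P = 9/11, R = 1 -> F = 0.9 exactly: not reported
        refs = {"R": frozenset(f"K{i}" for i in range(9))}
        clusters = {"C1": frozenset(list(f"K{i}" for i in range(9)) + ["X1", "X2"])}
        p, r, f = pair_scores(clusters["C1"], refs["R"])
        assert f == pytest.approx(0.9)
        assert propose_novel_members(clusters, refs, f_threshold=0.9) == []

    def test_subset_cluster_has_no_novel(self):
        refs = {"R": frozenset({"a", "b", "c"})}
        clusters = {"C1": frozenset({"a", "b", "c"})}
        assert propose_novel_members(clusters, refs) == []


class TestGmtIO:
    def test_round_trip_and_uppercase(self, tmp_path):
        p = tmp_path / "r.gmt"
        p.write_text("set1\tdesc\tabc\tdef\nset2\tdesc\tGHI\n")
        refs = read_gmt(p)
        assert refs == {"set1": frozenset({"ABC", "DEF"}), "set2": frozenset({"GHI"})}
        out = tmp_path / "w.gmt"
        write_gmt(refs, out)
        assert read_gmt(out) == refs

    def test_duplicate_name_rejected(self, tmp_path):
        p = tmp_path / "r.gmt"
        p.write_text("s\td\ta\ns\td\tb\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gmt(p)


class TestEvaluatePipeline:
    def test_perfect_clusters(self):
        g = make_graph([("A", "B"), ("C", "D")])
        clusters = {"C1": frozenset({"A", "B"}), "C2": frozenset({"C", "D"})}
        refs = {"R1": frozenset({"A", "B"}), "R2": frozenset({"C", "D"})}
        rep = evaluate(clusters, g, refs)
        assert rep.mean_f == 1.0 and rep.mean_p == 1.0
        assert rep.homogeneity_pct == 100.0
        assert rep.overlap_pct == 0.0

    def test_raises_when_nothing_scorable(self):
        g = make_graph([("A", "B")])
        with pytest.raises(ValueError):
            evaluate({"C1": frozenset({"A"})}, g, {"R": frozenset({"Z"})})
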