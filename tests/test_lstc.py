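"""Cutoff estimation, final single-linkage clustering, representatives."""

import random
from itertools import combinations

import pytest

from lstclust.coarse_cluster import Cluster
from lstclust.lstc import (
    ClusterThresholds,
    estimate_cutoffs,
    final_cluster,
    length_filter,
    select_representative,
    within_cluster_pairstats,
)
from lstclust.pairalign import PairStat, align_pair
from lstclust.seqio import Transcript
from oracles import mutate, nearest_rank_quantile, random_dna, union_find_components


def stat(a, b, identity, overlap=1.0):
    ia, ib = sorted((a, b))
    return PairStat(ia, ib, identity, overlap, 100, "+")


class TestWithinClusterPairstats:
    def _transcripts(self, rng, n, base_len=400):
        base = random_dna(rng, base_len)
        return {
            f"t{i}": Transcript(f"t{i}", "Locus_1", mutate(rng, base, rng.sample(range(base_len), 8)))
            for i in range(n)
        }

    def test_pair_count_bounded_by_combinations(self, rng):
        ts = self._transcripts(rng, 3)
        c = Cluster("T1", "tertiary", set(ts))
        stats = within_cluster_pairstats([c], ts)
        assert len(stats) == 3  # all pairs qualify here: C(3,2)

    def test_singletons_give_empty_list(self, rng):
        ts = self._transcripts(rng, 2)
        clusters = [
            Cluster("T1", "tertiary", {"t0"}),
            Cluster("T2", "tertiary", {"t1"}),
        ]
        assert within_cluster_pairstats(clusters, ts) == []

    def test_cross_cluster_pairs_excluded(self, rng):
        ts = self._transcripts(rng, 5)
        clusters = [
            Cluster("T1", "tertiary", {"t0", "t1"}),
            Cluster("T2", "tertiary", {"t2", "t3", "t4"}),
        ]
        stats = within_cluster_pairstats(clusters, ts)
        assert len(stats) <= 1 + 3
        within = {frozenset(["t0", "t1"])} | {
            frozenset(p) for p in combinations(["t2", "t3", "t4"], 2)
        }
        assert all(frozenset([s.id_a, s.id_b]) in within for s in stats)


class TestEstimateCutoffs:
    def test_all_identities_one(self):
        stats = [stat("a", f"b{i}", 1.0, 1.0) for i in range(10)]
        thr = estimate_cutoffs(stats)
        assert thr.min_identity == 1.0
        assert thr.min_overlap == 1.0
        assert thr.n_pairs_used == 10

    def test_matches_sort_and_index_oracle(self):
        rng = random.Random(7)
        idents = [0.90, 0.90] + [0.95 + 0.05 * rng.random() for _ in range(198)]
        overlaps = [0.4 + 0.6 * rng.random() for _ in range(200)]
        stats = [
            stat(f"a{i}", f"b{i}", idents[i], overlaps[i]) for i in range(200)
        ]
        thr = estimate_cutoffs(stats, 0.01)
        assert thr.min_identity == nearest_rank_quantile(idents, 0.01)
        assert thr.min_identity == 0.90  # ceil(0.01*200)=2nd smallest
        assert thr.min_overlap == nearest_rank_quantile(overlaps, 0.01)

    def test_tail_bound_holds(self):
        rng = random.Random(9)
        for n in (3, 17, 100, 999):
            idents = [rng.uniform(0.8, 1.0) for _ in range(n)]
            stats = [stat(f"a{i}", f"b{i}", idents[i]) for i in range(n)]
            thr = estimate_cutoffs(stats, 0.01)
            failing = sum(1 for v in idents if v < thr.min_identity) / n
            assert failing <= 0.01 + 1.0 / n

    def test_upper_mode_takes_right_tail(self):
        idents = [i / 100 for i in range(1, 101)]
        stats = [stat(f"a{i}", f"b{i}", v) for i, v in enumerate(idents)]
        thr = estimate_cutoffs(stats, 0.01, mode="upper")
        assert thr.min_identity == nearest_rank_quantile(idents, 0.99)

    def test_empty_stats_fatal_with_guidance(self):
        with pytest.raises(ValueError, match="manually"):
            estimate_cutoffs([])


class TestFinalCluster:
    def test_transitive_linkage(self):
        thr = ClusterThresholds(0.95, 0.65)
        stats = [stat("A", "B", 0.99, 0.9), stat("B", "C", 0.99, 0.9)]
        out = final_cluster(["A", "B", "C"], stats, thr)
        assert len(out) == 1
        assert out[0].members == {"A", "B", "C"}

    def test_no_edges_all_singletons(self):
        thr = ClusterThresholds(0.95, 0.65)
        out = final_cluster(["A", "B", "C", "D"], [], thr)
        assert len(out) == 4

    def test_edges_below_either_threshold_ignored(self):
        thr = ClusterThresholds(0.95, 0.65)
        stats = [stat("A", "B", 0.94, 0.9), stat("B", "C", 0.99, 0.6)]
        out = final_cluster(["A", "B", "C"], stats, thr)
        assert len(out) == 3

    def test_matches_union_find_oracle_on_random_instances(self):
        rng = random.Random(42)
        for trial in range(20):
            ids = [f"t{i:02d}" for i in range(30)]
            stats = []
            for a, b in combinations(ids, 2):
                if rng.random() < 0.08:
                    stats.append(stat(a, b, rng.uniform(0.9, 1.0), rng.uniform(0.4, 1.0)))
            thr = ClusterThresholds(0.95, 0.65)
            got = sorted(sorted(c.members) for c in final_cluster(ids, stats, thr))
            edges = [
                (s.id_a, s.id_b)
                for s in stats
                if s.identity >= 0.95 and s.overlap >= 0.65
            ]
            assert got == union_find_components(ids, edges)

    def test_monotonicity_in_thresholds(self):
        rng = random.Random(5)
        ids = [f"t{i}" for i in range(20)]
        stats = [
            stat(a, b, rng.uniform(0.85, 1.0), rng.uniform(0.3, 1.0))
            for a, b in combinations(ids, 2)
            if rng.random() < 0.3
        ]
        sizes = []
        for min_id in (0.0, 0.9, 0.95, 0.99, 1.01):
            thr = ClusterThresholds(min(min_id, 1.0), 0.5)
            if min_id > 1.0:
                stats_used = []  # identity can never reach above 1
                out = final_cluster(ids, stats_used, thr)
            else:
                out = final_cluster(ids, stats, thr)
            sizes.append(len(out))
        assert sizes == sorted(sizes)

    def test_flags_inherited_as_union(self):
        thr = ClusterThresholds(0.9, 0.5)
        out = final_cluster(
            ["A", "B"],
            [stat("A", "B", 0.99, 0.9)],
            thr,
            flags_by_transcript={"A": {"short"}, "B": {"contaminant"}},
        )
        assert out[0].flags == {"short", "contaminant"}

    def test_complete_linkage_requires_all_pairs(self):
        thr = ClusterThresholds(0.95, 0.65)
        stats = [stat("A", "B", 0.99, 0.9), stat("B", "C", 0.99, 0.9)]
        out = final_cluster(["A", "B", "C"], stats, thr, linkage="complete")
        assert sorted(sorted(c.members) for c in out) == [["A", "B"], ["C"]]


class TestLengthFilter:
    def test_boundary_strictly_below_350(self):
        c = Cluster("T1", "tertiary", {"s", "m"})
        main, short = length_filter([c], {"s": 349, "m": 350})
        assert short == {"s"}
        assert main[0].members == {"m"}

    def test_cluster_of_only_short_members_vanishes(self):
        c = Cluster("T1", "tertiary", {"a", "b"})
        main, short = length_filter([c], {"a": 100, "b": 200})
        assert main == []
        assert short == {"a", "b"}  # conserved, not lost


class TestSelectRepresentative:
    def test_highest_bitscore_wins(self):
        c = Cluster("L1", "final", {"t1", "t2"})
        rep = select_representative(c, {"t1": 200.0, "t2": 150.0}, {"t1": 500, "t2": 400})
        assert rep == "t1"

    def test_near_tie_prefers_shorter(self):
        c = Cluster("L1", "final", {"t1", "t2"})
        rep = select_representative(c, {"t1": 200.0, "t2": 199.0}, {"t1": 1200, "t2": 900})
        assert rep == "t2"

    def test_unannotated_takes_longest(self):
        c = Cluster("L1", "final", {"t1", "t2"})
        rep = select_representative(c, {"t1": None, "t2": None}, {"t1": 400, "t2": 500})
        assert rep == "t2"

    def test_mixed_annotation_prefers_annotated(self):
        c = Cluster("L1", "final", {"t1", "t2"})
        rep = select_representative(c, {"t1": 90.0, "t2": None}, {"t1": 300, "t2": 900})
        assert rep == "t1"


class TestEndToEndPartition:
    def test_partition_property_on_aligned_instance(self, rng):
        base = random_dna(rng, 500)
        ts = {}
        for i in range(8):
            nmut = rng.randint(0, 60)
            ts[f"t{i}"] = Transcript(
                f"t{i}", "Locus_1", mutate(rng, base, rng.sample(range(500), nmut))
            )
        stats = [
            s
            for a, b in combinations(sorted(ts), 2)
            if (s := align_pair(ts[a], ts[b])) is not None
        ]
        out = final_cluster(sorted(ts), stats, ClusterThresholds(0.95, 0.65))
        assert sorted(t for c in out for t in c.members) == sorted(ts)
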