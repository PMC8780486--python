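"""Discordant-pair filter, clustering and prioritization contracts."""

import numpy as np
import pytest

import cardiotrio as ct
from cardiotrio.discordant import (
    DiscordantFilterConfig,
    cluster_pairs,
    filter_discordant_pairs,
    implied_interval,
    prioritize_clusters,
)
from cardiotrio.model import GenomicInterval

from conftest import make_pair

DUP_SPAN = 68_048  # span of a published 68 kb pathogenic duplication


class TestFilter:
    @pytest.mark.parametrize(
        "mapq,tlen,kept",
        [
            (60, -DUP_SPAN, True),   # SV-scale template, unique mapping
            (60, 300, False),        # normal insert, below the window
            (59, 10_000, False),     # non-unique mapping quality
            (60, 2500, True),        # inclusive lower bound
            (60, 350_000, True),     # inclusive upper bound
            (60, 2499, False),
            (60, 350_001, False),
        ],
    )
    def test_predicate(self, mapq, tlen, kept):
        got = filter_discordant_pairs([make_pair(mapq=mapq, tlen=tlen)])
        assert bool(got) == kept

    def test_zero_tlen_excluded_and_tallied(self):
        stats = {}
        got = filter_discordant_pairs([make_pair(tlen=0)], stats=stats)
        assert got == [] and stats["skipped_zero_tlen"] == 1

    def test_one_record_per_template_prefers_leftmost(self):
        left = make_pair(read_id="t", pos=10_000, tlen=5000)
        right = make_pair(read_id="t", pos=14_900, tlen=-5000, is_first_in_pair=False)
        for order in ([left, right], [right, left]):
            got = filter_discordant_pairs(order)
            assert len(got) == 1 and got[0].tlen == 5000

    def test_idempotent_and_shuffle_invariant(self):
        rng = np.random.default_rng(0)
        pairs = [
            make_pair(
                read_id=f"r{i}",
                pos=int(rng.integers(1, 10**6)),
                mapq=int(rng.choice([60, 60, 60, 30])),
                tlen=int(rng.choice([300, 5000, -8000, 0, 400_000])),
            )
            for i in range(200)
        ]
        once = filter_discordant_pairs(pairs)
        assert filter_discordant_pairs(once) == once
        shuffled = list(pairs)
        rng.shuffle(shuffled)
        assert len(filter_discordant_pairs(shuffled)) == len(once)

    def test_widening_window_never_loses_pairs(self):
        rng = np.random.default_rng(1)
        pairs = [
            make_pair(read_id=f"r{i}", tlen=int(rng.integers(100, 500_000)))
            for i in range(300)
        ]
        kept = [
            len(filter_discordant_pairs(
                pairs, DiscordantFilterConfig(tlen_min=lo, tlen_max=hi)))
            for lo, hi in [(5000, 100_000), (2500, 200_000), (1000, 350_000), (500, 450_000)]
        ]
        assert kept == sorted(kept)


class TestImpliedInterval:
    def test_arithmetic(self):
        iv = implied_interval(make_pair(pos=10_001, tlen=5000))
        assert iv == GenomicInterval("chrS", 10_001, 15_000)

    def test_boundary_span_equals_tlen(self):
        iv = implied_interval(make_pair(pos=1, tlen=2500))
        assert iv.span == 2500

    def test_zero_tlen_is_contract_violation(self):
        with pytest.raises(ValueError):
            implied_interval(make_pair(tlen=0))

    def test_generator_pairs_land_on_truth(self, write_sam):
        truth = GenomicInterval("chrS", 300_000, 360_000)
        sam, manifest = ct.simulate_read_pairs(
            truth=[ct.CnvTruth(truth, "tandem_dup", 10)],
            n_background_pairs=0, decoy_fraction=0.0, seed=2,
        )
        rl = manifest["read_length"]
        recs = filter_discordant_pairs(ct.read_sam_pairs(write_sam(sam)))
        assert len(recs) == 10
        for r in recs:
            iv = implied_interval(r)
            assert abs(iv.start - truth.start) <= rl and abs(iv.end - truth.end) <= rl


def _pair_at(i, start, end, rf=False):
    return make_pair(
        read_id=f"c{i}",
        pos=start,
        tlen=end - start + 1,
        is_reverse=rf,
        mate_is_reverse=not rf,
    )


def brute_force_clusters(intervals, tolerance):
    """Independent oracle: transitive closure of the pairwise linkage
    predicate via boolean adjacency and scipy connected components."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n = len(intervals)
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            a, b = intervals[i], intervals[j]
            tol = tolerance * (a.span + b.span) / 2
            adj[i, j] = (
                a.chrom == b.chrom
                and abs(a.start - b.start) <= tol
                and abs(a.end - b.end) <= tol
            )
    _, labels = connected_components(csr_matrix(adj), directed=False)
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, set()).add(i)
    return {frozenset(g) for g in groups.values()}


class TestClustering:
    def test_identical_intervals_one_cluster(self):
        pairs = [_pair_at(0, 10_000, 20_000), _pair_at(1, 10_000, 20_000)]
        (c,) = cluster_pairs(pairs)
        assert c.support == 2
        assert c.interval == GenomicInterval("chrS", 10_000, 20_000)

    def test_offsets_within_tolerance_link(self):
        # mean span 10001, 5% ~ 500: offsets of 400 link
        pairs = [_pair_at(0, 10_000, 20_000), _pair_at(1, 10_400, 20_400)]
        assert len(cluster_pairs(pairs)) == 1

    def test_offsets_beyond_tolerance_split(self):
        # offsets of 1000 exceed 5% of the mean span
        pairs = [_pair_at(0, 10_000, 20_000), _pair_at(1, 11_000, 21_000)]
        assert len(cluster_pairs(pairs)) == 2

    def test_supports_sum_to_retained_count(self):
        rng = np.random.default_rng(3)
        pairs = []
        for i in range(150):
            start = int(rng.integers(1, 10**6))
            span = int(rng.integers(2500, 100_000))
            pairs.append(_pair_at(i, start, start + span - 1))
        clusters = cluster_pairs(pairs)
        assert sum(c.support for c in clusters) == len(pairs)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 200))
        pairs = []
        # mix of tight event clusters and scattered singletons
        for i in range(n):
            if rng.random() < 0.5:
                base = int(rng.choice([50_000, 300_000, 700_000]))
                span = int(rng.choice([8000, 40_000]))
                jitter_s = int(rng.integers(-200, 201))
                jitter_e = int(rng.integers(-200, 201))
                pairs.append(_pair_at(i, base + jitter_s, base + span + jitter_e))
            else:
                start = int(rng.integers(1, 10**6))
                pairs.append(_pair_at(i, start, start + int(rng.integers(2500, 80_000))))
        config = DiscordantFilterConfig()
        got = cluster_pairs(pairs, config)
        got_sets = {
            frozenset(int(m[1:]) for m in c.member_ids) for c in got
        }
        intervals = [implied_interval(p) for p in pairs]
        expected = brute_force_clusters(intervals, config.cluster_tolerance)
        assert got_sets == expected


class TestPrioritize:
    @staticmethod
    def _cluster(support, start=10_000, span=10_000, rf=0, fr=0, other=0):
        ids = tuple(f"m{i}" for i in range(support))
        profile = {"RF": rf, "FR": fr, "other": other}
        if rf + fr + other == 0:
            profile["FR"] = support
        return ct.DiscordantCluster(
            interval=GenomicInterval("chrS", start, start + span - 1),
            member_ids=ids,
            orientation_profile=profile,
        )

    def test_threshold_and_ranking(self):
        clusters = [self._cluster(5), self._cluster(2, start=50_000),
                    self._cluster(9, start=90_000)]
        calls = prioritize_clusters(clusters, DiscordantFilterConfig(min_support=3))
        assert [c.support for c in calls] == [9, 5]
        assert [c.rank for c in calls] == [1, 2]

    def test_all_singletons_yield_no_calls(self):
        clusters = [self._cluster(1, start=s) for s in (10_000, 50_000, 90_000)]
        assert prioritize_clusters(clusters, DiscordantFilterConfig(min_support=3)) == []

    def test_sv_type_from_orientation(self):
        dup = self._cluster(4, rf=4)
        dele = self._cluster(4, start=200_000, fr=4)
        tie = self._cluster(4, start=400_000, rf=2, fr=2)
        calls = prioritize_clusters([dup, dele, tie])
        types = {c.interval.start: c.sv_type for c in calls}
        assert types == {10_000: "dup", 200_000: "del", 400_000: "unknown"}

    def test_raising_min_support_never_adds_calls(self):
        rng = np.random.default_rng(5)
        clusters = [
            self._cluster(int(rng.integers(1, 12)), start=10_000 + 30_000 * i)
            for i in range(20)
        ]
        counts = [
            len(prioritize_clusters(clusters, DiscordantFilterConfig(min_support=ms)))
            for ms in range(1, 10)
        ]
        assert counts == sorted(counts, reverse=True)


class TestEndToEnd:
    def test_single_dup_called_top_ranked(self, write_sam):
        truth = GenomicInterval("chrS", 500_000, 500_000 + DUP_SPAN - 1)
        sam, _ = ct.simulate_read_pairs(
            truth=[ct.CnvTruth(truth, "tandem_dup", 6)],
            n_background_pairs=5000, seed=1,
        )
        calls = ct.call_cnv_discordant(write_sam(sam))
        assert len(calls) == 1
        call = calls[0]
        assert call.sv_type == "dup" and call.rank == 1
        assert call.interval.reciprocal_overlap(truth) >= 0.95

    def test_proper_pairs_only_yield_nothing(self, write_sam):
        sam, _ = ct.simulate_read_pairs(truth=[], n_background_pairs=2000,
                                        decoy_fraction=0.0, seed=6)
        assert ct.call_cnv_discordant(write_sam(sam)) == []

    def test_low_mapq_decoys_are_ignored(self, write_sam):
        sam, _ = ct.simulate_read_pairs(truth=[], n_background_pairs=2000,
                                        decoy_fraction=0.05, seed=8)
        assert ct.call_cnv_discordant(write_sam(sam)) == []

    def test_two_distant_events_stay_separate(self, write_sam):
        t1 = GenomicInterval("chrS", 200_000, 240_000)
        t2 = GenomicInterval("chrS", 740_000, 780_000)  # 500 kb away
        sam, _ = ct.simulate_read_pairs(
            truth=[ct.CnvTruth(t1, "deletion", 5), ct.CnvTruth(t2, "tandem_dup", 5)],
            n_background_pairs=3000, seed=9,
        )
        calls = ct.call_cnv_discordant(write_sam(sam))
        assert len(calls) == 2
        hit1 = any(c.interval.reciprocal_overlap(t1) >= 0.95 and c.sv_type == "del"
                   for c in calls)
        hit2 = any(c.interval.reciprocal_overlap(t2) >= 0.95 and c.sv_type == "dup"
                   for c in calls)
        assert hit1 and hit2
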