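"""Detector: insert stats, pair classification, clustering, scoring, filters."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svrecon.core import (
    HEAD,
    TAIL,
    Breakend,
    EstimationError,
    FilterParams,
    InsertStats,
    Interval,
    JunctionCall,
    PairRecord,
    ParameterError,
)
from svrecon.detection import (
    REASON_MAX_STRAND,
    REASON_MIN_SCORE,
    REASON_MIN_SUPPORT,
    REASON_TRACKS,
    classify_pair,
    cluster_discordant,
    estimate_insert_stats,
    filter_calls,
    score_cluster,
)

from conftest import breakend_pair_set, make_pair_table


def _fr_rows(inserts, chrom="chrA", start=10_000, read_len=100, mapq=60):
    rows = []
    for i, ins in enumerate(inserts):
        pos = start + 17 * i
        rows.append((chrom, pos, "+", chrom, pos + ins - read_len, "-", mapq))
    return rows


class TestInsertStats:
    def test_constant_insert_308(self):
        pairs = make_pair_table(_fr_rows([308] * 120))
        stats = estimate_insert_stats(pairs)
        assert stats.median == 308 and stats.mean == 308 and stats.sd == 0

    def test_median_of_three_point_distribution(self):
        pairs = make_pair_table(_fr_rows([300, 308, 316] * 40))
        assert estimate_insert_stats(pairs).median == 308

    def test_all_inter_chromosomal_raises(self):
        rows = [("chrA", 100 + i, "+", "chrB", 200 + i, "-", 60) for i in range(150)]
        with pytest.raises(EstimationError):
            estimate_insert_stats(make_pair_table(rows))

    def test_envelope_is_mean_plus_k_sd(self):
        pairs = make_pair_table(_fr_rows([300, 316] * 60))
        stats = estimate_insert_stats(pairs, k=2.0)
        assert stats.concordant_max_span == pytest.approx(stats.mean + 2 * stats.sd)


class TestClassifyPair:
    STATS = InsertStats(median=308, mean=308, sd=30, concordant_max_span=400)

    def _pair(self, chrom, pos, strand, mchrom, mpos, mstrand):
        return PairRecord("r", chrom, pos, strand, mchrom, mpos, mstrand, 60)

    @pytest.mark.parametrize(
        "pair_args, expected",
        [
            (("chr14", 100, "+", "chr18", 200, "-"), "inter_chromosomal"),
            (("chr14", 100, "+", "chr14", 900, "+"), "inversion_like"),
            (("chr14", 100, "-", "chr14", 900, "-"), "inversion_like"),
            # FR with outer span 210 + 100 = 310 <= 400
            (("chr14", 100, "+", "chr14", 310, "-"), "concordant"),
            (("chr14", 100, "+", "chr14", 900, "-"), "deletion_like"),
            (("chr14", 100, "-", "chr14", 900, "+"), "duplication_like"),
        ],
    )
    def test_classes(self, pair_args, expected):
        assert classify_pair(self._pair(*pair_args), self.STATS) == expected


class TestClustering:
    STATS = InsertStats(median=308, mean=308, sd=30, concordant_max_span=400)

    def test_thirty_pair_cluster_single_origin(self):
        rows = [
            ("chr14", 65_191_300 + 7 * i, "+", "chr18", 53_199_700 + 9 * i, "-", 60)
            for i in range(30)
        ]
        calls = cluster_discordant(make_pair_table(rows), self.STATS)
        assert len(calls) == 1
        assert calls[0].support == 30
        assert calls[0].svclass == "inter_chromosomal"

    def test_lone_pair_yields_no_call(self):
        rows = [("chr14", 100, "+", "chr18", 200, "-", 60)]
        assert cluster_discordant(make_pair_table(rows), self.STATS) == []

    def test_low_mapq_pairs_excluded(self):
        rows = [
            ("chr14", 1_000 + 5 * i, "+", "chr18", 2_000 + 5 * i, "-", 10)
            for i in range(30)
        ]
        assert cluster_discordant(make_pair_table(rows), self.STATS, min_mapq=35) == []

    def test_split_signal_two_loci_on_chr18(self):
        # two junctions 0.98 Mb apart split a 30-pair signal 14 / 16
        rows = [
            ("chr18", 52_256_300 + 6 * i, "-", "chr14", 65_191_700 + 5 * i, "-", 60)
            for i in range(14)
        ] + [
            ("chr18", 53_199_700 + 6 * i, "+", "chr14", 65_191_200 + 5 * i, "+", 60)
            for i in range(16)
        ]
        calls = cluster_discordant(make_pair_table(rows), self.STATS)
        assert sorted(c.support for c in calls) == [14, 16]

    def test_breakend_is_innermost_coordinate(self):
        read_len = 100
        rows = [
            ("chrA", 900 + i, "+", "chrB", 5_000 - i, "-", 60) for i in range(5)
        ] * 2
        calls = cluster_discordant(
            make_pair_table(rows), self.STATS, read_len=read_len
        )
        (call,) = calls
        assert call.breakend_1 == Breakend("chrA", 904 + read_len - 1, HEAD)
        assert call.breakend_2 == Breakend("chrB", 4_996, TAIL)


def _poisson_tail_bruteforce(k: int, mu: float) -> float:
    # oracle: P[X >= k] by direct summation of the Poisson pmf
    p_lt = sum(math.exp(-mu) * mu**i / math.factorial(i) for i in range(k))
    return 1.0 - p_lt


class TestScoring:
    def test_zero_support_scores_zero(self):
        assert score_cluster(0, background_rate=0.1) == 0

    def test_support_30_rate_point1_caps_at_99(self):
        assert _poisson_tail_bruteforce(30, 0.1) < 1e-10
        assert score_cluster(30, 0.1) == 99

    def test_support_2_rate_2_matches_bruteforce(self):
        expected = round(-10 * math.log10(_poisson_tail_bruteforce(2, 2.0)))
        assert score_cluster(2, 2.0) == expected == 2

    def test_monotone_in_support(self):
        scores = [score_cluster(s, 0.5) for s in range(1, 101)]
        assert scores == sorted(scores)

    def test_rate_must_be_positive(self):
        with pytest.raises(ParameterError):
            score_cluster(5, 0.0)


def _call(support=30, plus1=None, score=99, pos1=10_000, pos2=20_000, cid="c1"):
    plus1 = support if plus1 is None else plus1
    return JunctionCall(
        breakend_1=Breakend("chrA", pos1, HEAD),
        breakend_2=Breakend("chrB", pos2, TAIL),
        svclass="inter_chromosomal",
        support=support,
        plus_reads_1=plus1,
        minus_reads_1=support - plus1,
        plus_reads_2=0,
        minus_reads_2=support,
        score=score,
        call_id=cid,
    )


EMPTY_TRACKS = {"dgv": [], "segdup": [], "depth": []}


class TestFilterCascade:
    def test_support_11_rejected_min_support(self):
        retained, rejected = filter_calls([_call(support=11)], EMPTY_TRACKS)
        assert retained == [] and rejected[0][1] == REASON_MIN_SUPPORT

    def test_strand_count_61_rejected(self):
        call = _call(support=61, plus1=61)
        retained, rejected = filter_calls([call], EMPTY_TRACKS)
        assert rejected[0][1] == REASON_MAX_STRAND

    def test_score_98_rejected(self):
        retained, rejected = filter_calls([_call(score=98)], EMPTY_TRACKS)
        assert rejected[0][1] == REASON_MIN_SCORE

    def test_breakend_exactly_500bp_from_track_rejected(self):
        tracks = {"segdup": [Interval("chrA", 10_500, 10_900)], "b": [], "c": []}
        retained, rejected = filter_calls([_call(pos1=10_000)], tracks)
        assert rejected[0][1] == REASON_TRACKS

    def test_breakend_501bp_from_track_retained(self):
        tracks = {"segdup": [Interval("chrA", 10_501, 10_900)], "b": [], "c": []}
        retained, rejected = filter_calls([_call(pos1=10_000)], tracks)
        assert len(retained) == 1

    def test_clean_call_retained(self):
        tracks = {"segdup": [Interval("chrA", 50_000, 51_000)], "b": [], "c": []}
        retained, rejected = filter_calls([_call()], tracks)
        assert len(retained) == 1 and rejected == []

    def test_first_matching_reason_wins(self):
        # violates support, strand cap and score at once; support is reported
        call = _call(support=11, score=0)
        _, rejected = filter_calls([call], EMPTY_TRACKS)
        assert rejected[0][1] == REASON_MIN_SUPPORT

    @given(st.randoms(use_true_random=False))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_partition_and_order_independence(self, rnd):
        calls = [
            _call(support=11, cid="a"),
            _call(score=98, cid="b"),
            _call(cid="c"),
            _call(support=61, plus1=61, cid="d"),
            _call(pos1=10_000, cid="e"),
        ]
        tracks = {"t": [Interval("chrA", 10_400, 10_600)], "u": [], "v": []}
        baseline_r, baseline_x = filter_calls(calls, tracks)
        base = (
            {c.call_id for c in baseline_r},
            {(c.call_id, reason) for c, reason in baseline_x},
        )
        shuffled = list(calls)
        rnd.shuffle(shuffled)
        retained, rejected = filter_calls(shuffled, tracks)
        assert {c.call_id for c in retained} == base[0]
        assert {(c.call_id, r) for c, r in rejected} == base[1]
        assert len(retained) + len(rejected) == len(calls)


class TestEndToEndDetection:
    def test_exactly_three_truth_junctions_retained(
        self, scored_calls_30x, derived_truth
    ):
        _, truth = derived_truth
        retained, rejected = filter_calls(scored_calls_30x, EMPTY_TRACKS)
        assert len(retained) == 3
        # each retained call sits within one insert length of a truth junction
        for call in retained:
            got = breakend_pair_set(call)
            best = min(
                max(
                    min(
                        (
                            abs(p1 - p2)
                            for (c2, p2, _) in breakend_pair_set(tj)
                            if c1 == c2
                        ),
                        default=float("inf"),
                    )
                    for (c1, p1, _) in got
                )
                for tj in truth.junctions
            )
            assert best <= 338

    def test_track_near_junction_rejects_call(
        self, scored_calls_30x, derived_truth, demo_spec
    ):
        bp = demo_spec.translocation.break_a
        tracks = {
            "dgv": [Interval("chrA", bp + 400, bp + 450)],
            "segdup": [],
            "depth": [],
        }
        retained, rejected = filter_calls(scored_calls_30x, tracks)
        # both inter-chromosomal junctions carry a chrA breakend near break_a,
        # so the track window removes both; only the inversion junction stays
        assert len(retained) == 1
        assert retained[0].svclass == "inversion_like"
        assert sum(r == REASON_TRACKS for _, r in rejected) == 2
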