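"""Discordant-pair structural-variant detection.

The detector follows the classic read-pair paradigm: estimate the concordant
insert-size envelope, classify every pair by mate chromosome / orientation /
span, cluster discordant pairs of the same signature by single linkage,
assign each cluster a Poisson-tail phred score capped at 99, and apply a
stringent filter cascade (support, per-strand read caps, score, and a
+/-500 bp exclusion window around annotated repetitive/high-depth tracks).
"""

from __future__ import annotations

from bisect import bisect_left
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    CONCORDANT,
    DELETION_LIKE,
    DUPLICATION_LIKE,
    HEAD,
    INTER_CHROMOSOMAL,
    INVERSION_LIKE,
    TAIL,
    Breakend,
    EstimationError,
    FilterParams,
    InsertStats,
    Interval,
    JunctionCall,
    PairRecord,
    ParameterError,
    chrom_sort_key,
)

# ---------------------------------------------------------------------------
# Insert statistics
# ---------------------------------------------------------------------------


def estimate_insert_stats(
    pairs: pd.DataFrame,
    k: float = 3.0,
    read_len: int = 100,
    min_pairs: int = 100,
) -> InsertStats:
    """Estimate the insert distribution from same-chromosome FR pairs.

    The span of an FR pair is measured outer-edge to outer-edge
    (``mate_pos - pos + read_len`` with the plus-strand read leftmost), which
    equals the fragment length for concordant pairs.  The concordant envelope
    is ``mean + k * sd``.
    """
    if k <= 0:
        raise ParameterError("k must be positive")
    same = pairs[pairs["chrom"] == pairs["mate_chrom"]]
    lo = np.minimum(same["pos"], same["mate_pos"])
    hi = np.maximum(same["pos"], same["mate_pos"])
    left_strand = np.where(same["pos"] <= same["mate_pos"], same["strand"], same["mate_strand"])
    right_strand = np.where(same["pos"] <= same["mate_pos"], same["mate_strand"], same["strand"])
    fr = same[(left_strand == "+") & (right_strand == "-")]
    spans = (hi - lo + read_len)[fr.index].to_numpy(dtype=float)
    if len(spans) < min_pairs:
        raise EstimationError(
            f"need >= {min_pairs} same-chromosome FR pairs, found {len(spans)}"
        )
    mean = float(spans.mean())
    sd = float(spans.std(ddof=0))
    return InsertStats(
        median=float(np.median(spans)),
        mean=mean,
        sd=sd,
        concordant_max_span=mean + k * sd,
    )


# ---------------------------------------------------------------------------
# Pair classification
# ---------------------------------------------------------------------------


def classify_pair(pair: PairRecord, stats_: InsertStats, read_len: int = 100) -> str:
    """Evidence class of one pair (total function, never raises).

    Inter-chromosomal if the mates map to different chromosomes; otherwise FR
    pairs within the concordant envelope are concordant, FR beyond it
    deletion-like, same-strand pairs inversion-like and RF pairs
    duplication-like.
    """
    if pair.chrom != pair.mate_chrom:
        return INTER_CHROMOSOMAL
    if pair.pos <= pair.mate_pos:
        left_strand, right_strand = pair.strand, pair.mate_strand
        span = pair.mate_pos - pair.pos + read_len
    else:
        left_strand, right_strand = pair.mate_strand, pair.strand
        span = pair.pos - pair.mate_pos + read_len
    if left_strand == right_strand:
        return INVERSION_LIKE
    if left_strand == "-":  # RF
        return DUPLICATION_LIKE
    return CONCORDANT if span <= stats_.concordant_max_span else DELETION_LIKE


def classify_pairs(
    pairs: pd.DataFrame, stats_: InsertStats, read_len: int = 100
) -> pd.Series:
    """Vectorised :func:`classify_pair` over a pair table."""
    same = (pairs["chrom"] == pairs["mate_chrom"]).to_numpy()
    first_left = (pairs["pos"] <= pairs["mate_pos"]).to_numpy()
    strand = pairs["strand"].to_numpy()
    mstrand = pairs["mate_strand"].to_numpy()
    left_strand = np.where(first_left, strand, mstrand)
    right_strand = np.where(first_left, mstrand, strand)
    span = (
        np.abs(pairs["mate_pos"].to_numpy() - pairs["pos"].to_numpy()) + read_len
    )
    out = np.full(len(pairs), CONCORDANT, dtype=object)
    out[~same] = INTER_CHROMOSOMAL
    inv = same & (left_strand == right_strand)
    out[inv] = INVERSION_LIKE
    dup = same & ~inv & (left_strand == "-")
    out[dup] = DUPLICATION_LIKE
    dele = same & ~inv & ~dup & (span > stats_.concordant_max_span)
    out[dele] = DELETION_LIKE
    return pd.Series(out, index=pairs.index, name="svclass")


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def _canonical_ends(pairs: pd.DataFrame) -> pd.DataFrame:
    """Order each pair's two ends lexicographically by (chrom, pos)."""
    key1 = [chrom_sort_key(c) for c in pairs["chrom"]]
    key2 = [chrom_sort_key(c) for c in pairs["mate_chrom"]]
    first = np.array(
        [
            (k1, p1) <= (k2, p2)
            for k1, p1, k2, p2 in zip(key1, pairs["pos"], key2, pairs["mate_pos"])
        ]
    )
    out = pd.DataFrame(
        {
            "chrom1": np.where(first, pairs["chrom"], pairs["mate_chrom"]),
            "pos1": np.where(first, pairs["pos"], pairs["mate_pos"]),
            "strand1": np.where(first, pairs["strand"], pairs["mate_strand"]),
            "chrom2": np.where(first, pairs["mate_chrom"], pairs["chrom"]),
            "pos2": np.where(first, pairs["mate_pos"], pairs["pos"]),
            "strand2": np.where(first, pairs["mate_strand"], pairs["strand"]),
            "mapq": pairs["mapq"].to_numpy(),
        },
        index=pairs.index,
    )
    return out


def _breakend(chrom: str, positions: np.ndarray, strand: str, read_len: int) -> Breakend:
    """Innermost coordinate of a breakend cluster.

    Plus-strand evidence points rightward at the junction, so the innermost
    aligned base is the rightmost read end; minus-strand evidence points
    leftward, so it is the leftmost read start.
    """
    if strand == "+":
        return Breakend(chrom, int(positions.max()) + read_len - 1, HEAD)
    return Breakend(chrom, int(positions.min()), TAIL)


def cluster_discordant(
    pairs: pd.DataFrame,
    stats_: InsertStats,
    max_intra_cluster_gap: float | None = None,
    min_mapq: int = 35,
    min_reads_call: int = 2,
    read_len: int = 100,
) -> list[JunctionCall]:
    """Cluster discordant pairs into unscored junction calls.

    Pairs below ``min_mapq`` are discarded first; remaining discordant pairs
    are grouped by (class, chromosome pair, strand pair) and single-linkage
    clustered with a gap of at most ``max_intra_cluster_gap`` (default: the
    concordant envelope) required at both breakends.  Clusters smaller than
    ``min_reads_call`` are dropped.  The call breakend is the innermost
    aligned coordinate of the cluster.
    """
    if max_intra_cluster_gap is None:
        max_intra_cluster_gap = stats_.concordant_max_span
    if pairs.empty:
        return []
    usable = pairs[pairs["mapq"] >= min_mapq]
    if usable.empty:
        return []
    svclass = classify_pairs(usable, stats_, read_len)
    disc = usable[svclass != CONCORDANT]
    if disc.empty:
        return []
    ends = _canonical_ends(disc)
    ends["svclass"] = classify_pairs(disc, stats_, read_len).to_numpy()

    calls: list[JunctionCall] = []
    group_cols = ["svclass", "chrom1", "chrom2", "strand1", "strand2"]
    for key, grp in ends.groupby(group_cols, sort=True):
        svclass_, chrom1, chrom2, strand1, strand2 = key
        grp = grp.sort_values(["pos1", "pos2"]).reset_index(drop=True)
        p1 = grp["pos1"].to_numpy()
        p2 = grp["pos2"].to_numpy()
        n = len(grp)
        uf = _UnionFind(n)
        for i in range(n):
            j = i - 1
            # pos1-sorted: only neighbours within the gap can link
            while j >= 0 and p1[i] - p1[j] <= max_intra_cluster_gap:
                if abs(p2[i] - p2[j]) <= max_intra_cluster_gap:
                    uf.union(i, j)
                j -= 1
        members: dict[int, list[int]] = {}
        for i in range(n):
            members.setdefault(uf.find(i), []).append(i)
        for idxs in members.values():
            if len(idxs) < min_reads_call:
                continue
            sub1 = p1[idxs]
            sub2 = p2[idxs]
            be1 = _breakend(chrom1, sub1, strand1, read_len)
            be2 = _breakend(chrom2, sub2, strand2, read_len)
            support = len(idxs)
            calls.append(
                JunctionCall(
                    breakend_1=be1,
                    breakend_2=be2,
                    svclass=svclass_,
                    support=support,
                    plus_reads_1=support if strand1 == "+" else 0,
                    minus_reads_1=support if strand1 == "-" else 0,
                    plus_reads_2=support if strand2 == "+" else 0,
                    minus_reads_2=support if strand2 == "-" else 0,
                )
            )
    calls.sort(
        key=lambda c: (chrom_sort_key(c.breakend_1.chrom), c.breakend_1.pos)
    )
    for i, call in enumerate(calls, start=1):
        call.call_id = f"jc_{i}"
    return calls


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def score_cluster(call: JunctionCall | int, background_rate: float) -> int:
    """Poisson-tail phred score capped at 99.

    ``score = min(99, round(-10 * log10 P[X >= support]))`` with
    X ~ Poisson(background_rate), the expected number of spurious discordant
    pairs per clustering window.  Monotone non-decreasing in support; a
    support of zero scores zero.
    """
    if background_rate <= 0:
        raise ParameterError("background_rate must be positive")
    support = call if isinstance(call, int) else call.support
    if support <= 0:
        return 0
    tail = stats.poisson.sf(support - 1, background_rate)  # P[X >= support]
    if tail <= 0:
        return 99
    return min(99, int(round(-10.0 * np.log10(tail))))


def score_calls(calls: Iterable[JunctionCall], background_rate: float) -> None:
    """Assign scores in place."""
    for call in calls:
        call.score = score_cluster(call, background_rate)


# ---------------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------------

REASON_MIN_SUPPORT = "min_support"
REASON_MAX_STRAND = "max_strand_reads"
REASON_MIN_SCORE = "min_score"
REASON_TRACKS = "tracks"


def _near_track(
    chrom: str, pos: int, track: Sequence[Interval], window: int
) -> bool:
    """True if pos falls within +/-window bp (inclusive) of any interval,
    i.e. the (2*window + 1) bp window centered on pos touches annotation.

    Assumes the track is sorted and merged (documented precondition), so only
    the interval with the largest start <= pos + window can overlap.
    """
    spans = sorted((iv.start, iv.end) for iv in track if iv.chrom == chrom)
    i = bisect_left(spans, (pos + window + 1,)) - 1
    return i >= 0 and spans[i][1] >= pos - window


def filter_calls(
    calls: Sequence[JunctionCall],
    tracks: dict[str, Sequence[Interval]] | Sequence[Sequence[Interval]],
    params: FilterParams = FilterParams(),
) -> tuple[list[JunctionCall], list[tuple[JunctionCall, str]]]:
    """Apply the filter cascade; return (retained, rejected-with-reason).

    A call is rejected with the first matching reason, checked in the fixed
    order: support below ``min_support``; any per-breakend strand count above
    ``max_strand_reads``; score below ``min_score``; either breakend within
    ``track_window_bp`` (inclusive) of any annotated interval — for a
    translocation breakend this is exactly the 1001 bp window centered on it.
    Retained and rejected partition the input and the decision for each call
    is independent of input order.
    """
    track_list = list(tracks.values()) if isinstance(tracks, dict) else list(tracks)
    retained: list[JunctionCall] = []
    rejected: list[tuple[JunctionCall, str]] = []
    for call in calls:
        reason = None
        if call.support < params.min_support:
            reason = REASON_MIN_SUPPORT
        elif (
            max(
                call.plus_reads_1,
                call.minus_reads_1,
                call.plus_reads_2,
                call.minus_reads_2,
            )
            > params.max_strand_reads
        ):
            reason = REASON_MAX_STRAND
        elif call.score < params.min_score:
            reason = REASON_MIN_SCORE
        else:
            for track in track_list:
                for be in (call.breakend_1, call.breakend_2):
                    if _near_track(be.chrom, be.pos, track, params.track_window_bp):
                        reason = REASON_TRACKS
                        break
                if reason:
                    break
        if reason is None:
            retained.append(call)
        else:
            rejected.append((call, reason))
    return retained, rejected
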