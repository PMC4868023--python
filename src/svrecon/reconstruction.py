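"""Breakpoint-graph reconstruction of derivative chromosomes.

Filtered junction calls cut the reference chromosomes into oriented
segments; novel adjacencies join segment ends.  Derivatives are assembled by
walking from each pter-bearing segment, alternating reference segments and
novel edges until a qter end is reached.  Interior segments untouched by any
novel edge are the breakpoint-flanking deletions.  The module also renders
karyotype strings in ISCN style and extracts junction-spanning sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio.Seq import reverse_complement

from .core import (
    HEAD,
    TAIL,
    AmbiguityError,
    BandMap,
    Breakend,
    DerivativeChromosome,
    Interval,
    JunctionCall,
    ParameterError,
    ReconstructionError,
    Segment,
    SegmentAdjacency,
    chrom_display,
    chrom_sort_key,
)

# An end key is (chrom, segment_index, side) with side "L" (start) or "R" (end).
EndKey = tuple[str, int, str]


@dataclass
class BreakpointGraph:
    """Reference chromosomes cut at breakends, plus novel adjacencies."""

    chrom_lengths: dict[str, int]
    segments: dict[str, list[Segment]]
    edges: dict[EndKey, tuple[EndKey, str]]
    absent: list[Interval] = field(default_factory=list)


def _merge_cuts(points: list[int], slop: int) -> dict[int, int]:
    """Single-linkage merge of cut positions closer than ``slop``; each cut
    maps to its cluster's representative (the rounded cluster mean)."""
    mapping: dict[int, int] = {}
    cluster: list[int] = []
    for p in sorted(set(points)):
        if cluster and p - cluster[-1] > slop:
            rep = int(round(sum(cluster) / len(cluster)))
            mapping.update({c: rep for c in cluster})
            cluster = []
        cluster.append(p)
    if cluster:
        rep = int(round(sum(cluster) / len(cluster)))
        mapping.update({c: rep for c in cluster})
    return mapping


def _end_key_for_breakend(
    segments: dict[str, list[Segment]], be: Breakend, cut_map: dict[str, dict[int, int]]
) -> EndKey:
    cut = cut_map[be.chrom][be.pos if be.orientation == HEAD else be.pos - 1]
    for idx, seg in enumerate(segments[be.chrom]):
        if be.orientation == HEAD and seg.end == cut:
            return (be.chrom, idx, "R")
        if be.orientation == TAIL and seg.start == cut + 1:
            return (be.chrom, idx, "L")
    raise ReconstructionError(f"breakend {be} does not align with any segment cut")


def build_breakpoint_graph(
    junctions: list[JunctionCall],
    chrom_lengths: dict[str, int],
    merge_slop: int = 0,
) -> BreakpointGraph:
    """Cut the reference at every breakend and wire the novel adjacencies.

    A HEAD breakend at pos cuts after pos (junction uses [..pos]); a TAIL
    breakend at pos cuts after pos-1.  Interior segments with no novel edge at
    either end are marked absent (deleted).  Two junctions claiming the same
    segment end raise :class:`AmbiguityError`.

    ``merge_slop`` reconciles imprecise breakpoints estimated from read
    clusters: cuts closer than the slop (use about one insert length) are
    merged into a single cut, so a small breakpoint-flanking deletion whose
    two estimated cuts jitter across each other still yields a coherent
    topology.  Truth junctions with exact coordinates need no slop.
    """
    cuts: dict[str, set[int]] = {c: set() for c in chrom_lengths}
    for call in junctions:
        for be in (call.breakend_1, call.breakend_2):
            if be.chrom not in chrom_lengths:
                raise ParameterError(f"breakend on unknown chromosome {be.chrom!r}")
            if not 1 <= be.pos <= chrom_lengths[be.chrom]:
                raise ParameterError(f"breakend {be} outside chromosome bounds")
            cuts[be.chrom].add(be.pos if be.orientation == HEAD else be.pos - 1)

    cut_map: dict[str, dict[int, int]] = {
        chrom: _merge_cuts(list(points), merge_slop) for chrom, points in cuts.items()
    }
    segments: dict[str, list[Segment]] = {}
    for chrom, length in chrom_lengths.items():
        points = sorted(
            {p for p in cut_map[chrom].values() if 0 < p < length}
        )
        bounds = [0] + points + [length]
        segments[chrom] = [
            Segment(chrom, lo + 1, hi, "+") for lo, hi in zip(bounds, bounds[1:])
        ]

    edges: dict[EndKey, tuple[EndKey, str]] = {}
    for call in junctions:
        k1 = _end_key_for_breakend(segments, call.breakend_1, cut_map)
        k2 = _end_key_for_breakend(segments, call.breakend_2, cut_map)
        for k in (k1, k2):
            if k in edges:
                raise AmbiguityError(
                    f"segment end {k} is claimed by two junctions "
                    f"({edges[k][1]} and {call.call_id})"
                )
        edges[k1] = (k2, call.call_id)
        edges[k2] = (k1, call.call_id)

    absent = []
    for chrom, segs in segments.items():
        for idx, seg in enumerate(segs):
            interior = 0 < idx < len(segs) - 1
            touched = (chrom, idx, "L") in edges or (chrom, idx, "R") in edges
            if interior and not touched:
                absent.append(Interval(chrom, seg.start, seg.end))
    return BreakpointGraph(dict(chrom_lengths), segments, edges, absent)


def _breakend_of_end(graph: BreakpointGraph, key: EndKey) -> Breakend:
    chrom, idx, side = key
    seg = graph.segments[chrom][idx]
    return (
        Breakend(chrom, seg.end, HEAD) if side == "R" else Breakend(chrom, seg.start, TAIL)
    )


def assemble_derivatives(graph: BreakpointGraph) -> list[DerivativeChromosome]:
    """Walk from each pter segment to a qter end, alternating reference
    segments and novel edges.

    Each reference segment is used at most once; a walk revisiting a segment
    raises :class:`ReconstructionError`, and a walk ending on a free interior
    end emits an incomplete-derivative warning.  A chromosome untouched by
    any junction is returned unchanged under its own name.
    """
    used: set[tuple[str, int]] = set()
    derivatives: list[DerivativeChromosome] = []

    for chrom in sorted(graph.chrom_lengths, key=chrom_sort_key):
        if (chrom, 0) in used:
            continue
        segs_out: list[Segment] = []
        adjacencies: list[SegmentAdjacency] = []
        idx, sign = 0, "+"
        cur_chrom = chrom
        while True:
            if (cur_chrom, idx) in used:
                raise ReconstructionError(
                    f"cyclic walk revisits segment {cur_chrom}:{idx}"
                )
            used.add((cur_chrom, idx))
            seg = graph.segments[cur_chrom][idx]
            segs_out.append(Segment(seg.chrom, seg.start, seg.end, sign))
            exit_key: EndKey = (cur_chrom, idx, "R" if sign == "+" else "L")
            if exit_key not in graph.edges:
                terminal_qter = (
                    sign == "+"
                    and seg.end == graph.chrom_lengths[cur_chrom]
                )
                if not terminal_qter:
                    warnings.warn(
                        f"derivative starting at {chrom}pter ends on a free "
                        f"end at {cur_chrom}:{seg.start if sign == '-' else seg.end}; "
                        "incomplete derivative",
                        stacklevel=2,
                    )
                break
            entry_key, jid = graph.edges[exit_key]
            adjacencies.append(
                SegmentAdjacency(
                    left=_breakend_of_end(graph, exit_key),
                    right=_breakend_of_end(graph, entry_key),
                    source_junction=jid,
                )
            )
            cur_chrom, idx, entry_side = entry_key
            sign = "+" if entry_side == "L" else "-"

        if len(segs_out) == 1 and segs_out[0].sign == "+" and not adjacencies:
            name = chrom
        else:
            name = f"der({chrom_display(chrom)})"
        derivatives.append(DerivativeChromosome(name, segs_out, adjacencies))
    return derivatives


def deletion_sizes(graph: BreakpointGraph) -> dict[Interval, int]:
    """Deleted bases per absent interval, 1-based inclusive arithmetic
    (size = end - start + 1)."""
    return {iv: iv.size for iv in graph.absent}


def bases_strictly_between(pos1: int, pos2: int) -> int:
    """Bases strictly between two breakpoint coordinates on one chromosome."""
    lo, hi = sorted((pos1, pos2))
    return max(0, hi - lo - 1)


# ---------------------------------------------------------------------------
# ISCN-style karyotype rendering
# ---------------------------------------------------------------------------

ARROW = "→"  # ISCN direction arrow

# Event tuples: ("del", chrom, start, end), ("inv", chrom, start, end),
# ("t", chrom_a, pos_a, chrom_b, pos_b)
_EVENT_RANK = {"del": 0, "inv": 1, "t": 2}


def infer_events(
    graph: BreakpointGraph, derivatives: list[DerivativeChromosome]
) -> list[tuple]:
    """Derive del/inv/t event terms from a reconstructed genome.

    Deletions come from absent intervals, inversions from minus-sign
    segments, and one translocation term per chromosome pair from the
    inter-chromosomal adjacency of the lower-sorting derivative.
    """
    events: list[tuple] = [
        ("del", iv.chrom, iv.start, iv.end) for iv in graph.absent
    ]
    for der in derivatives:
        for seg in der.segments:
            if seg.sign == "-":
                events.append(("inv", seg.chrom, seg.start, seg.end))
    seen_pairs: set[frozenset] = set()
    ordered = sorted(
        derivatives, key=lambda d: chrom_sort_key(d.segments[0].chrom)
    )
    for der in ordered:
        for adj in der.adjacencies:
            if adj.left.chrom == adj.right.chrom:
                continue
            pair = frozenset((adj.left.chrom, adj.right.chrom))
            if pair in seen_pairs:
                continue
            seen_pairs.add(pair)
            a, b = adj.left, adj.right
            if chrom_sort_key(b.chrom) < chrom_sort_key(a.chrom):
                a, b = b, a
            events.append(("t", a.chrom, a.pos, b.chrom, b.pos))
    return events


def _point_label(
    chrom: str,
    pos: int,
    band_map: BandMap,
    chrom_lengths: dict[str, int],
) -> str:
    disp = chrom_display(chrom)
    if pos == 1:
        return f"{disp}pter"
    if pos == chrom_lengths.get(chrom):
        return f"{disp}qter"
    return f"{disp}{band_map.band(chrom, pos)}"


def _segment_term(
    seg: Segment, band_map: BandMap, chrom_lengths: dict[str, int]
) -> str:
    if seg.sign == "+":
        first, last = seg.start, seg.end
    else:
        first, last = seg.end, seg.start
    return (
        _point_label(seg.chrom, first, band_map, chrom_lengths)
        + ARROW
        + _point_label(seg.chrom, last, band_map, chrom_lengths)
    )


def karyotype_string(
    derivatives: list[DerivativeChromosome],
    events: list[tuple],
    band_map: BandMap,
    chrom_lengths: dict[str, int],
    sex_prefix: str = "46,XY",
) -> str:
    """Render the revised karyotype: sex prefix, del/inv/t terms, then the
    pter->qter composition of each rearranged derivative with ``::``
    separators.

    Event terms are ordered by (type, chromosome, position) — deletions,
    then inversions, then translocations — matching the published style in
    which the translocation term precedes the derivative composition.
    """

    def band_of(chrom: str, pos: int) -> str:
        return band_map.band(chrom, pos)

    terms: list[str] = []
    for ev in sorted(
        events,
        key=lambda e: (_EVENT_RANK[e[0]], chrom_sort_key(e[1]), e[2]),
    ):
        kind = ev[0]
        if kind in ("del", "inv"):
            _, chrom, start, end = ev
            disp = chrom_display(chrom)
            terms.append(f"{kind}({disp})({band_of(chrom, start)}{band_of(chrom, end)})")
        elif kind == "t":
            _, ca, pa, cb, pb = ev
            terms.append(
                f"t({chrom_display(ca)};{chrom_display(cb)})"
                f"({band_of(ca, pa)};{band_of(cb, pb)})"
            )
        else:
            raise ParameterError(f"unknown event kind {kind!r}")

    rearranged = [d for d in derivatives if not d.is_reference]
    composition = ""
    if rearranged:
        rearranged.sort(key=lambda d: chrom_sort_key(d.segments[0].chrom))
        parts = [
            "::".join(
                _segment_term(seg, band_map, chrom_lengths) for seg in d.segments
            )
            for d in rearranged
        ]
        composition = "(" + ";".join(parts) + ")"

    return sex_prefix + ("," if terms else "") + "".join(terms) + composition


# ---------------------------------------------------------------------------
# Junction sequence extraction
# ---------------------------------------------------------------------------


def _oriented_sequence(ref_sequences: dict[str, str], seg: Segment) -> str:
    piece = ref_sequences[seg.chrom][seg.start - 1 : seg.end]
    return piece if seg.sign == "+" else reverse_complement(piece)


def junction_reference_sequence(
    ref_sequences: dict[str, str],
    derivative: DerivativeChromosome,
    junction_index: int,
    flank: int,
) -> str:
    """Sequence across a derivative junction: ``flank`` bases either side.

    Minus-sign segments contribute reverse-complemented reference sequence.
    A flank longer than the adjoining segment is truncated with a warning.
    """
    if flank < 1:
        raise ParameterError("flank must be >= 1")
    if not 0 <= junction_index < len(derivative.segments) - 1:
        raise ParameterError(
            f"junction_index {junction_index} out of range for "
            f"{len(derivative.segments)} segments"
        )
    left = derivative.segments[junction_index]
    right = derivative.segments[junction_index + 1]
    if flank > left.length or flank > right.length:
        warnings.warn(
            "flank exceeds segment length; junction sequence truncated",
            stacklevel=2,
        )
    left_seq = _oriented_sequence(ref_sequences, left)[-flank:]
    right_seq = _oriented_sequence(ref_sequences, right)[:flank]
    return left_seq + right_seq
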