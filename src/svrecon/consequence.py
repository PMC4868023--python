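"""Transcript consequences of rearrangement breakpoints.

Classifies isoforms as interrupted / intact-proximal / intact-distal
relative to a breakpoint set, predicts fusion transcripts across derivative
adjacencies (5' partner transcribed toward the junction, 3' partner away
from it, orientations evaluated on the derivative), reports which annotated
protein domains survive, and summarises isoform-panel expression by status.

"Distal" is defined in transcription order: an intact transcript is distal
when it initiates downstream of the breakpoint along its own direction of
transcription (for a minus-strand gene such as TCF4 that is the genomically
centromeric side), and proximal otherwise.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Sequence

import pandas as pd

from .core import (
    HEAD,
    INTACT_DISTAL,
    INTACT_PROXIMAL,
    INTERRUPTED,
    Breakend,
    ConsequenceCall,
    FusionModel,
    Interval,
    ParameterError,
    SchemaError,
    SegmentAdjacency,
    TranscriptModel,
)

# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def classify_transcripts(
    models: Sequence[TranscriptModel],
    breakends: Sequence[Breakend],
    deleted_intervals: Sequence[Interval] = (),
) -> list[ConsequenceCall]:
    """Assign exactly one status per transcript on the breakpoint chromosomes.

    A transcript is *interrupted* when its genomic span contains a breakend
    or intersects a deleted interval (promoter loss included: a TSS inside a
    deletion interrupts the transcript).  Otherwise it is *intact_distal*
    when it lies entirely downstream of every breakend in its own
    transcription direction, else *intact_proximal*.  Transcripts on other
    chromosomes are skipped with a notice.
    """
    if not breakends:
        raise ParameterError("at least one breakend is required")
    bp_chroms = {be.chrom for be in breakends}
    calls: list[ConsequenceCall] = []
    for model in models:
        if model.chrom not in bp_chroms:
            warnings.warn(
                f"{model.transcript_id}: chromosome {model.chrom} carries no "
                "breakend; transcript skipped",
                stacklevel=2,
            )
            continue
        span_lo, span_hi = model.span
        local = [be for be in breakends if be.chrom == model.chrom]
        dels = [iv for iv in deleted_intervals if iv.chrom == model.chrom]
        hit = any(span_lo <= be.pos <= span_hi for be in local) or any(
            iv.start <= span_hi and span_lo <= iv.end for iv in dels
        )
        if hit:
            used = next(
                (be for be in local if span_lo <= be.pos <= span_hi), local[0]
            )
            calls.append(ConsequenceCall(model.transcript_id, INTERRUPTED, used))
            continue
        min_bp = min(be.pos for be in local)
        max_bp = max(be.pos for be in local)
        if model.strand == "+":
            distal = span_lo > max_bp
        else:
            distal = span_hi < min_bp
        status = INTACT_DISTAL if distal else INTACT_PROXIMAL
        calls.append(ConsequenceCall(model.transcript_id, status, None))
    return calls


# ---------------------------------------------------------------------------
# Fusion prediction
# ---------------------------------------------------------------------------


def _derivative_forward(strand: str, breakend: Breakend, side: str) -> bool:
    """Is the gene transcribed left-to-right on the derivative at this
    adjacency?

    ``side`` is "left" or "right" of the junction.  A HEAD breakend keeps the
    reference orientation on the left side but appears reverse-complemented
    on the right side (and vice versa for TAIL), so the derivative direction
    of transcription is the reference strand composed with the segment sign.
    """
    plus_segment = (side == "left") == (breakend.orientation == HEAD)
    return (strand == "+") == plus_segment


def _retained_exons(
    model: TranscriptModel, breakend: Breakend
) -> tuple[tuple[int, int], ...]:
    """Exons wholly on the retained side of the breakend: HEAD keeps the
    [..pos] side of the reference, TAIL keeps [pos..]."""
    if breakend.orientation == HEAD:
        keep = [e for e in model.exons if e[1] <= breakend.pos]
    else:
        keep = [e for e in model.exons if e[0] >= breakend.pos]
    return tuple(keep)


def predict_fusions(
    adjacency: SegmentAdjacency, models: Sequence[TranscriptModel]
) -> list[FusionModel]:
    """Fusion transcripts compatible with one derivative adjacency.

    For every transcript interrupted by the left breakend and transcribed
    toward the junction on the derivative, paired with every transcript
    interrupted by the right breakend and transcribed away from it, emit a
    fusion retaining the 5' partner's exons upstream of the junction and the
    3' partner's exons downstream.  Partners whose derivative orientations
    conflict yield nothing.
    """

    def interrupted_here(model: TranscriptModel, be: Breakend) -> bool:
        lo, hi = model.span
        return model.chrom == be.chrom and lo <= be.pos <= hi

    five_prime = [
        m
        for m in models
        if interrupted_here(m, adjacency.left)
        and _derivative_forward(m.strand, adjacency.left, "left")
    ]
    three_prime = [
        m
        for m in models
        if interrupted_here(m, adjacency.right)
        and _derivative_forward(m.strand, adjacency.right, "right")
    ]
    fusions = []
    for up in five_prime:
        up_exons = _retained_exons(up, adjacency.left)
        if not up_exons:
            continue  # promoter and all exons lost; nothing to splice from
        for down in three_prime:
            down_exons = _retained_exons(down, adjacency.right)
            if not down_exons:
                continue
            # orientation soundness: both partners must read left-to-right on
            # the derivative — guaranteed by the selection above
            assert _derivative_forward(up.strand, adjacency.left, "left")
            assert _derivative_forward(down.strand, adjacency.right, "right")
            note = _frame_note(up, up_exons, down, down_exons)
            fusions.append(
                FusionModel(
                    five_prime_gene=up.gene,
                    five_prime_transcript=up.transcript_id,
                    five_prime_exons=up_exons,
                    three_prime_gene=down.gene,
                    three_prime_transcript=down.transcript_id,
                    three_prime_exons=down_exons,
                    junction=adjacency,
                    frame_note=note,
                )
            )
    return fusions


def _frame_note(up, up_exons, down, down_exons) -> str:
    """Annotation-level reading-frame remark (no splicing simulation)."""

    def overlaps_cds(model, exons):
        if model.cds is None:
            return False
        lo, hi = model.cds
        return any(s <= hi and lo <= e for s, e in exons)

    up_coding = overlaps_cds(up, up_exons)
    down_coding = overlaps_cds(down, down_exons)
    if not up_coding and down_coding:
        return "5' partner contributes non-coding exons; ORF may initiate in 3' partner"
    if up_coding and down_coding:
        return "both partners contribute coding exons; frame not validated"
    return "no coding exons retained"


# ---------------------------------------------------------------------------
# Domain retention
# ---------------------------------------------------------------------------


def _merge_intervals(exons: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(exons):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _retained_exons_for_call(
    call: ConsequenceCall, model: TranscriptModel
) -> tuple[tuple[int, int], ...]:
    if call.status != INTERRUPTED or call.breakpoint is None:
        return model.exons
    # truncated transcript keeps its 5' exons up to the first breakend met in
    # transcription order
    bp = call.breakpoint.pos
    if model.strand == "+":
        return tuple(e for e in model.exons if e[1] < bp)
    return tuple(e for e in model.exons if e[0] > bp)


def domain_retention(
    call: ConsequenceCall | FusionModel,
    models: Sequence[TranscriptModel],
) -> set[str]:
    """Domain labels whose genomic intervals are fully contained in the exons
    present in the (possibly truncated or fused) model."""
    by_id = {m.transcript_id: m for m in models}
    if isinstance(call, FusionModel):
        exons = list(call.five_prime_exons) + list(call.three_prime_exons)
        donors = [
            by_id[t]
            for t in (call.five_prime_transcript, call.three_prime_transcript)
            if t in by_id
        ]
        domains = [d for m in donors for d in m.domains]
    else:
        model = by_id.get(call.transcript_id)
        if model is None:
            raise ParameterError(f"unknown transcript {call.transcript_id!r}")
        exons = list(_retained_exons_for_call(call, model))
        domains = list(model.domains)
    if not domains:
        warnings.warn("no domains annotated; returning empty set", stacklevel=2)
        return set()
    merged = _merge_intervals(exons)
    retained = set()
    for label, d_start, d_end in domains:
        if any(s <= d_start and d_end <= e for s, e in merged):
            retained.add(label)
    return retained


# ---------------------------------------------------------------------------
# Panel summary
# ---------------------------------------------------------------------------


def transcript_group_summary(
    calls: Sequence[ConsequenceCall],
    panel: pd.DataFrame,
    fusion_probes: Sequence[str] = ("fusion",),
) -> tuple[pd.DataFrame, float]:
    """Composite expression per consequence status plus the fusion fraction.

    ``panel`` must have columns probe / count_case / count_control, with each
    probe either a classified transcript id or a fusion probe.  Composite
    level = sum of member levels; the log2 ratio compares case to control
    composites; fusion fraction = fusion case level / total case level.
    """
    for col in ("probe", "count_case", "count_control"):
        if col not in panel.columns:
            raise SchemaError(f"panel table lacks column {col!r}")
    status_of = {c.transcript_id: c.status for c in calls}
    fusion_set = set(fusion_probes)
    unmapped = [
        p
        for p in panel["probe"]
        if p not in status_of and p not in fusion_set
    ]
    if unmapped:
        raise ParameterError(
            f"panel rows map to no consequence status: {sorted(set(unmapped))}"
        )

    group = panel.assign(
        status=[
            "fusion" if p in fusion_set else status_of[p] for p in panel["probe"]
        ]
    )
    agg = group.groupby("status")[["count_case", "count_control"]].sum()

    def log2_ratio(case: float, control: float) -> float:
        if control == 0:
            return math.inf if case > 0 else math.nan
        if case == 0:
            return -math.inf
        return math.log2(case / control)

    agg["log2_ratio"] = [
        log2_ratio(c, ctrl)
        for c, ctrl in zip(agg["count_case"], agg["count_control"])
    ]
    total_case = float(panel["count_case"].sum())
    fusion_case = float(
        panel.loc[panel["probe"].isin(fusion_set), "count_case"].sum()
    )
    fusion_fraction = fusion_case / total_case if total_case > 0 else math.nan
    return agg, fusion_fraction
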