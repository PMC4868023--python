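"""Synthetic genomes, rearrangements, read pairs and expression tables.

Everything downstream of alignment is testable offline against this module:
it builds a toy two-chromosome reference, applies a three-break
inversion-plus-translocation mechanism with breakpoint-flanking deletions
(the topology of a complex t(14;18) disrupting TCF4), simulates short-insert
paired-end alignments (308 bp median insert, 100 bp reads) in reference
coordinates, and emits lognormal two-condition expression tables with
injectable regional effects.  Each generator is deterministic for a fixed
seed and returns its ground truth alongside the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .core import (
    HEAD,
    TAIL,
    INTER_CHROMOSOMAL,
    INVERSION_LIKE,
    DELETION_LIKE,
    DUPLICATION_LIKE,
    Breakend,
    DerivativeChromosome,
    Interval,
    JunctionCall,
    PAIR_TABLE_COLUMNS,
    ParameterError,
    RearrangementSpecError,
    Segment,
    SegmentAdjacency,
    chrom_display,
)

BASES = np.frombuffer(b"ACGT", dtype="S1")

# ---------------------------------------------------------------------------
# Toy reference
# ---------------------------------------------------------------------------


@dataclass
class ToyReference:
    """A small multi-chromosome reference with a banding annotation."""

    chromosomes: dict[str, str]
    band_map: list[tuple[str, int, int, str]]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def validate(self) -> None:
        for name, length in self.lengths.items():
            bands = sorted(
                (s, e, lab) for c, s, e, lab in self.band_map if c == name
            )
            if not bands:
                raise ParameterError(f"no bands for {name}")
            if bands[0][0] != 1 or bands[-1][1] != length:
                raise ParameterError(f"bands do not tile chromosome {name}")
            for (s1, e1, _), (s2, e2, _) in zip(bands, bands[1:]):
                if s2 != e1 + 1:
                    raise ParameterError(f"bands not contiguous on {name}")


_BAND_LABELS = ["p12", "p11", "q11", "q12", "q21", "q22"]


def build_toy_genome(
    n_chroms: int = 2,
    length_bp: int = 500_000,
    gc: float = 0.4,
    seed: int = 0,
    names: Optional[Sequence[str]] = None,
) -> ToyReference:
    """Generate a random reference with the given GC fraction.

    Each chromosome receives six equal bands (p12..q22) tiling [1, length].
    Deterministic for a fixed seed.
    """
    if n_chroms < 2:
        raise ParameterError("n_chroms must be >= 2")
    if length_bp < 10_000:
        raise ParameterError("length_bp must be >= 10,000")
    if not 0.0 <= gc <= 1.0:
        raise ParameterError("gc must lie in [0, 1]")
    if names is None:
        names = [f"chr{i + 1}" for i in range(n_chroms)]
    elif len(names) != n_chroms:
        raise ParameterError("names must match n_chroms")

    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    chromosomes = {}
    band_map: list[tuple[str, int, int, str]] = []
    for name in names:
        idx = rng.choice(4, size=length_bp, p=probs)
        chromosomes[name] = BASES[idx].tobytes().decode("ascii")
        edges = np.linspace(0, length_bp, len(_BAND_LABELS) + 1).astype(int)
        for lab, lo, hi in zip(_BAND_LABELS, edges[:-1], edges[1:]):
            band_map.append((name, int(lo) + 1, int(hi), lab))
    ref = ToyReference(chromosomes, band_map)
    ref.validate()
    return ref


# ---------------------------------------------------------------------------
# Rearrangement specification and application
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InversionSpec:
    """Inverted segment [start, end] with optional flanking deletions.

    ``deletion_centromeric`` must end at start-1; ``deletion_telomeric`` must
    begin at end+1 (each breakpoint lies adjacent to its deletion).
    """

    chrom: str
    start: int
    end: int
    deletion_centromeric: Optional[Interval] = None
    deletion_telomeric: Optional[Interval] = None


@dataclass(frozen=True)
class TranslocationSpec:
    """Translocation break: der(A) keeps A[1..break_a]; optional deletion_a
    (starting at break_a+1) is lost before A resumes on der(B).  When no
    inversion is present, ``break_b`` plays the same role on chromosome B."""

    chrom_a: str
    break_a: int
    chrom_b: str
    break_b: Optional[int] = None
    deletion_a: Optional[Interval] = None
    deletion_b: Optional[Interval] = None


@dataclass(frozen=True)
class RearrangementSpec:
    translocation: Optional[TranslocationSpec] = None
    inversion: Optional[InversionSpec] = None


@dataclass
class TruthSet:
    """Ground truth emitted next to every rearranged genome."""

    junctions: list[JunctionCall]
    derivatives: list[DerivativeChromosome]
    deleted_bases: dict[Interval, int]


@dataclass
class DerivedGenome:
    """Derivative (and untouched) sequences with their reference segments."""

    sequences: dict[str, str]
    segments: dict[str, list[Segment]]
    ref_lengths: dict[str, int]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}


def identity_derived(ref: ToyReference) -> DerivedGenome:
    """Wrap an unrearranged reference so it can feed the read simulator."""
    segments = {
        name: [Segment(name, 1, length, "+")] for name, length in ref.lengths.items()
    }
    return DerivedGenome(dict(ref.chromosomes), segments, ref.lengths)


def _check_in_bounds(lengths: dict[str, int], chrom: str, pos: int, what: str) -> None:
    if chrom not in lengths:
        raise RearrangementSpecError(f"{what}: unknown chromosome {chrom!r}")
    if not 1 <= pos <= lengths[chrom]:
        raise RearrangementSpecError(f"{what}: position {pos} outside {chrom}")


def _validate_spec(spec: RearrangementSpec, lengths: dict[str, int]) -> None:
    if spec.translocation is None and spec.inversion is None:
        raise RearrangementSpecError("spec contains no event")
    deletions: list[Interval] = []
    inv = spec.inversion
    if inv is not None:
        _check_in_bounds(lengths, inv.chrom, inv.start, "inversion start")
        _check_in_bounds(lengths, inv.chrom, inv.end, "inversion end")
        if inv.end <= inv.start:
            raise RearrangementSpecError("inversion end must exceed start")
        if inv.deletion_centromeric is not None:
            d = inv.deletion_centromeric
            if d.chrom != inv.chrom or d.end != inv.start - 1:
                raise RearrangementSpecError(
                    "centromeric deletion must abut the inversion start"
                )
            deletions.append(d)
        if inv.deletion_telomeric is not None:
            d = inv.deletion_telomeric
            if d.chrom != inv.chrom or d.start != inv.end + 1:
                raise RearrangementSpecError(
                    "telomeric deletion must abut the inversion end"
                )
            deletions.append(d)
    t = spec.translocation
    if t is not None:
        _check_in_bounds(lengths, t.chrom_a, t.break_a, "translocation break_a")
        if t.deletion_a is not None:
            if t.deletion_a.chrom != t.chrom_a or t.deletion_a.start != t.break_a + 1:
                raise RearrangementSpecError(
                    "deletion_a must begin immediately after break_a"
                )
            deletions.append(t.deletion_a)
        if inv is not None:
            if t.chrom_b != inv.chrom:
                raise RearrangementSpecError(
                    "translocation chrom_b must match the inversion chromosome"
                )
        else:
            if t.break_b is None:
                raise RearrangementSpecError(
                    "break_b is required when no inversion is specified"
                )
            _check_in_bounds(lengths, t.chrom_b, t.break_b, "translocation break_b")
            if t.deletion_b is not None:
                if (
                    t.deletion_b.chrom != t.chrom_b
                    or t.deletion_b.start != t.break_b + 1
                ):
                    raise RearrangementSpecError(
                        "deletion_b must begin immediately after break_b"
                    )
                deletions.append(t.deletion_b)
    for d in deletions:
        _check_in_bounds(lengths, d.chrom, d.start, "deletion")
        _check_in_bounds(lengths, d.chrom, d.end, "deletion")
    for i, d1 in enumerate(deletions):
        for d2 in deletions[i + 1 :]:
            if d1.overlaps(d2):
                raise RearrangementSpecError(f"overlapping deletions {d1} / {d2}")


def _segment_lists(
    spec: RearrangementSpec, lengths: dict[str, int]
) -> dict[str, list[Segment]]:
    """Derivative name -> ordered signed segment list implied by the spec."""
    inv, t = spec.inversion, spec.translocation
    out: dict[str, list[Segment]] = {}

    if t is not None:
        a, b = t.chrom_a, t.chrom_b
        a_resume = (t.deletion_a.end + 1) if t.deletion_a else t.break_a + 1
        if inv is not None:
            cent_keep = (
                inv.deletion_centromeric.start - 1
                if inv.deletion_centromeric
                else inv.start - 1
            )
            telo_resume = (
                inv.deletion_telomeric.end + 1
                if inv.deletion_telomeric
                else inv.end + 1
            )
            out[f"der({chrom_display(a)})"] = [
                Segment(a, 1, t.break_a, "+"),
                Segment(b, inv.start, inv.end, "-"),
                Segment(b, telo_resume, lengths[b], "+"),
            ]
            out[f"der({chrom_display(b)})"] = [
                Segment(b, 1, cent_keep, "+"),
                Segment(a, a_resume, lengths[a], "+"),
            ]
        else:
            b_resume = (t.deletion_b.end + 1) if t.deletion_b else t.break_b + 1
            out[f"der({chrom_display(a)})"] = [
                Segment(a, 1, t.break_a, "+"),
                Segment(b, b_resume, lengths[b], "+"),
            ]
            out[f"der({chrom_display(b)})"] = [
                Segment(b, 1, t.break_b, "+"),
                Segment(a, a_resume, lengths[a], "+"),
            ]
    else:  # inversion only
        b = inv.chrom
        cent_keep = (
            inv.deletion_centromeric.start - 1
            if inv.deletion_centromeric
            else inv.start - 1
        )
        telo_resume = (
            inv.deletion_telomeric.end + 1 if inv.deletion_telomeric else inv.end + 1
        )
        out[f"der({chrom_display(b)})"] = [
            Segment(b, 1, cent_keep, "+"),
            Segment(b, inv.start, inv.end, "-"),
            Segment(b, telo_resume, lengths[b], "+"),
        ]
    return out


def segment_junctions(segments: Sequence[Segment]) -> list[tuple[Breakend, Breakend]]:
    """Breakend pairs for every novel adjacency between consecutive segments."""
    pairs = []
    for left, right in zip(segments, segments[1:]):
        # reference continuation is not a novel adjacency
        if (
            left.chrom == right.chrom
            and left.sign == right.sign == "+"
            and right.start == left.end + 1
        ):
            continue
        if (
            left.chrom == right.chrom
            and left.sign == right.sign == "-"
            and left.start == right.end + 1
        ):
            continue
        be_left = (
            Breakend(left.chrom, left.end, HEAD)
            if left.sign == "+"
            else Breakend(left.chrom, left.start, TAIL)
        )
        be_right = (
            Breakend(right.chrom, right.start, TAIL)
            if right.sign == "+"
            else Breakend(right.chrom, right.end, HEAD)
        )
        pairs.append((be_left, be_right))
    return pairs


def junction_class(be1: Breakend, be2: Breakend) -> str:
    """Evidence class implied by a breakend pair."""
    if be1.chrom != be2.chrom:
        return INTER_CHROMOSOMAL
    if be1.orientation == be2.orientation:
        return INVERSION_LIKE
    lo, hi = sorted((be1, be2), key=lambda b: b.pos)
    return DELETION_LIKE if lo.orientation == HEAD else DUPLICATION_LIKE


def _truth_junction(be1: Breakend, be2: Breakend, call_id: str) -> JunctionCall:
    return JunctionCall(
        breakend_1=be1,
        breakend_2=be2,
        svclass=junction_class(be1, be2),
        support=1,
        plus_reads_1=1 if be1.orientation == HEAD else 0,
        minus_reads_1=0 if be1.orientation == HEAD else 1,
        plus_reads_2=1 if be2.orientation == HEAD else 0,
        minus_reads_2=0 if be2.orientation == HEAD else 1,
        score=99,
        call_id=call_id,
    )


def apply_rearrangement(
    ref: ToyReference, spec: RearrangementSpec
) -> tuple[DerivedGenome, TruthSet]:
    """Apply the rearrangement and return the derived genome plus truth.

    der(A) = A-centromeric(+) :: inverted-B-segment(-) :: B-telomeric(+) and
    der(B) = B-centromeric(+) :: A-telomeric(+) for the full three-break
    topology; degenerate specs (translocation-only, inversion-only) yield the
    corresponding simpler structures.  Total derivative length equals total
    reference length minus the deleted bases, exactly.
    """
    lengths = ref.lengths
    _validate_spec(spec, lengths)
    der_segments = _segment_lists(spec, lengths)

    rearranged_chroms = {
        seg.chrom for segs in der_segments.values() for seg in segs
    }
    sequences: dict[str, str] = {}
    segments: dict[str, list[Segment]] = {}
    derivatives: list[DerivativeChromosome] = []
    junctions: list[JunctionCall] = []

    for name, segs in der_segments.items():
        parts = []
        for seg in segs:
            piece = ref.chromosomes[seg.chrom][seg.start - 1 : seg.end]
            parts.append(piece if seg.sign == "+" else reverse_complement(piece))
        sequences[name] = "".join(parts)
        segments[name] = list(segs)
        adjacencies = []
        for be1, be2 in segment_junctions(segs):
            jid = f"truth_{len(junctions) + 1}"
            junctions.append(_truth_junction(be1, be2, jid))
            adjacencies.append(SegmentAdjacency(be1, be2, jid))
        derivatives.append(DerivativeChromosome(name, list(segs), adjacencies))

    for name, seq in ref.chromosomes.items():
        if name not in rearranged_chroms:
            sequences[name] = seq
            segments[name] = [Segment(name, 1, len(seq), "+")]

    deleted: dict[Interval, int] = {}
    inv, t = spec.inversion, spec.translocation
    for d in (
        inv.deletion_centromeric if inv else None,
        inv.deletion_telomeric if inv else None,
        t.deletion_a if t else None,
        t.deletion_b if (t and inv is None) else None,
    ):
        if d is not None:
            deleted[d] = d.size

    total_ref = sum(lengths[c] for c in rearranged_chroms)
    total_der = sum(len(sequences[d.name]) for d in derivatives)
    if total_der + sum(deleted.values()) != total_ref:
        raise RearrangementSpecError("length conservation violated (internal bug)")

    truth = TruthSet(junctions, derivatives, deleted)
    return DerivedGenome(sequences, segments, lengths), truth


def demo_rearrangement_spec(ref: ToyReference) -> RearrangementSpec:
    """Three-break demo topology scaled onto a toy reference.

    Chromosome A carries the translocation break with a 29 bp flanking
    deletion; chromosome B carries the inversion with a 3,892 bp deletion at
    its centromeric breakpoint and a 1,939 bp deletion at its telomeric
    breakpoint (the published event scaled down tenfold where the toy
    chromosome is shorter than the real one).
    """
    names = list(ref.chromosomes)
    chrom_a, chrom_b = names[0], names[1]
    la, lb = ref.lengths[chrom_a], ref.lengths[chrom_b]
    if min(la, lb) < 100_000:
        raise ParameterError("demo spec needs chromosomes of >= 100 kb")
    break_a = int(0.65 * la)
    inv_start = int(0.368 * lb)
    inv_end = int(0.554 * lb)
    return RearrangementSpec(
        translocation=TranslocationSpec(
            chrom_a=chrom_a,
            break_a=break_a,
            chrom_b=chrom_b,
            deletion_a=Interval(chrom_a, break_a + 1, break_a + 29),
        ),
        inversion=InversionSpec(
            chrom=chrom_b,
            start=inv_start,
            end=inv_end,
            deletion_centromeric=Interval(chrom_b, inv_start - 3_892, inv_start - 1),
            deletion_telomeric=Interval(chrom_b, inv_end + 1, inv_end + 1_939),
        ),
    )


# ---------------------------------------------------------------------------
# Read-pair simulation
# ---------------------------------------------------------------------------


def simulate_read_pairs(
    genome: DerivedGenome,
    n_pairs: int,
    insert_mean: float = 308.0,
    insert_sd: float = 30.0,
    read_len: int = 100,
    mapq_range: tuple[int, int] = (60, 60),
    seed: int = 0,
    background_discordant_rate: float = 0.0,
) -> pd.DataFrame:
    """Sample read pairs uniformly from the derived sequences and report them
    in reference coordinates.

    Fragments are placed uniformly; the insert length is normal (default
    308 +/- 30, the short-insert library of the source data) truncated at
    ``2 * read_len``.  A read overlapping a junction is assigned to the
    segment holding the majority of its bases (soft-clip style), so pairs
    wholly inside one reference segment come out concordant and
    junction-spanning pairs acquire the discordant signature implied by the
    segment orientations.  ``background_discordant_rate`` adds that fraction
    of uniformly random (spurious) discordant pairs.
    """
    if n_pairs <= 0:
        raise ParameterError("n_pairs must be positive")
    if insert_mean <= 2 * read_len:
        raise ParameterError("insert_mean must exceed 2 * read_len")
    if not 0 <= mapq_range[0] <= mapq_range[1]:
        raise ParameterError("bad mapq_range")

    rng = np.random.default_rng(seed)
    names = list(genome.sequences)
    lens = np.array([len(genome.sequences[n]) for n in names], dtype=float)
    counts = rng.multinomial(n_pairs, lens / lens.sum())

    frames = []
    serial = 0
    for name, n_here in zip(names, counts):
        if n_here == 0:
            continue
        L = int(len(genome.sequences[name]))
        inserts = np.rint(rng.normal(insert_mean, insert_sd, n_here)).astype(int)
        inserts = np.maximum(inserts, 2 * read_len)
        inserts = np.minimum(inserts, L)
        starts = 1 + np.floor(rng.random(n_here) * (L - inserts + 1)).astype(int)

        segs = genome.segments[name]
        offsets = np.cumsum([0] + [s.length for s in segs])  # derivative offsets
        seg_chrom = np.array([s.chrom for s in segs])
        seg_start = np.array([s.start for s in segs])
        seg_end = np.array([s.end for s in segs])
        seg_neg = np.array([s.sign == "-" for s in segs])

        def project(dstart: np.ndarray, der_strand_plus: bool):
            mid = dstart + (read_len - 1) / 2.0
            idx = np.searchsorted(offsets, mid, side="right") - 1
            idx = np.clip(idx, 0, len(segs) - 1)
            within = dstart - 1 - offsets[idx]  # 0-based offset into segment
            neg = seg_neg[idx]
            ref_left = np.where(
                neg,
                seg_end[idx] - within - (read_len - 1),
                seg_start[idx] + within,
            )
            ref_left = np.maximum(ref_left, 1)
            # signs compose: derivative '+' read on a '-' segment maps to the
            # reference '-' strand, a derivative '-' read on it to '+'
            strand = np.where(
                neg, "-" if der_strand_plus else "+", "+" if der_strand_plus else "-"
            )
            return seg_chrom[idx], ref_left.astype(int), strand

        c1, p1, s1 = project(starts, True)
        c2, p2, s2 = project(starts + inserts - read_len, False)
        frames.append(
            pd.DataFrame(
                {
                    "read_id": [f"sim_{serial + i:08d}" for i in range(n_here)],
                    "chrom": c1,
                    "pos": p1,
                    "strand": s1,
                    "mate_chrom": c2,
                    "mate_pos": p2,
                    "mate_strand": s2,
                    "mapq": rng.integers(
                        mapq_range[0], mapq_range[1] + 1, n_here
                    ),
                }
            )
        )
        serial += int(n_here)

    n_bg = int(round(background_discordant_rate * n_pairs))
    if n_bg > 0:
        ref_names = list(genome.ref_lengths)
        ref_lens = np.array([genome.ref_lengths[n] for n in ref_names])
        ci = rng.integers(0, len(ref_names), n_bg)
        cj = rng.integers(0, len(ref_names), n_bg)
        frames.append(
            pd.DataFrame(
                {
                    "read_id": [f"bg_{i:06d}" for i in range(n_bg)],
                    "chrom": np.array(ref_names)[ci],
                    "pos": 1 + np.floor(rng.random(n_bg) * (ref_lens[ci] - read_len)).astype(int),
                    "strand": np.where(rng.random(n_bg) < 0.5, "+", "-"),
                    "mate_chrom": np.array(ref_names)[cj],
                    "mate_pos": 1 + np.floor(rng.random(n_bg) * (ref_lens[cj] - read_len)).astype(int),
                    "mate_strand": np.where(rng.random(n_bg) < 0.5, "+", "-"),
                    "mapq": rng.integers(mapq_range[0], mapq_range[1] + 1, n_bg),
                }
            )
        )

    table = pd.concat(frames, ignore_index=True)
    return table[PAIR_TABLE_COLUMNS]


def pairs_for_depth(
    genome: DerivedGenome, depth: float, read_len: int = 100
) -> int:
    """Number of pairs giving the requested read depth over the genome."""
    total = sum(len(s) for s in genome.sequences.values())
    return int(round(depth * total / (2 * read_len)))


# ---------------------------------------------------------------------------
# Expression profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionalAnticorrelation:
    """Reflect control log-expression about the regional mean so that the
    case/control correlation inside [start_index, end_index] equals
    ``strength`` (use -1 for a fully anti-correlated region)."""

    start_index: int
    end_index: int
    strength: float = -1.0


@dataclass(frozen=True)
class BreakpointShift:
    """Shift the named genes by ``log2_effect`` in the case sample."""

    genes: tuple[str, ...]
    log2_effect: float


def simulate_expression_profiles(
    gene_positions: Sequence[tuple[str, str, int]],
    effect: Optional[object] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    control_log2_mean: float = 3.0,
    control_log2_sd: float = 1.5,
) -> tuple[pd.DataFrame, dict]:
    """Two-condition FPKM table with a known injected effect.

    Control FPKM is lognormal (normal on the log2 scale, mean 3 and sd 1.5 by
    default, a realistic bulk RNA-seq spread); the case profile equals the
    control modified by ``effect`` plus independent N(0, noise_sd) log2 noise.
    Returns the table and the truth description.
    """
    genes = list(gene_positions)
    if len(genes) < 10:
        raise ParameterError("need at least 10 genes")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    n = len(genes)
    control = rng.normal(control_log2_mean, control_log2_sd, n)
    case = control.copy()
    truth: dict = {"effect": "none"}

    if isinstance(effect, RegionalAnticorrelation):
        if not 0 <= effect.start_index <= effect.end_index < n:
            raise ParameterError("anti-correlation region outside the gene list")
        sl = slice(effect.start_index, effect.end_index + 1)
        m = control[sl].mean()
        case[sl] = m + effect.strength * (control[sl] - m)
        truth = {
            "effect": "regional_anticorrelation",
            "region": (effect.start_index, effect.end_index),
            "strength": effect.strength,
        }
    elif isinstance(effect, BreakpointShift):
        name_to_idx = {g[0]: i for i, g in enumerate(genes)}
        missing = [g for g in effect.genes if g not in name_to_idx]
        if missing:
            raise ParameterError(f"unknown genes in breakpoint_shift: {missing}")
        idx = [name_to_idx[g] for g in effect.genes]
        case[idx] += effect.log2_effect
        truth = {
            "effect": "breakpoint_shift",
            "genes": tuple(effect.genes),
            "log2_effect": effect.log2_effect,
        }
    elif effect is not None:
        raise ParameterError(f"unknown effect {effect!r}")

    case = case + rng.normal(0.0, noise_sd, n) if noise_sd > 0 else case
    table = pd.DataFrame(
        {
            "gene": [g[0] for g in genes],
            "chrom": [g[1] for g in genes],
            "position": [g[2] for g in genes],
            "fpkm_case": np.exp2(case),
            "fpkm_control": np.exp2(control),
        }
    )
    return table, truth


def demo_transcript_models(spec: RearrangementSpec) -> list:
    """Toy transcript models around the demo breakpoints.

    One plus-strand gene on chromosome A interrupted within an intron by the
    translocation break (the 5' fusion partner), two minus-strand genes on
    chromosome B spanning the telomeric inversion breakpoint (interrupted,
    potential 3' fusion partners) and two minus-strand genes initiating
    below it (intact, distal in transcription order).
    """
    from .core import TranscriptModel  # local import keeps module header lean

    t, inv = spec.translocation, spec.inversion
    if t is None or inv is None:
        raise ParameterError("demo models need the full three-break topology")
    a, b = t.chrom_a, inv.chrom
    ba, bp = t.break_a, inv.end
    models = [
        TranscriptModel(
            transcript_id="TOY_A1.1",
            gene="GENE_A",
            chrom=a,
            strand="+",
            exons=((ba - 20_000, ba - 19_800), (ba + 2_000, ba + 2_300)),
            cds=(ba + 2_050, ba + 2_250),
        )
    ]
    for i, tid in enumerate(("TOY_B_LONG1.1", "TOY_B_LONG2.1")):
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene=f"GENE_B_LONG{i + 1}",
                chrom=b,
                strand="-",
                exons=(
                    (bp + 12_000 + 3_000 * i, bp + 12_400 + 3_000 * i),
                    (bp - 6_000, bp - 5_700),
                    (bp - 9_000, bp - 8_800),
                ),
                cds=(bp - 9_000, bp - 5_700),
            )
        )
    for i, tid in enumerate(("TOY_B_SHORT1.1", "TOY_B_SHORT2.1")):
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene=f"GENE_B_SHORT{i + 1}",
                chrom=b,
                strand="-",
                exons=(
                    (bp - 4_000 - 1_000 * i, bp - 3_800 - 1_000 * i),
                    (bp - 9_500, bp - 9_300),
                ),
                cds=(bp - 9_500, bp - 9_300),
            )
        )
    return models


# ---------------------------------------------------------------------------
# Transcript panel, qPCR and droplet simulation
# ---------------------------------------------------------------------------


def simulate_transcript_panel(
    models: Sequence,
    breakends: Sequence[Breakend],
    deleted_intervals: Sequence[Interval],
    group_effects: dict[str, float],
    seed: int = 0,
    base_count: float = 500.0,
    noise_sd: float = 0.0,
    fusion_name: str = "fusion",
    fusion_level: float = 0.0,
    droplet_total: int = 4_000_000,
    droplet_lambda: float = 0.3,
    allele_fraction: float = 0.5,
    ct_intercept: float = 34.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Isoform-panel counts, a derived Ct table and a droplet-count table.

    Every transcript model is classified against the breakpoints; case counts
    are the control counts scaled by the per-status fold in ``group_effects``
    (keys: interrupted / intact_proximal / intact_distal), with lognormal
    noise.  ``fusion_level`` adds a case-only fusion probe.  Ct values follow
    Ct = intercept - log2(abundance); droplet positives are binomial under
    Poisson occupancy with the stated allele fraction.
    """
    from .consequence import classify_transcripts  # local: avoid module cycle

    valid = {"interrupted", "intact_proximal", "intact_distal", "fusion"}
    unknown = set(group_effects) - valid
    if unknown:
        raise ParameterError(f"unknown status keys in group_effects: {sorted(unknown)}")

    calls = classify_transcripts(models, breakends, deleted_intervals)
    status = {c.transcript_id: c.status for c in calls}
    missing = [m.transcript_id for m in models if m.transcript_id not in status]
    if missing:
        raise ParameterError(f"transcripts not classified: {missing}")

    rng = np.random.default_rng(seed)
    rows = []
    for m in models:
        fold = group_effects.get(status[m.transcript_id], 1.0)
        control = base_count * np.exp2(rng.normal(0.0, noise_sd))
        case = control * fold * np.exp2(rng.normal(0.0, noise_sd))
        rows.append((m.transcript_id, status[m.transcript_id], case, control))
    if fusion_level > 0 or "fusion" in group_effects:
        level = fusion_level if fusion_level > 0 else group_effects.get("fusion", 0.0)
        rows.append((fusion_name, "fusion", float(level), 0.0))
    panel = pd.DataFrame(
        rows, columns=["probe", "status", "count_case", "count_control"]
    )

    ct_rows = []
    for _, r in panel.iterrows():
        for sample, level in (("case", r.count_case), ("control", r.count_control)):
            if level > 0:
                ct_rows.append((sample, r["probe"], ct_intercept - np.log2(level)))
    ct = pd.DataFrame(ct_rows, columns=["sample", "gene", "ct"])

    lam_a = allele_fraction * droplet_lambda
    lam_b = (1 - allele_fraction) * droplet_lambda
    droplets = pd.DataFrame(
        {
            "assay": ["allele_derivative", "allele_reference"],
            "positive": [
                int(rng.binomial(droplet_total, 1 - np.exp(-lam_a))),
                int(rng.binomial(droplet_total, 1 - np.exp(-lam_b))),
            ],
            "total": [droplet_total, droplet_total],
        }
    )
    return panel, ct, droplets


# ---------------------------------------------------------------------------
# Filter tracks
# ---------------------------------------------------------------------------

TRACK_NAMES = ("dgv_like", "segdup_like", "high_depth_like")


def _merge(intervals: list[Interval]) -> list[Interval]:
    merged: list[Interval] = []
    for iv in sorted(intervals, key=lambda i: (i.chrom, i.start, i.end)):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end + 1:
            last = merged.pop()
            merged.append(Interval(last.chrom, last.start, max(last.end, iv.end)))
        else:
            merged.append(iv)
    return merged


def generate_filter_tracks(
    ref: ToyReference,
    n_intervals: int,
    seed: int = 0,
    length_range: tuple[int, int] = (200, 2_000),
) -> dict[str, list[Interval]]:
    """Three sorted, merged interval tracks emulating common-SV, segmental
    duplication and high-depth exclusion annotations."""
    if n_intervals < 0:
        raise ParameterError("n_intervals must be >= 0")
    rng = np.random.default_rng(seed)
    names = list(ref.chromosomes)
    lengths = ref.lengths
    tracks: dict[str, list[Interval]] = {}
    for track in TRACK_NAMES:
        ivs = []
        for _ in range(n_intervals):
            chrom = names[int(rng.integers(0, len(names)))]
            width = int(rng.integers(length_range[0], length_range[1] + 1))
            start = int(rng.integers(1, max(2, lengths[chrom] - width)))
            ivs.append(Interval(chrom, start, start + width - 1))
        tracks[track] = _merge(ivs)
    return tracks
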