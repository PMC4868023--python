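"""Shared domain types, conventions and exceptions.

Coordinate convention: all public coordinates are 1-based inclusive (the
convention of hg19 genome-browser positions and of karyotype reports).
Conversion to/from 0-based half-open happens only at BED/BEDPE boundaries
(see :mod:`svrecon.io`).

Breakend orientation convention: a breakend ``(chrom, pos, orientation)``
names one oriented side of a novel adjacency.  ``head`` means the junction
uses the centromeric side ``[1..pos]`` of the chromosome (the retained
material ends at ``pos`` and the partner is ligated to its right);
``tail`` means the junction uses ``[pos..end]``.  Plus-strand read evidence
supports a ``head`` breakend, minus-strand evidence a ``tail`` breakend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

# ---------------------------------------------------------------------------
# Exceptions
# ---------------------------------------------------------------------------


class SvreconError(Exception):
    """Base class for all package errors."""


class ParameterError(SvreconError, ValueError):
    """A function argument is outside its documented domain."""


class RearrangementSpecError(SvreconError, ValueError):
    """A rearrangement specification is internally inconsistent."""


class EstimationError(SvreconError):
    """Not enough usable data to estimate a quantity."""


class AmbiguityError(SvreconError):
    """Two junctions share an identical breakend; the graph is ambiguous."""


class ReconstructionError(SvreconError):
    """A derivative walk is cyclic or otherwise impossible."""


class RenderingError(SvreconError):
    """A karyotype element cannot be rendered (e.g. breakend outside bands)."""


class SchemaError(SvreconError, ValueError):
    """A tabular input does not match its documented schema."""


class UndefinedValueError(SvreconError, ValueError):
    """A ratio or log is undefined for the given inputs."""


class SaturationError(SvreconError, ValueError):
    """All droplets positive; Poisson occupancy is unbounded."""


# ---------------------------------------------------------------------------
# Coordinates and intervals
# ---------------------------------------------------------------------------

HEAD = "head"
TAIL = "tail"


def chrom_sort_key(chrom: str):
    """Natural ordering for chromosome names: chr2 < chr14 < chrX."""
    name = chrom.removeprefix("chr")
    return (0, int(name)) if name.isdigit() else (1, name)


def chrom_display(chrom: str) -> str:
    """Chromosome name as it appears in karyotype strings (no 'chr')."""
    return chrom.removeprefix("chr")


@dataclass(frozen=True, order=True)
class Interval:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 1:
            raise ParameterError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ParameterError(
                f"interval end {self.end} precedes start {self.start}"
            )

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass(frozen=True)
class Breakend:
    """One oriented side of a novel adjacency (see module docstring)."""

    chrom: str
    pos: int
    orientation: str  # HEAD or TAIL

    def __post_init__(self):
        if self.orientation not in (HEAD, TAIL):
            raise ParameterError(f"orientation must be head/tail, got {self.orientation!r}")
        if self.pos < 1:
            raise ParameterError("breakend position must be >= 1")


# ---------------------------------------------------------------------------
# Read-pair evidence
# ---------------------------------------------------------------------------

PAIR_TABLE_COLUMNS = [
    "read_id",
    "chrom",
    "pos",
    "strand",
    "mate_chrom",
    "mate_pos",
    "mate_strand",
    "mapq",
]


@dataclass(frozen=True)
class PairRecord:
    """One aligned read pair (positions are leftmost aligned bases)."""

    read_id: str
    chrom: str
    pos: int
    strand: str
    mate_chrom: str
    mate_pos: int
    mate_strand: str
    mapq: int

    def __post_init__(self):
        if self.pos < 1 or self.mate_pos < 1:
            raise ParameterError("pair positions must be >= 1")
        if self.strand not in "+-" or self.mate_strand not in "+-":
            raise ParameterError("strand must be '+' or '-'")
        if self.mapq < 0:
            raise ParameterError("mapq must be >= 0")


@dataclass(frozen=True)
class InsertStats:
    """Insert-size summary of the concordant fragment population."""

    median: float
    mean: float
    sd: float
    concordant_max_span: float


# Junction classes
INTER_CHROMOSOMAL = "inter_chromosomal"
INVERSION_LIKE = "inversion_like"
DELETION_LIKE = "deletion_like"
DUPLICATION_LIKE = "duplication_like"
CONCORDANT = "concordant"

JUNCTION_CLASSES = (
    INTER_CHROMOSOMAL,
    INVERSION_LIKE,
    DELETION_LIKE,
    DUPLICATION_LIKE,
)


@dataclass
class JunctionCall:
    """One novel adjacency supported by a cluster of discordant pairs."""

    breakend_1: Breakend
    breakend_2: Breakend
    svclass: str
    support: int
    plus_reads_1: int = 0
    minus_reads_1: int = 0
    plus_reads_2: int = 0
    minus_reads_2: int = 0
    score: int = 0
    call_id: str = ""

    def __post_init__(self):
        if self.svclass not in JUNCTION_CLASSES:
            raise ParameterError(f"unknown junction class {self.svclass!r}")
        if self.support < 1:
            raise ParameterError("junction support must be >= 1")
        if not 0 <= self.score <= 99:
            raise ParameterError("score must lie in [0, 99]")
        if self.plus_reads_1 + self.minus_reads_1 != self.support:
            raise ParameterError("breakend-1 strand counts must sum to support")
        if self.plus_reads_2 + self.minus_reads_2 != self.support:
            raise ParameterError("breakend-2 strand counts must sum to support")


@dataclass(frozen=True)
class FilterParams:
    """Post-call filtering thresholds (defaults follow the published cascade:
    mapping quality 35, two supporting reads per cluster, >=12 supporting
    pairs, <=60 reads of one strand per breakend, phred-style score >=99 and
    a +/-500 bp repeat-track exclusion window, i.e. a 1001 bp window centered
    on a translocation breakend)."""

    min_mapq: int = 35
    min_reads_call: int = 2
    min_support: int = 12
    max_strand_reads: int = 60
    min_score: int = 99
    track_window_bp: int = 500

    def __post_init__(self):
        for name in (
            "min_mapq",
            "min_reads_call",
            "min_support",
            "max_strand_reads",
            "min_score",
            "track_window_bp",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# Derivative chromosomes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Segment:
    """An oriented reference segment, 1-based inclusive, sign + or -."""

    chrom: str
    start: int
    end: int
    sign: str = "+"

    def __post_init__(self):
        if self.sign not in "+-":
            raise ParameterError("segment sign must be '+' or '-'")
        if self.end < self.start or self.start < 1:
            raise ParameterError(f"bad segment bounds {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SegmentAdjacency:
    """A novel join between two oriented segment ends on a derivative."""

    left: Breakend
    right: Breakend
    source_junction: str = ""


@dataclass
class DerivativeChromosome:
    """An ordered, signed segment list representing one rearranged chromosome."""

    name: str
    segments: list[Segment]
    adjacencies: list[SegmentAdjacency] = field(default_factory=list)

    @property
    def total_length(self) -> int:
        return sum(seg.length for seg in self.segments)

    @property
    def is_reference(self) -> bool:
        return len(self.segments) == 1 and self.segments[0].sign == "+"


@dataclass
class BandMap:
    """Cytogenetic band intervals: sorted, non-overlapping per chromosome."""

    intervals: list[tuple[str, int, int, str]]  # (chrom, start, end, label)

    def __post_init__(self):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, _ in self.intervals:
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, spans in by_chrom.items():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise ParameterError(f"overlapping bands on {chrom}")

    def band(self, chrom: str, pos: int) -> str:
        for c, start, end, label in self.intervals:
            if c == chrom and start <= pos <= end:
                return label
        raise RenderingError(f"position {chrom}:{pos} is outside the band map")


# ---------------------------------------------------------------------------
# Transcript models and consequences
# ---------------------------------------------------------------------------

INTERRUPTED = "interrupted"
INTACT_PROXIMAL = "intact_proximal"
INTACT_DISTAL = "intact_distal"
CONSEQUENCE_STATUSES = (INTERRUPTED, INTACT_PROXIMAL, INTACT_DISTAL)


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded exon chain; the unit of consequence classification.

    ``exons`` are (start, end) 1-based inclusive, sorted 5'->3' in
    transcription order (descending genomic coordinates on the minus strand).
    ``domains`` are (label, start, end) genomic intervals of encoded protein
    features (e.g. NLS, AD1, AD2, bHLH).
    """

    transcript_id: str
    gene: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: Optional[tuple[int, int]] = None
    domains: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self):
        if self.strand not in "+-":
            raise ParameterError("transcript strand must be '+' or '-'")
        if not self.exons:
            raise ParameterError("transcript must have at least one exon")
        genomic = sorted(self.exons)
        expected = genomic if self.strand == "+" else genomic[::-1]
        if tuple(expected) != tuple(self.exons):
            raise ParameterError(
                f"{self.transcript_id}: exons must be listed in transcription order"
            )

    @property
    def tss(self) -> int:
        first = self.exons[0]
        return first[0] if self.strand == "+" else first[1]

    @property
    def span(self) -> tuple[int, int]:
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)


@dataclass(frozen=True)
class ConsequenceCall:
    """Status of one transcript relative to a breakpoint set."""

    transcript_id: str
    status: str
    breakpoint: Optional[Breakend] = None

    def __post_init__(self):
        if self.status not in CONSEQUENCE_STATUSES:
            raise ParameterError(f"unknown consequence status {self.status!r}")


@dataclass(frozen=True)
class FusionModel:
    """A predicted fusion transcript across a derivative adjacency."""

    five_prime_gene: str
    five_prime_transcript: str
    five_prime_exons: tuple[tuple[int, int], ...]
    three_prime_gene: str
    three_prime_transcript: str
    three_prime_exons: tuple[tuple[int, int], ...]
    junction: SegmentAdjacency
    frame_note: str = ""

    @property
    def name(self) -> str:
        return f"{self.five_prime_gene}-{self.three_prime_gene}"


# ---------------------------------------------------------------------------
# Expression analysis
# ---------------------------------------------------------------------------

EXPRESSION_TABLE_COLUMNS = ["gene", "chrom", "position", "fpkm_case", "fpkm_control"]


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene FPKM in case and control, positioned on a chromosome."""

    gene: str
    chrom: str
    position: int
    fpkm_case: float
    fpkm_control: float
    p_value: Optional[float] = None

    def __post_init__(self):
        if self.fpkm_case < 0 or self.fpkm_control < 0:
            raise ParameterError("FPKM values must be non-negative")


@dataclass(frozen=True)
class ScanParams:
    """Windowed positional-correlation scan parameters.

    ``window_w`` genes per window (default 3), pseudo-count of 1 FPKM before
    taking logs, and an anti-correlation call threshold of r <= -0.8.
    """

    window_w: int = 3
    n_permutations: int = 1000
    anticorrelation_threshold: float = -0.8
    pseudo_count: float = 1.0
    log_base: float = 2.0

    def __post_init__(self):
        if self.window_w < 2:
            raise ParameterError("window_w must be >= 2")
        if self.n_permutations < 100:
            raise ParameterError("n_permutations must be >= 100")
        if self.log_base not in (2, 10):
            raise ParameterError("log_base must be 2 or 10")


@dataclass
class ScanResult:
    """Windowed correlation scan output.

    ``window_r[i]`` is the Pearson r between the case and control log
    abundance vectors of the genes in window i (NaN where a window vector has
    zero variance).  ``pair_matrix`` is the symmetric window-by-window Pearson
    matrix of window fold-change vectors.  ``candidates`` are maximal runs of
    consecutive windows at or below the anti-correlation threshold, as
    (first_window, last_window) index pairs.
    """

    window_r: "object"  # numpy array
    pair_matrix: "object"  # numpy array
    candidates: list[tuple[int, int]]
    genes: list[str]
    p_value: Optional[float] = None
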