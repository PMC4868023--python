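"""Readers and writers for the standard formats the pipeline touches.

Disk formats follow their standards: BED/BEDPE are 0-based half-open and are
converted to the package's 1-based inclusive coordinates at this boundary;
FASTA goes through Biopython; the pair table and report tables are TSV with
documented headers.  Writers prepend provenance comment lines (tool version,
config hash, seed); readers skip ``#`` comments.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .core import (
    HEAD,
    TAIL,
    BandMap,
    Breakend,
    Interval,
    JunctionCall,
    PAIR_TABLE_COLUMNS,
    SchemaError,
    TranscriptModel,
)

_STRAND_OF_ORIENTATION = {HEAD: "+", TAIL: "-"}
_ORIENTATION_OF_STRAND = {"+": HEAD, "-": TAIL}


def provenance_lines(seed: Optional[int] = None, config_hash: Optional[str] = None) -> list[str]:
    parts = [f"svrecon v{__version__}"]
    if config_hash is not None:
        parts.append(f"config_hash={config_hash}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return ["# " + " ".join(parts)]


def write_lines(path, lines: Iterable[str], seed=None, config_hash=None) -> None:
    """Write text lines behind a provenance comment header."""
    path = Path(path)
    with path.open("w") as fh:
        for line in provenance_lines(seed, config_hash):
            fh.write(line + "\n")
        for line in lines:
            fh.write(line.rstrip("\n") + "\n")


_write_with_header = write_lines


# ---------------------------------------------------------------------------
# Pair tables (TSV, and minimal SAM)
# ---------------------------------------------------------------------------


def write_pair_table(pairs: pd.DataFrame, path, seed=None, config_hash=None) -> None:
    lines = ["\t".join(PAIR_TABLE_COLUMNS)]
    for row in pairs[PAIR_TABLE_COLUMNS].itertuples(index=False):
        lines.append("\t".join(str(v) for v in row))
    _write_with_header(path, lines, seed, config_hash)


def read_pair_table(path) -> pd.DataFrame:
    """Read a TSV pair table, validating schema and rows (errors carry the
    offending line number)."""
    path = Path(path)
    rows = []
    header: Optional[list[str]] = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in PAIR_TABLE_COLUMNS if c not in header]
                if missing:
                    raise SchemaError(
                        f"{path}:{lineno}: pair table missing columns {missing}"
                    )
                continue
            if len(fields) != len(header):
                raise SchemaError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            rec = dict(zip(header, fields))
            try:
                rows.append(
                    {
                        "read_id": rec["read_id"],
                        "chrom": rec["chrom"],
                        "pos": int(rec["pos"]),
                        "strand": rec["strand"],
                        "mate_chrom": rec["mate_chrom"],
                        "mate_pos": int(rec["mate_pos"]),
                        "mate_strand": rec["mate_strand"],
                        "mapq": int(rec["mapq"]),
                    }
                )
            except (KeyError, ValueError) as exc:
                raise SchemaError(f"{path}:{lineno}: malformed row ({exc})") from exc
            if rows[-1]["strand"] not in "+-" or rows[-1]["mate_strand"] not in "+-":
                raise SchemaError(f"{path}:{lineno}: strand must be '+' or '-'")
    if header is None:
        raise SchemaError(f"{path}: empty pair table (no header)")
    return pd.DataFrame(rows, columns=PAIR_TABLE_COLUMNS)


def read_sam_pairs(path) -> pd.DataFrame:
    """Read mate information from a (text) SAM file into a pair table.

    Only primary alignments with a mapped mate are used; one row per pair,
    keyed on the leftmost-read record.
    """
    import pysam  # deferred: only needed for SAM input

    rows = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for rec in sam:
            if (
                rec.is_unmapped
                or rec.mate_is_unmapped
                or rec.is_secondary
                or rec.is_supplementary
                or not rec.is_read1
            ):
                continue
            rows.append(
                {
                    "read_id": rec.query_name,
                    "chrom": rec.reference_name,
                    "pos": rec.reference_start + 1,
                    "strand": "-" if rec.is_reverse else "+",
                    "mate_chrom": rec.next_reference_name,
                    "mate_pos": rec.next_reference_start + 1,
                    "mate_strand": "-" if rec.mate_is_reverse else "+",
                    "mapq": rec.mapping_quality,
                }
            )
    return pd.DataFrame(rows, columns=PAIR_TABLE_COLUMNS)


# ---------------------------------------------------------------------------
# BED / BEDPE
# ---------------------------------------------------------------------------


def write_bed(intervals: Sequence[Interval], path, seed=None, config_hash=None) -> None:
    lines = [f"{iv.chrom}\t{iv.start - 1}\t{iv.end}" for iv in intervals]
    _write_with_header(path, lines, seed, config_hash)


def read_bed(path) -> list[Interval]:
    """Read BED intervals, converting 0-based half-open to 1-based inclusive."""
    out = []
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                out.append(Interval(fields[0], int(fields[1]) + 1, int(fields[2])))
            except ValueError as exc:
                raise SchemaError(f"{path}:{lineno}: malformed BED row") from exc
    return out


BEDPE_COLUMNS = [
    "chrom1",
    "start1",
    "end1",
    "chrom2",
    "start2",
    "end2",
    "name",
    "score",
    "strand1",
    "strand2",
    "support",
    "svclass",
    "reason",
]


def write_bedpe(
    calls: Sequence[JunctionCall],
    path,
    reasons: Optional[dict[str, str]] = None,
    seed=None,
    config_hash=None,
) -> None:
    """One BEDPE line per junction call; orientation encoded in the strand
    columns (head = '+', tail = '-'), plus support/class/reason columns."""
    reasons = reasons or {}
    lines = ["\t".join(BEDPE_COLUMNS)]
    for call in calls:
        b1, b2 = call.breakend_1, call.breakend_2
        lines.append(
            "\t".join(
                str(v)
                for v in (
                    b1.chrom,
                    b1.pos - 1,
                    b1.pos,
                    b2.chrom,
                    b2.pos - 1,
                    b2.pos,
                    call.call_id or ".",
                    call.score,
                    _STRAND_OF_ORIENTATION[b1.orientation],
                    _STRAND_OF_ORIENTATION[b2.orientation],
                    call.support,
                    call.svclass,
                    reasons.get(call.call_id, "."),
                )
            )
        )
    _write_with_header(path, lines, seed, config_hash)


def read_bedpe(path) -> tuple[list[JunctionCall], dict[str, str]]:
    """Inverse of :func:`write_bedpe`; returns (calls, rejection reasons)."""
    calls: list[JunctionCall] = []
    reasons: dict[str, str] = {}
    header: Optional[list[str]] = None
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None and fields[0] == "chrom1":
                header = fields
                continue
            if len(fields) < len(BEDPE_COLUMNS):
                raise SchemaError(f"{path}:{lineno}: truncated BEDPE row")
            try:
                support = int(fields[10])
                s1, s2 = fields[8], fields[9]
                call = JunctionCall(
                    breakend_1=Breakend(
                        fields[0], int(fields[2]), _ORIENTATION_OF_STRAND[s1]
                    ),
                    breakend_2=Breakend(
                        fields[3], int(fields[5]), _ORIENTATION_OF_STRAND[s2]
                    ),
                    svclass=fields[11],
                    support=support,
                    plus_reads_1=support if s1 == "+" else 0,
                    minus_reads_1=support if s1 == "-" else 0,
                    plus_reads_2=support if s2 == "+" else 0,
                    minus_reads_2=support if s2 == "-" else 0,
                    score=int(fields[7]),
                    call_id=fields[6],
                )
            except (KeyError, ValueError) as exc:
                raise SchemaError(f"{path}:{lineno}: malformed BEDPE row ({exc})") from exc
            calls.append(call)
            if fields[12] != ".":
                reasons[call.call_id] = fields[12]
    return calls, reasons


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Cytogenetic bands (UCSC cytoBand format)
# ---------------------------------------------------------------------------


def read_cytoband(path) -> BandMap:
    """UCSC cytoBand TSV: chrom, start (0-based), end, band label[, stain]."""
    intervals = []
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise SchemaError(f"{path}:{lineno}: cytoband needs >= 4 columns")
            intervals.append((fields[0], int(fields[1]) + 1, int(fields[2]), fields[3]))
    return BandMap(intervals)


def write_cytoband(band_map: BandMap, path) -> None:
    lines = [
        f"{chrom}\t{start - 1}\t{end}\t{label}"
        for chrom, start, end, label in band_map.intervals
    ]
    _write_with_header(path, lines)


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------


def read_expression_table(path) -> pd.DataFrame:
    """TSV with columns gene, chrom, position, fpkm_case, fpkm_control and an
    optional p_value column."""
    try:
        table = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SchemaError(f"{path}: unreadable expression table ({exc})") from exc
    required = ["gene", "chrom", "position", "fpkm_case", "fpkm_control"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: expression table missing columns {missing}")
    if (table["fpkm_case"] < 0).any() or (table["fpkm_control"] < 0).any():
        raise SchemaError(f"{path}: negative FPKM values")
    return table


def write_expression_table(table: pd.DataFrame, path, seed=None, config_hash=None) -> None:
    cols = list(table.columns)
    lines = ["\t".join(cols)]
    for row in table.itertuples(index=False):
        lines.append("\t".join(str(v) for v in row))
    _write_with_header(path, lines, seed, config_hash)


# ---------------------------------------------------------------------------
# Transcript models (BED12 + optional domain BED)
# ---------------------------------------------------------------------------


def read_transcripts_bed12(path, domains_path=None) -> list[TranscriptModel]:
    """BED12 transcript models: name column = ``gene|transcript_id`` (or the
    transcript id alone); thickStart/thickEnd = CDS.  An optional companion
    BED carries domain intervals with a 4th column ``transcript_id:label``."""
    domain_map: dict[str, list[tuple[str, int, int]]] = {}
    if domains_path is not None:
        with Path(domains_path).open() as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 4 or ":" not in fields[3]:
                    raise SchemaError(
                        f"{domains_path}:{lineno}: domain BED needs a "
                        "'transcript_id:label' name column"
                    )
                tid, label = fields[3].split(":", 1)
                domain_map.setdefault(tid, []).append(
                    (label, int(fields[1]) + 1, int(fields[2]))
                )

    models = []
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise SchemaError(f"{path}:{lineno}: BED12 needs 12 columns")
            try:
                chrom = fields[0]
                chrom_start = int(fields[1])
                name = fields[3]
                strand = fields[5]
                thick_start, thick_end = int(fields[6]), int(fields[7])
                n_blocks = int(fields[9])
                sizes = [int(v) for v in fields[10].rstrip(",").split(",")]
                starts = [int(v) for v in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise SchemaError(f"{path}:{lineno}: malformed BED12 row") from exc
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise SchemaError(f"{path}:{lineno}: block count mismatch")
            gene, _, tid = name.partition("|")
            if not tid:
                gene = tid = name
            exons = [
                (chrom_start + s + 1, chrom_start + s + size)
                for s, size in zip(starts, sizes)
            ]
            if strand == "-":
                exons = exons[::-1]
            cds = (thick_start + 1, thick_end) if thick_end > thick_start else None
            models.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene=gene,
                    chrom=chrom,
                    strand=strand,
                    exons=tuple(exons),
                    cds=cds,
                    domains=tuple(domain_map.get(tid, ())),
                )
            )
    return models


def write_transcripts_bed12(models: Sequence[TranscriptModel], path) -> None:
    lines = []
    for m in models:
        exons = sorted(m.exons)
        chrom_start = exons[0][0] - 1
        chrom_end = exons[-1][1]
        sizes = ",".join(str(e - s + 1) for s, e in exons)
        starts = ",".join(str(s - 1 - chrom_start) for s, _ in exons)
        thick = (m.cds[0] - 1, m.cds[1]) if m.cds else (chrom_start, chrom_start)
        lines.append(
            "\t".join(
                str(v)
                for v in (
                    m.chrom,
                    chrom_start,
                    chrom_end,
                    f"{m.gene}|{m.transcript_id}",
                    0,
                    m.strand,
                    thick[0],
                    thick[1],
                    "0,0,0",
                    len(exons),
                    sizes,
                    starts,
                )
            )
        )
    _write_with_header(path, lines)


# ---------------------------------------------------------------------------
# VCF breakend (BND) output
# ---------------------------------------------------------------------------


def write_vcf_bnd(
    calls: Sequence[JunctionCall],
    chrom_lengths: dict[str, int],
    path,
    seed=None,
    config_hash=None,
) -> None:
    """Minimal VCF 4.2 with one BND record per breakend."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=svrecon_v{__version__}"
        + (f"_seed{seed}" if seed is not None else ""),
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend">',
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting pairs">',
        '##ALT=<ID=BND,Description="Breakend">',
    ]
    for chrom in sorted(chrom_lengths):
        lines.append(f"##contig=<ID={chrom},length={chrom_lengths[chrom]}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")

    def alt_of(be: Breakend, mate: Breakend) -> str:
        mate_loc = f"{mate.chrom}:{mate.pos}"
        if be.orientation == HEAD:
            # partner attached after this base
            return (
                f"N[{mate_loc}[" if mate.orientation == TAIL else f"N]{mate_loc}]"
            )
        return f"]{mate_loc}]N" if mate.orientation == HEAD else f"[{mate_loc}[N"

    for call in calls:
        for idx, (be, mate) in enumerate(
            ((call.breakend_1, call.breakend_2), (call.breakend_2, call.breakend_1)),
            start=1,
        ):
            other = 2 if idx == 1 else 1
            lines.append(
                "\t".join(
                    str(v)
                    for v in (
                        be.chrom,
                        be.pos,
                        f"{call.call_id}_{idx}",
                        "N",
                        alt_of(be, mate),
                        call.score,
                        "PASS",
                        f"SVTYPE=BND;MATEID={call.call_id}_{other};"
                        f"SUPPORT={call.support}",
                    )
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Text reports
# ---------------------------------------------------------------------------


def write_karyotype(karyotype: str, path, seed=None, config_hash=None) -> None:
    """Single-line karyotype file, newline-terminated, after the provenance
    comment."""
    _write_with_header(path, [karyotype], seed, config_hash)


def read_karyotype(path) -> str:
    lines = [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    if len(lines) != 1:
        raise SchemaError(f"{path}: expected exactly one karyotype line")
    return lines[0]


def format_float(x: float) -> str:
    if isinstance(x, float) and math.isnan(x):
        return "NA"
    return str(x)
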