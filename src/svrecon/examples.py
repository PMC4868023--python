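"""Worked example: the complex t(14;18) disrupting TCF4.

This module encodes, as package data, the published complex rearrangement in
which a 0.94 Mb inversion of 18q21.2 plus a 14;18 translocation disrupts
TCF4 and PLEKHG3 and creates a PLEKHG3-TCF4 fusion: the three junction
breakends (hg19), the breakpoint-flanking deletions, the band assignments
used by the case report, an isoform fixture mirroring the TCF4 locus
topology (six long isoforms initiating above the breakpoint, six short ones
initiating below it), and the breakpoint-neighborhood FPKM table.

Coordinates printed in the case report are real hg19 positions; everything
else (exact exon structures, band boundaries) is a SYNTHETIC stand-in built
to reproduce the case's topology, not a copy of RefSeq/UCSC annotation.
"""

from __future__ import annotations

from .core import (
    HEAD,
    INTER_CHROMOSOMAL,
    INVERSION_LIKE,
    TAIL,
    BandMap,
    Breakend,
    ExpressionRecord,
    JunctionCall,
    TranscriptModel,
)

HG19_CHROM_LENGTHS = {"chr14": 107_349_540, "chr18": 78_077_248}

# Breakpoint anatomy (hg19, 1-based inclusive)
CHR14_DELETION = ("chr14", 65_191_595, 65_191_623)  # 29 bp within PLEKHG3 intron 1
CHR18_CENTROMERIC_DELETION = ("chr18", 52_217_704, 52_256_628)  # DYNAP promoter
CHR18_TELOMERIC_DELETION = ("chr18", 53_200_018, 53_219_411)  # within TCF4
INVERSION_SPAN = ("chr18", 52_256_629, 53_200_017)


def _call(be1: Breakend, be2: Breakend, svclass: str, support: int, cid: str) -> JunctionCall:
    return JunctionCall(
        breakend_1=be1,
        breakend_2=be2,
        svclass=svclass,
        support=support,
        plus_reads_1=support if be1.orientation == HEAD else 0,
        minus_reads_1=support if be1.orientation == TAIL else 0,
        plus_reads_2=support if be2.orientation == HEAD else 0,
        minus_reads_2=support if be2.orientation == TAIL else 0,
        score=99,
        call_id=cid,
    )


def tcf4_translocation_junctions() -> list[JunctionCall]:
    """The three novel adjacencies of the derivative chromosomes.

    der(14) joins chr14 (centromeric of the PLEKHG3 intron-1 break) to the
    inverted TCF4 segment head-to-head; the inversion-interior junction joins
    the two tails on chr18; der(18) joins chr18 centromeric of the DYNAP
    break to the telomeric remainder of chr14.  Supports reflect the read
    clusters of the case (30 pairs on chr14; the chr18 signal split 14/16).
    """
    return [
        _call(
            Breakend("chr14", 65_191_594, HEAD),
            Breakend("chr18", 53_200_017, HEAD),
            INTER_CHROMOSOMAL,
            30,
            "t14_18",
        ),
        _call(
            Breakend("chr18", 52_256_629, TAIL),
            Breakend("chr18", 53_219_412, TAIL),
            INVERSION_LIKE,
            16,
            "inv18_interior",
        ),
        _call(
            Breakend("chr18", 52_217_703, HEAD),
            Breakend("chr14", 65_191_624, TAIL),
            INTER_CHROMOSOMAL,
            14,
            "t18_14",
        ),
    ]


def breakpoint_band_fixture() -> BandMap:
    """Bands covering the breakpoints, following the case report's usage.

    SYNTHETIC stand-in: boundaries are approximate, and the label telomeric
    of chr18:53,219,411 is "q21.1" because that is the band the case report
    assigns to the derivative segment starting at 53,219,412 (under UCSC hg19
    banding the position would fall in q21.2; see the methods note).
    """
    return BandMap(
        [
            ("chr14", 64_300_000, 67_400_000, "q23.3"),
            ("chr18", 48_200_000, 53_219_411, "q21.2"),
            ("chr18", 53_219_412, 56_200_000, "q21.1"),
        ]
    )


# ---------------------------------------------------------------------------
# Isoform fixture mirroring the TCF4 locus topology
# ---------------------------------------------------------------------------

# TCF4 is transcribed on the minus strand; long isoforms initiate near the
# telomeric end of the gene (high coordinates, above the 53,200,017 break),
# short isoforms at internal promoters below it.  Shared 3' exons carry the
# NLS, AD2 and bHLH domains; AD1 sits in long-isoform-specific 5' exons.
_SHARED_3P_EXONS = (
    (53_131_307, 53_131_368),  # the coding exon joined by the fusion (real)
    (53_050_000, 53_050_400),
    (52_990_000, 52_990_300),
    (52_902_000, 52_903_000),
)
_TCF4_DOMAINS = (
    ("NLS", 53_050_100, 53_050_160),
    ("AD2", 52_990_050, 52_990_200),
    ("bHLH", 52_902_100, 52_902_400),
    ("AD1", 53_260_100, 53_260_300),
)

INTERRUPTED_TCF4_ISOFORMS = (
    "NM_001243226.1",
    "NM_001243227.1",
    "NM_001243228.1",
    "NM_001243230.1",
    "NM_003199.2",
    "NM_001083962.1",
)
DISTAL_TCF4_ISOFORMS = (
    "NM_001243231.1",
    "NM_001243233.1",
    "NM_001243232.1",
    "NM_001243235.1",
    "NM_001243234.1",
    "NM_001243236.1",
)


def tcf4_isoform_models() -> list[TranscriptModel]:
    """Twelve TCF4-like isoforms plus PLEKHG3 and DYNAP models."""
    models = []
    # long isoforms: TSS above the deletion, span crosses the breakpoint
    for i, tid in enumerate(INTERRUPTED_TCF4_ISOFORMS):
        tss_exon = (53_330_000 - 2_000 * i, 53_332_018 - 2_000 * i)
        ad1_exon = (53_260_000, 53_260_400)
        exons = (tss_exon, ad1_exon) + _SHARED_3P_EXONS
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene="TCF4",
                chrom="chr18",
                strand="-",
                exons=exons,
                cds=(52_902_000, 53_131_368),
                domains=_TCF4_DOMAINS,
            )
        )
    # short isoforms: initiate below the breakpoint, entirely distal
    for i, tid in enumerate(DISTAL_TCF4_ISOFORMS):
        tss_exon = (53_150_000 - 1_000 * i, 53_150_200 - 1_000 * i)
        exons = (tss_exon,) + _SHARED_3P_EXONS[1:]
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene="TCF4",
                chrom="chr18",
                strand="-",
                exons=exons,
                cds=(52_902_000, 53_050_400),
                domains=_TCF4_DOMAINS[:3],  # no AD1 exon in short isoforms
            )
        )
    # PLEKHG3: plus strand on chr14, first (non-coding) exon is real; the
    # intron-1 breakpoint at 65,191,59x falls before the downstream exons
    models.append(
        TranscriptModel(
            transcript_id="NM_015549.1",
            gene="PLEKHG3",
            chrom="chr14",
            strand="+",
            exons=(
                (65_171_193, 65_171_422),
                (65_192_500, 65_192_800),
                (65_196_000, 65_196_400),
            ),
            cds=(65_192_520, 65_196_380),
        )
    )
    # DYNAP: promoter and first exon inside the centromeric chr18 deletion
    models.append(
        TranscriptModel(
            transcript_id="NM_173629",
            gene="DYNAP",
            chrom="chr18",
            strand="-",
            exons=(
                (52_255_500, 52_256_100),
                (52_240_000, 52_240_500),
            ),
            cds=(52_240_050, 52_240_450),
        )
    )
    return models


# ---------------------------------------------------------------------------
# Breakpoint-neighborhood expression table (FPKM and p-values as reported)
# ---------------------------------------------------------------------------

_NEIGHBORHOOD_ROWS = [
    # (gene, chrom, fpkm_case, fpkm_control, p_value)
    ("MBD2", "chr18", 10.0, 9.0, 0.250),
    ("SNORA37", "chr18", 0.0, 0.0, 1.000),
    ("POLI", "chr18", 3.7, 2.7, 0.001),
    ("STARD6", "chr18", 0.0, 0.0, 1.000),
    ("C18orf54", "chr18", 3.0, 1.4, 0.000),
    ("DYNAP", "chr18", 2.6, 0.0, 0.000),
    ("RAB27B", "chr18", 0.6, 1.7, 0.000),
    ("CCDC68", "chr18", 0.3, 1.1, 0.000),
    ("TCF4", "chr18", 17.6, 21.5, 0.026),
    ("LOC100505474", "chr18", 0.0, 0.0, 1.000),
    ("TXNL1", "chr18", 22.5, 25.7, 0.155),
    ("WDR7", "chr18", 6.7, 6.4, 0.563),
    ("BOD1P", "chr18", 0.0, 0.0, 1.000),
    ("TEX21P", "chr14", 0.1, 0.1, 1.00),
    ("MTHFD1", "chr14", 32.0, 29.4, 0.36),
    ("AKAP5", "chr14", 0.1, 0.5, 0.00),
    ("ZBTB25", "chr14", 2.4, 2.5, 0.66),
    ("ZBTB1", "chr14", 13.2, 14.6, 0.28),
    ("HSPA2", "chr14", 53.3, 120.4, 0.00),
    ("PPP1R36", "chr14", 0.3, 0.3, 0.71),
    ("PLEKHG3", "chr14", 2.5, 3.2, 0.02),
    ("SPTB", "chr14", 0.0, 0.1, 1.00),
    ("CHURC1,CHURC1-FNTB,FNTB", "chr14", 20.3, 20.4, 0.97),
    ("GPX2", "chr14", 0.0, 0.0, 1.00),
    ("LOC100506321", "chr14", 0.0, 0.1, 1.00),
    ("MAX", "chr14", 23.2, 18.8, 0.26),
    ("MIR4706", "chr14", 0.0, 0.0, 1.00),
    ("RAB15", "chr14", 3.4, 2.3, 0.23),
]


def neighborhood_expression_records() -> list[ExpressionRecord]:
    """The reported FPKM/p-value rows for the genes flanking the breakpoints
    (positions are rank placeholders; only ordering matters here)."""
    return [
        ExpressionRecord(
            gene=gene,
            chrom=chrom,
            position=(i + 1) * 100_000,
            fpkm_case=case,
            fpkm_control=control,
            p_value=p,
        )
        for i, (gene, chrom, case, control, p) in enumerate(_NEIGHBORHOOD_ROWS)
    ]


LOW_EXPRESSION_FOOTNOTE_GENES = {
    "POLI",
    "C18orf54",
    "DYNAP",
    "RAB27B",
    "CCDC68",
    "AKAP5",
    "PLEKHG3",
}

REVISED_KARYOTYPE = (
    "46,XY,del(14)(q23.3q23.3)del(18)(q21.2q21.2)del(18)(q21.2q21.2)"
    "inv(18)(q21.2q21.2)t(14;18)(q23.3;q21.2)"
    "(14pter→14q23.3::18q21.2→18q21.2::18q21.1→18qter;"
    "18pter→18q21.2::14q23.3→14qter)"
)
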