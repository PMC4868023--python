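"""End-to-end orchestration with a YAML config and deterministic outputs.

Stages run in order: simulate (optional) -> detect -> filter -> reconstruct
-> consequence -> expression.  Every output file carries a provenance header
(tool version, config hash, seed) and a rerun with the same config produces
byte-identical summaries.  On stage failure the partial outputs written so
far are retained and listed in ``manifest.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import io as svio
from .consequence import classify_transcripts, predict_fusions
from .core import (
    BandMap,
    FilterParams,
    ParameterError,
    ScanParams,
)
from .detection import (
    cluster_discordant,
    estimate_insert_stats,
    filter_calls,
    score_calls,
)
from .expression import permutation_null, window_correlation_scan
from .reconstruction import (
    assemble_derivatives,
    build_breakpoint_graph,
    deletion_sizes,
    infer_events,
    junction_reference_sequence,
    karyotype_string,
)
from .synthetic import (
    apply_rearrangement,
    build_toy_genome,
    demo_rearrangement_spec,
    demo_transcript_models,
    generate_filter_tracks,
    pairs_for_depth,
    simulate_expression_profiles,
    simulate_read_pairs,
)

logger = logging.getLogger("svrecon")


@dataclass
class PipelineConfig:
    """Run configuration; defaults reproduce the packaged demo."""

    seed: int = 1
    outdir: str = "svrecon_run"
    # stage toggles
    simulate: bool = True
    run_consequence: bool = True
    run_expression: bool = True
    # synthetic-genome stage
    n_chroms: int = 2
    length_bp: int = 500_000
    gc: float = 0.4
    depth: float = 30.0
    insert_mean: float = 308.0
    insert_sd: float = 30.0
    read_len: int = 100
    background_discordant_rate: float = 0.0
    n_track_intervals: int = 0
    write_pairs: bool = False
    # detection stage
    insert_k: float = 3.0
    score_background_rate: float = 0.1
    filter_params: FilterParams = field(default_factory=FilterParams)
    # expression stage
    scan_params: ScanParams = field(default_factory=lambda: ScanParams(n_permutations=200))
    n_genes: int = 60
    expression_noise_sd: float = 0.25
    # external inputs (used when simulate is False)
    pair_table: Optional[str] = None
    track_beds: tuple[str, ...] = ()
    reference_fasta: Optional[str] = None
    cytoband: Optional[str] = None
    expression_table: Optional[str] = None
    transcripts_bed12: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "filter_params" in raw:
            raw["filter_params"] = FilterParams(**raw["filter_params"])
        if "scan_params" in raw:
            raw["scan_params"] = ScanParams(**raw["scan_params"])
        if "track_beds" in raw:
            raw["track_beds"] = tuple(raw["track_beds"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; return the machine-readable summary.

    Outputs are written under ``config.outdir``; the summary is also written
    to ``summary.json`` there.  Rerunning with the same config reproduces the
    summary bit for bit.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash
    seed = config.seed
    manifest: list[str] = []
    summary: dict = {
        "seed": seed,
        "config_hash": chash,
        "stages": [],
        "notices": [],
    }

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        manifest.append(name)

    try:
        _run_stages(config, outdir, summary, emit)
    finally:
        (outdir / "manifest.json").write_text(
            json.dumps({"config_hash": chash, "seed": seed, "files": manifest}, indent=2)
            + "\n"
        )
    blob = json.dumps(summary, indent=2, sort_keys=True, allow_nan=True)
    (outdir / "summary.json").write_text(blob + "\n")
    return summary


def _run_stages(config: PipelineConfig, outdir: Path, summary: dict, emit) -> None:
    chash = config.config_hash
    seed = config.seed

    # ---- simulate ---------------------------------------------------------
    band_map: Optional[BandMap] = None
    ref_sequences: Optional[dict[str, str]] = None
    truth = None
    spec = None
    if config.simulate:
        summary["stages"].append("simulate")
        ref = build_toy_genome(
            config.n_chroms,
            config.length_bp,
            config.gc,
            seed=seed,
            names=["chrA", "chrB"] if config.n_chroms == 2 else None,
        )
        band_map = BandMap(ref.band_map)
        ref_sequences = dict(ref.chromosomes)
        chrom_lengths = ref.lengths
        spec = demo_rearrangement_spec(ref)
        derived, truth = apply_rearrangement(ref, spec)
        tracks = generate_filter_tracks(ref, config.n_track_intervals, seed=seed + 1)
        n_pairs = pairs_for_depth(derived, config.depth, config.read_len)
        pairs = simulate_read_pairs(
            derived,
            n_pairs,
            insert_mean=config.insert_mean,
            insert_sd=config.insert_sd,
            read_len=config.read_len,
            seed=seed + 2,
            background_discordant_rate=config.background_discordant_rate,
        )
        emit("reference.fasta", lambda p: svio.write_fasta(ref_sequences, p))
        emit("derivatives.fasta", lambda p: svio.write_fasta(
            {n: derived.sequences[n] for n in derived.sequences}, p))
        emit("truth_junctions.bedpe", lambda p: svio.write_bedpe(
            truth.junctions, p, seed=seed, config_hash=chash))
        if config.write_pairs:
            emit("pairs.tsv", lambda p: svio.write_pair_table(
                pairs, p, seed=seed, config_hash=chash))
        summary["n_pairs"] = int(len(pairs))
        summary["truth_junctions"] = len(truth.junctions)
    else:
        if config.pair_table is None:
            raise ParameterError("pair_table is required when simulate is false")
        pairs = svio.read_pair_table(config.pair_table)
        tracks = {f"track_{i}": svio.read_bed(p) for i, p in enumerate(config.track_beds)}
        if config.reference_fasta:
            ref_sequences = svio.read_fasta(config.reference_fasta)
            chrom_lengths = {n: len(s) for n, s in ref_sequences.items()}
        else:
            raise ParameterError("reference_fasta is required when simulate is false")
        if config.cytoband:
            band_map = svio.read_cytoband(config.cytoband)
        summary["n_pairs"] = int(len(pairs))

    # ---- detect + filter --------------------------------------------------
    summary["stages"].append("detect")
    if pairs.empty:
        summary["notices"].append("empty pair table; downstream stages skipped")
        emit("junctions.bedpe", lambda p: svio.write_bedpe([], p, seed=seed, config_hash=chash))
        summary.update(n_calls=0, n_retained=0, retained=[])
        return
    stats = estimate_insert_stats(pairs, k=config.insert_k, read_len=config.read_len)
    summary["insert_median"] = stats.median
    calls = cluster_discordant(
        pairs,
        stats,
        min_mapq=config.filter_params.min_mapq,
        min_reads_call=config.filter_params.min_reads_call,
        read_len=config.read_len,
    )
    score_calls(calls, config.score_background_rate)
    retained, rejected = filter_calls(calls, tracks, config.filter_params)
    reasons = {c.call_id: r for c, r in rejected}
    emit("junctions.bedpe", lambda p: svio.write_bedpe(
        calls, p, reasons=reasons, seed=seed, config_hash=chash))
    emit("retained.bedpe", lambda p: svio.write_bedpe(
        retained, p, seed=seed, config_hash=chash))
    summary["n_calls"] = len(calls)
    summary["n_retained"] = len(retained)
    summary["retained"] = [
        {
            "id": c.call_id,
            "class": c.svclass,
            "support": c.support,
            "score": c.score,
            "breakend_1": [c.breakend_1.chrom, c.breakend_1.pos, c.breakend_1.orientation],
            "breakend_2": [c.breakend_2.chrom, c.breakend_2.pos, c.breakend_2.orientation],
        }
        for c in retained
    ]
    if not retained:
        summary["notices"].append("no retained junctions; reconstruction skipped")
        return

    # ---- reconstruct ------------------------------------------------------
    summary["stages"].append("reconstruct")
    graph = build_breakpoint_graph(
        retained, chrom_lengths, merge_slop=int(round(stats.mean))
    )
    derivatives = assemble_derivatives(graph)
    rearranged = [d for d in derivatives if not d.is_reference]
    deletions = deletion_sizes(graph)
    summary["derivatives"] = {
        d.name: [[s.chrom, s.start, s.end, s.sign] for s in d.segments]
        for d in rearranged
    }
    summary["n_derivatives"] = len(rearranged)
    summary["deleted_bases"] = {
        f"{iv.chrom}:{iv.start}-{iv.end}": size for iv, size in deletions.items()
    }
    seg_lines = ["derivative\tchrom\tstart\tend\tsign"]
    for d in rearranged:
        for s in d.segments:
            seg_lines.append(f"{d.name}\t{s.chrom}\t{s.start}\t{s.end}\t{s.sign}")
    emit("segments.tsv", lambda p: svio.write_lines(p, seg_lines, seed, chash))
    emit("junctions.vcf", lambda p: svio.write_vcf_bnd(
        retained, chrom_lengths, p, seed=seed, config_hash=chash))
    if band_map is not None:
        events = infer_events(graph, derivatives)
        karyotype = karyotype_string(derivatives, events, band_map, chrom_lengths)
        summary["karyotype"] = karyotype
        emit("karyotype.txt", lambda p: svio.write_karyotype(
            karyotype, p, seed=seed, config_hash=chash))
    if ref_sequences is not None and rearranged:
        junction_seqs = {}
        for d in rearranged:
            for j in range(len(d.segments) - 1):
                junction_seqs[f"{d.name}_junction_{j + 1}"] = (
                    junction_reference_sequence(ref_sequences, d, j, flank=60)
                )
        emit("junction_sequences.fasta", lambda p: svio.write_fasta(junction_seqs, p))

    # ---- consequence ------------------------------------------------------
    if config.run_consequence:
        summary["stages"].append("consequence")
        if config.simulate and spec is not None:
            models = demo_transcript_models(spec)
        elif config.transcripts_bed12:
            models = svio.read_transcripts_bed12(config.transcripts_bed12)
        else:
            models = []
            summary["notices"].append("no transcript models; consequence skipped")
        if models:
            # classify against the junction of the derivative carrying the
            # disrupted locus (chromosome B side of the translocation)
            der_a = rearranged[0]
            adj = der_a.adjacencies[0] if der_a.adjacencies else None
            b_chrom = adj.right.chrom if adj else retained[0].breakend_2.chrom
            breakends = [
                be
                for c in retained
                for be in (c.breakend_1, c.breakend_2)
                if be.chrom == b_chrom
            ]
            # restrict to the telomeric (disrupting) breakpoint neighborhood
            bp = max(breakends, key=lambda b: b.pos) if breakends else None
            dels = [iv for iv in deletions if iv.chrom == b_chrom]
            focal = [b for b in breakends if abs(b.pos - bp.pos) <= 50_000] if bp else []
            b_models = [m for m in models if m.chrom == b_chrom]
            a_models = [m for m in models if m.chrom != b_chrom]
            calls_b = classify_transcripts(b_models, focal or breakends, dels) if b_models else []
            summary["consequence"] = {
                c.transcript_id: c.status for c in calls_b
            }
            cons_lines = ["transcript_id\tstatus\tbreakpoint"]
            for c in calls_b:
                bp_str = (
                    f"{c.breakpoint.chrom}:{c.breakpoint.pos}" if c.breakpoint else "."
                )
                cons_lines.append(f"{c.transcript_id}\t{c.status}\t{bp_str}")
            emit("consequence.tsv", lambda p: svio.write_lines(
                p, cons_lines, seed, chash))
            if adj is not None:
                fusions = predict_fusions(adj, a_models + b_models)
                summary["fusions"] = [f.name for f in fusions]

    # ---- expression -------------------------------------------------------
    if config.run_expression:
        summary["stages"].append("expression")
        if config.simulate:
            chrom_b = "chrB" if "chrB" in chrom_lengths else sorted(chrom_lengths)[-1]
            step = chrom_lengths[chrom_b] // (config.n_genes + 1)
            genes = [
                (f"g{i:03d}", chrom_b, (i + 1) * step) for i in range(config.n_genes)
            ]
            table, _ = simulate_expression_profiles(
                genes, effect=None, noise_sd=config.expression_noise_sd, seed=seed + 3
            )
        elif config.expression_table:
            table = svio.read_expression_table(config.expression_table)
        else:
            summary["notices"].append("no expression table; expression skipped")
            return
        scan = window_correlation_scan(table, config.scan_params)
        p, reject = permutation_null(table, config.scan_params, seed=seed + 4)
        scan.p_value = p
        summary["scan"] = {
            "n_windows": int(len(scan.window_r)),
            "n_candidates": len(scan.candidates),
            "p_value": p,
            "reject_null": bool(reject),
        }
        lines = ["window\tr"]
        for i, r in enumerate(scan.window_r):
            lines.append(f"{i}\t{svio.format_float(float(r))}")
        emit("expression_scan.tsv", lambda p_: svio.write_lines(
            p_, lines, seed, chash))


def run_from_yaml(path) -> dict:
    return run_pipeline(PipelineConfig.from_yaml(path))
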