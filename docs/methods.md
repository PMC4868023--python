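# Methods

This note documents the models and procedures implemented in `svrecon`, the
parameters that matter, the design choices made where the design was open,
and what the synthetic-data tests do and do not establish.

## Coordinates and breakends

All public coordinates are 1-based inclusive; BED/BEDPE conversion to
0-based half-open happens only in `svrecon.io`. A breakend
`(chrom, pos, orientation)` names one oriented side of a novel adjacency:
`head` means the junction uses the `[1..pos]` side of the chromosome (the
partner ligates to the right of `pos`), `tail` the `[pos..end]` side.
Because strand signs compose through inverted segments, plus-strand read
evidence always supports a `head` breakend and minus-strand evidence a
`tail` breakend — this holds for every junction type, including both sides
of an inversion.

## Read-pair detection

*Insert statistics.* The concordant insert distribution is estimated from
same-chromosome FR pairs as the outer span `mate_pos − pos + read_len`
(read length is a parameter, default 100 bp, because the pair table carries
no per-read length). The concordant envelope is `mean + k·sd` with k = 3 by
default; FR pairs beyond it are deletion-like, same-strand pairs
inversion-like, RF pairs duplication-like, and cross-chromosome pairs
inter-chromosomal.

*Clustering.* Discordant pairs are grouped by (class, chromosome pair,
strand pair) and single-linkage clustered requiring a gap of at most one
concordant envelope at **both** breakends. The call breakend is the
innermost aligned coordinate of the cluster: rightmost read end
(`max(pos) + read_len − 1`) on the `head` side, leftmost read start on the
`tail` side.

*Scoring.* The published pipeline used an external caller's opaque score
with a "score ≥ 99" cutoff; to keep that stringency knob meaningful we
define a reproducible one-parameter replacement: a Poisson-tail phred score
`min(99, round(−10·log₁₀ P[X ≥ support]))`, `X ~ Poisson(λ_bg)` with λ_bg
the expected spurious discordant pairs per clustering window (default 0.1
in the pipeline). The score is monotone in support; support 0 scores 0.

*Filter cascade.* Defaults follow the published criteria exactly: mapping
quality ≥ 35 (applied before clustering), ≥ 2 pairs to form a call,
support ≥ 12, at most 60 reads of one strand per breakend, score ≥ 99, and
rejection when either breakend lies within ±500 bp (inclusive at exactly
500) of any interval of the three exclusion tracks. The "1001 bp window
centered on a translocation breakpoint" is the same predicate
(`|x − breakend| ≤ 500`) and is implemented once. Rejected calls carry the
first matching reason in the fixed order support → strand cap → score →
tracks; this machine-readable rejection list stands in for the original
manual IGV review, which is a human step and out of scope.

## Derivative reconstruction

Breakends cut the reference chromosomes; segment ends are wired by novel
adjacencies and each derivative is the walk from a pter-bearing segment,
alternating segments and novel edges, to a qter end. Each segment may be
used once (a revisit raises a reconstruction error; a free interior end
yields an incomplete-derivative warning rather than a guess). Interior
segments with no novel edge are the breakpoint-flanking deletions; sizes
are inclusive (`end − start + 1`), which reproduces the case's 29 bp and
19,394 bp exactly. The case report prints the third deletion as
"38,926 bases", but its own printed coordinates (chr18:52,217,704–52,256,628)
give 38,925; we reproduce the coordinate arithmetic and do not force the
rounded prose value. Likewise the inversion is quoted both as "0.98 Mb" and
"943,387 bases"; the strict interior of the printed breakpoints is 943,387.

*Breakpoint reconciliation (`merge_slop`).* Cluster-estimated breakpoints
carry up to ~half-a-read of jitter, because reads crossing a junction are
assigned to the majority segment. Around a small breakpoint-flanking
deletion (29 bp here) the two estimated cuts can cross each other, which
would corrupt the graph. `build_breakpoint_graph(..., merge_slop=s)`
therefore merges cuts closer than `s` (use about one insert length, the
scale of breakpoint uncertainty) into one representative cut; a deletion
smaller than the slop is then reported as absent rather than mis-ordered.
Truth junctions with exact coordinates use slop 0.

*Karyotype rendering.* Event terms are ordered deletions → inversions →
translocations, then by chromosome and position, matching the case report's
revised-karyotype style; each rearranged derivative is rendered
pter→qter with `::` separators, minus-sign segments written high→low. The
shipped band fixture for the case (`svrecon.examples.breakpoint_band_fixture`)
is a synthetic stand-in that follows the **report's own band usage**,
including its label "18q21.1" for the segment starting at chr18:53,219,412;
under UCSC hg19 banding that position falls in q21.2 and the rendered
string would differ in that one token. The fixture is honest about this in
its docstring; users analysing real data should supply a UCSC cytoBand
file.

## Transcript consequences

"Upstream/downstream of the breakpoint" is defined in transcription order,
not genomic order — necessary because *TCF4* is transcribed on the minus
strand. A transcript is interrupted when its genomic span contains a
breakend or intersects a deleted interval (this covers promoter loss: a TSS
inside a deletion, the *DYNAP* situation); otherwise intact-distal when it
lies entirely on the downstream side of the breakpoints along its own
strand, else intact-proximal. Classification is per breakpoint set: the
isoform panel is classified against the breakpoint within its own locus,
not against every breakend on the chromosome.

Fusions across a derivative adjacency pair every gene interrupted by the
left breakend and transcribed toward the junction **on the derivative**
(reference strand composed with segment sign) with every gene interrupted
by the right breakend and transcribed away from it; retained exons are
those wholly on the ligated side of each breakend. Reading-frame remarks
are annotation-level only (no splicing simulation). A domain is retained
iff its genomic interval lies within the union of retained exon intervals.

## Expression statistics

*Fold changes.* `log_fold_change(a, b, base, ψ) = log_base((b+ψ)/(a+ψ))`.
Two conventions coexist deliberately: the neighborhood table uses base 2,
ψ = 0, control/case — the convention under which the case report's printed
per-gene values reproduce exactly (TCF4 0.29, HSPA2 1.18) despite its
column header and its Methods' "base 10 with pseudo-count 1" — while the
window scan adds ψ = 1 FPKM per the Methods. Both are explicit parameters.

*Neighborhood table.* p-values are inputs (upstream differential testing is
out of scope); q-values are Benjamini–Hochberg over the table. A row is
footnoted *low expression* when it is nominally significant (p ≤ α) but
`max(FPKM_case, FPKM_control) < 5` — the threshold 5 FPKM is a
reconstruction chosen because it exactly separates the case report's
footnoted rows (max ≤ 3.7) from its interpretable significant row (HSPA2,
53.3); it is not a value stated by the source. The `significant` flag
additionally requires q ≤ α and adequate expression.

*Window scan.* For windows of w = 3 positionally consecutive genes
(step 1), `r_i` is the Pearson correlation between case and control
log-abundance vectors; the window-pair matrix `M_ij` is the Pearson
correlation of window fold-change vectors over all window pairs.
Zero-variance windows are recorded as missing and break runs. Candidate
regions are maximal runs with `r_i ≤ τ` (τ = −0.8 by default). With w = 3 a
parametric Pearson test is meaningless, so inference is purely by
permutation: gene order is shuffled within the chromosome (case/control
pairing preserved), the statistic is the largest summed exceedance
`Σ(τ − r_i)` over any run, and `p = (1 + #{perm ≥ obs})/(1 + N)`.

*Panel, qPCR, droplets.* nCounter-style normalisation divides each sample's
counts by its housekeeping geometric mean (rescaled by the grand geometric
mean), making ratios invariant to per-sample scaling; qPCR uses
2^(−ΔΔCt) against a reference gene and calibrator sample; droplet counts
are Poisson-corrected (`λ = −ln(1 − positives/total)`) and allele fractions
are ratios of λ. A saturated assay raises rather than returning infinity.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* of the source experiment: a
two-chromosome reference (six bands each), the three-break mechanism with
breakpoint-flanking deletions of 29 bp / ~3.9 kb / ~1.9 kb (the real sizes,
scaled tenfold for the kb-scale deletions to fit 500 kb toy chromosomes),
already-aligned 100 bp read pairs with normal 308 ± 30 inserts truncated at
2×read length (the analysis starts from alignments, so no sequence-level
aligner is modelled), and lognormal expression tables (log2-normal, mean 3,
sd 1.5 — a realistic bulk-RNA-seq spread) with injectable regional
anti-correlation or per-gene shifts. It does **not** model base-call
errors, quality strings, GC bias, mappability, real aligner soft-clipping
or multi-mapping; a green round-trip test therefore establishes the
correctness of the classification/clustering/assembly logic on ideal
alignments, not robustness to alignment artefacts. Junction-crossing reads
are assigned to the majority segment, which is what gives the estimated
breakpoints their ±half-read jitter and makes the reconciliation step above
necessary — a deliberate, realistic imperfection.

Calibration tests draw case and control as two *independent* lognormal
profiles: with the truth-preserving generator (`effect=None`), case equals
control plus noise, every window correlates positively and the permutation
statistic degenerates to zero, so independence is the correct null for
p-value uniformity.

## Defaults worth knowing

| parameter | default | meaning |
|---|---|---|
| `FilterParams.min_mapq` | 35 | mapping-quality floor before clustering |
| `FilterParams.min_reads_call` | 2 | pairs to form a cluster |
| `FilterParams.min_support` | 12 | pairs to survive filtering |
| `FilterParams.max_strand_reads` | 60 | per-breakend strand cap (high-depth guard) |
| `FilterParams.min_score` | 99 | Poisson-phred floor |
| `FilterParams.track_window_bp` | 500 | ±window, inclusive at 500 |
| `estimate_insert_stats(k)` | 3 | concordant envelope multiplier |
| `ScanParams.window_w` | 3 | genes per scan window |
| `ScanParams.anticorrelation_threshold` | −0.8 | run membership |
| `ScanParams.pseudo_count` | 1 FPKM | added before logs in the scan |
| `score background rate` | 0.1 | expected spurious pairs per window |
| `merge_slop` (pipeline) | insert mean | breakpoint reconciliation scale |

## Known limitations

- The detector is a single self-defined read-pair caller; it does not
  reimplement any published caller's internals, and no split-read or
  assembly refinement is performed, so breakpoint precision is limited to
  roughly half a read length.
- Derivative walks require each segment end to carry at most one novel
  adjacency; more complex graphs return all maximal walks (with warnings)
  rather than guessing, and event *order/mechanism* is never inferred —
  only the final structure.
- Copy-number calling from depth, SNV pathogenicity ranking and read-level
  RNA-seq processing are out of scope; FPKM tables and per-gene p-values
  are inputs.
- The case-report band fixture intentionally mirrors the publication's
  internally inconsistent band usage (see above) and must not be used as a
  real hg19 cytoband source.
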