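"""Expression statistics around rearrangement breakpoints.

Implements the expression side of the analysis: pseudo-counted log fold
changes, the breakpoint-neighborhood differential table, a sliding-window
Pearson correlation scan along a chromosome with a gene-order permutation
null (the test for positional anti-correlation signatures), ddCt relative
quantification, housekeeping geometric-mean panel normalisation, and
Poisson-corrected droplet-count allele fractions.

Two fold-change conventions coexist deliberately: the neighborhood table
reports log2(control/case) with no pseudo-count (the convention under which
the published per-gene values reproduce exactly), while the scan adds a
pseudo-count of 1 FPKM before taking logs to damp low-expression ratios.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import (
    ExpressionRecord,
    ParameterError,
    SaturationError,
    ScanParams,
    ScanResult,
    SchemaError,
    UndefinedValueError,
)

# ---------------------------------------------------------------------------
# Fold changes
# ---------------------------------------------------------------------------


def log_fold_change(
    fpkm_a: float, fpkm_b: float, base: float = 2, pseudo: float = 0.0
) -> float:
    """log_base((fpkm_b + pseudo) / (fpkm_a + pseudo)).

    Antisymmetric in its two abundance arguments.  With pseudo 0 a zero
    denominator is undefined (raises); a zero numerator returns -inf.
    """
    if fpkm_a < 0 or fpkm_b < 0 or pseudo < 0:
        raise ParameterError("FPKM and pseudo-count must be non-negative")
    if base not in (2, 10):
        raise ParameterError("base must be 2 or 10")
    denom = fpkm_a + pseudo
    numer = fpkm_b + pseudo
    if denom == 0:
        raise UndefinedValueError("zero denominator with pseudo-count 0")
    if numer == 0:
        return -math.inf
    return math.log(numer / denom, base)


def neighborhood_table(
    records: Sequence[ExpressionRecord],
    low_fpkm_threshold: float = 5.0,
    alpha: float = 0.05,
    base: float = 2,
    pseudo: float = 0.0,
) -> pd.DataFrame:
    """Differential report for the genes around a breakpoint.

    Fold change is log_base(control/case) (pseudo-counted only on request); a
    row is footnoted *low expression* when it would be called at ``alpha`` but
    neither condition reaches ``low_fpkm_threshold`` FPKM — too low to
    interpret.  The ``significant`` flag requires p <= alpha, a
    Benjamini-Hochberg q <= alpha over the table, and adequate expression.
    p-values are inputs carried on the records (upstream differential
    testing), not recomputed here.
    """
    if not 0 < alpha < 1:
        raise ParameterError("alpha must lie in (0, 1)")
    if not records:
        return pd.DataFrame(
            columns=[
                "gene",
                "chrom",
                "fpkm_case",
                "fpkm_control",
                "log_fc",
                "p_value",
                "q_value",
                "significant",
                "low_expression",
            ]
        )
    rows = []
    for rec in records:
        try:
            lfc = log_fold_change(rec.fpkm_case, rec.fpkm_control, base, pseudo)
        except UndefinedValueError:
            lfc = math.nan
        rows.append(
            {
                "gene": rec.gene,
                "chrom": rec.chrom,
                "fpkm_case": rec.fpkm_case,
                "fpkm_control": rec.fpkm_control,
                "log_fc": lfc,
                "p_value": rec.p_value if rec.p_value is not None else math.nan,
            }
        )
    table = pd.DataFrame(rows)
    pvals = table["p_value"].to_numpy(dtype=float)
    q = np.full_like(pvals, math.nan)
    ok = ~np.isnan(pvals)
    if ok.any():
        q[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    table["q_value"] = q
    low = np.maximum(table["fpkm_case"], table["fpkm_control"]) < low_fpkm_threshold
    nominal = table["p_value"] <= alpha
    table["low_expression"] = (nominal & low).to_numpy()
    table["significant"] = (nominal & (table["q_value"] <= alpha) & ~low).to_numpy()
    return table


# ---------------------------------------------------------------------------
# Windowed correlation scan
# ---------------------------------------------------------------------------


def _window_pearson(x: np.ndarray, y: np.ndarray, w: int) -> np.ndarray:
    """Pearson r between x and y over every length-w sliding window."""
    xw = np.lib.stride_tricks.sliding_window_view(x, w)
    yw = np.lib.stride_tricks.sliding_window_view(y, w)
    xm = xw - xw.mean(axis=1, keepdims=True)
    ym = yw - yw.mean(axis=1, keepdims=True)
    num = (xm * ym).sum(axis=1)
    den = np.sqrt((xm**2).sum(axis=1) * (ym**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den == 0] = np.nan
    return np.clip(r, -1.0, 1.0)


def _anticorrelation_runs(
    window_r: np.ndarray, threshold: float
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive windows with r <= threshold (NaN breaks)."""
    flags = np.where(np.isnan(window_r), False, window_r <= threshold)
    runs = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(flags) - 1))
    return runs


def _log_vectors(
    table: pd.DataFrame, params: ScanParams
) -> tuple[np.ndarray, np.ndarray]:
    case = table["fpkm_case"].to_numpy(dtype=float) + params.pseudo_count
    control = table["fpkm_control"].to_numpy(dtype=float) + params.pseudo_count
    if (case <= 0).any() or (control <= 0).any():
        raise UndefinedValueError("zero FPKM requires a positive pseudo-count")
    log = np.log2 if params.log_base == 2 else np.log10
    return log(case), log(control)


def window_correlation_scan(
    records: pd.DataFrame | Sequence[ExpressionRecord],
    params: ScanParams = ScanParams(),
) -> ScanResult:
    """Sliding-window case/control correlation along one chromosome.

    For each window of ``window_w`` positionally consecutive genes (step 1),
    ``r_i`` is the Pearson correlation between the case and control log
    abundance vectors.  ``pair_matrix[i, j]`` is the Pearson correlation of
    the window fold-change vectors of windows i and j (all window pairs).
    Candidate regions are maximal runs of windows with
    r_i <= anticorrelation_threshold; zero-variance windows are recorded as
    missing and excluded from runs.
    """
    table = _as_table(records)
    if len(table) < params.window_w:
        raise ParameterError(
            f"need at least window_w={params.window_w} genes, got {len(table)}"
        )
    x, y = _log_vectors(table, params)
    w = params.window_w
    window_r = _window_pearson(x, y, w)

    f = x - y  # per-gene log fold change
    fw = np.lib.stride_tricks.sliding_window_view(f, w)
    fm = fw - fw.mean(axis=1, keepdims=True)
    norms = np.sqrt((fm**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = fm / norms[:, None]
    pair_matrix = unit @ unit.T
    np.fill_diagonal(pair_matrix, 1.0)
    pair_matrix[norms == 0, :] = np.nan
    pair_matrix[:, norms == 0] = np.nan
    pair_matrix = np.clip(pair_matrix, -1.0, 1.0)

    candidates = _anticorrelation_runs(window_r, params.anticorrelation_threshold)
    return ScanResult(
        window_r=window_r,
        pair_matrix=pair_matrix,
        candidates=candidates,
        genes=list(table["gene"]),
    )


def _as_table(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        missing = {"gene", "fpkm_case", "fpkm_control"} - set(records.columns)
        if missing:
            raise SchemaError(f"expression table lacks columns {sorted(missing)}")
        return records
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "chrom": [r.chrom for r in records],
            "position": [r.position for r in records],
            "fpkm_case": [r.fpkm_case for r in records],
            "fpkm_control": [r.fpkm_control for r in records],
        }
    )


def _run_statistic(window_r: np.ndarray, threshold: float) -> float:
    """Length-weighted strength of the best anti-correlation run: the largest
    summed exceedance sum(threshold - r_i) over any maximal run."""
    runs = _anticorrelation_runs(window_r, threshold)
    if not runs:
        return 0.0
    return max(
        float(np.sum(threshold - window_r[a : b + 1])) for a, b in runs
    )


def permutation_null(
    records: pd.DataFrame | Sequence[ExpressionRecord],
    params: ScanParams = ScanParams(),
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """Permutation test for a positional anti-correlation signature.

    Gene order is shuffled within the chromosome (case/control pairing per
    gene preserved), the run statistic recomputed each time, and
    ``p = (1 + #{perm >= observed}) / (1 + n_permutations)``.  Returns
    (p_value, reject) where reject means the observed positional signal is
    unlikely under random gene placement at level ``alpha``.
    """
    table = _as_table(records)
    x, y = _log_vectors(table, params)
    w, tau = params.window_w, params.anticorrelation_threshold
    observed = _run_statistic(_window_pearson(x, y, w), tau)
    rng = np.random.default_rng(seed)
    n = len(x)
    count = 0
    for _ in range(params.n_permutations):
        perm = rng.permutation(n)
        stat = _run_statistic(_window_pearson(x[perm], y[perm], w), tau)
        if stat >= observed:
            count += 1
    p = (1 + count) / (1 + params.n_permutations)
    return p, p <= alpha


# ---------------------------------------------------------------------------
# qPCR ddCt
# ---------------------------------------------------------------------------


def qpcr_relative_expression(
    ct_table: pd.DataFrame, reference_gene: str, calibrator_sample: str
) -> pd.DataFrame:
    """2^(-ddCt) relative expression.

    dCt = Ct_target - Ct_reference within each sample; ddCt subtracts the
    calibrator sample's dCt, so the calibrator reads 1 by construction.
    """
    for col in ("sample", "gene", "ct"):
        if col not in ct_table.columns:
            raise SchemaError(f"Ct table lacks column {col!r}")
    ref = ct_table[ct_table["gene"] == reference_gene].set_index("sample")["ct"]
    samples = ct_table["sample"].unique()
    missing = [s for s in samples if s not in ref.index]
    if missing:
        raise ParameterError(
            f"reference gene {reference_gene!r} missing in samples: {missing}"
        )
    if calibrator_sample not in ref.index:
        raise ParameterError(f"calibrator sample {calibrator_sample!r} not present")
    targets = ct_table[ct_table["gene"] != reference_gene].copy()
    targets["dct"] = targets["ct"] - targets["sample"].map(ref).astype(float)
    calib = targets[targets["sample"] == calibrator_sample].set_index("gene")["dct"]
    missing_genes = [g for g in targets["gene"].unique() if g not in calib.index]
    if missing_genes:
        raise ParameterError(
            f"calibrator sample lacks Ct for genes: {missing_genes}"
        )
    targets["ddct"] = targets["dct"] - targets["gene"].map(calib).astype(float)
    targets["relative_expression"] = np.exp2(-targets["ddct"])
    return targets[["sample", "gene", "relative_expression"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Panel (nCounter-style) normalisation
# ---------------------------------------------------------------------------


def panel_normalize(
    counts: pd.DataFrame,
    housekeeping_probes: Sequence[str],
    control_sample: str,
) -> pd.DataFrame:
    """Housekeeping geometric-mean normalisation and log2 ratios vs control.

    Per-sample factor = geomean over samples of the per-sample housekeeping
    geomean, divided by this sample's housekeeping geomean; normalised counts
    are raw counts times the factor, and each probe is reported as
    log2(normalized_sample / normalized_control).  Invariant under rescaling
    all counts of any one sample.
    """
    for col in ("sample", "probe", "count"):
        if col not in counts.columns:
            raise SchemaError(f"counts table lacks column {col!r}")
    hk = counts[counts["probe"].isin(set(housekeeping_probes))]
    if hk.empty:
        raise ParameterError("no housekeeping probes found in the counts table")
    if (hk["count"] <= 0).any():
        raise ParameterError("housekeeping counts must be positive in all samples")
    geo = hk.groupby("sample")["count"].apply(
        lambda v: float(np.exp(np.mean(np.log(v))))
    )
    samples = counts["sample"].unique()
    missing = [s for s in samples if s not in geo.index]
    if missing:
        raise ParameterError(f"samples without housekeeping counts: {missing}")
    if control_sample not in geo.index:
        raise ParameterError(f"control sample {control_sample!r} not present")
    grand = float(np.exp(np.mean(np.log(geo.loc[samples]))))
    factor = grand / geo

    normed = counts.copy()
    normed["normalized"] = normed["count"] * normed["sample"].map(factor).astype(float)
    control = (
        normed[normed["sample"] == control_sample]
        .set_index("probe")["normalized"]
    )
    out_rows = []
    for sample in samples:
        if sample == control_sample:
            continue
        sub = normed[normed["sample"] == sample]
        for _, row in sub.iterrows():
            probe = row["probe"]
            if probe not in control.index:
                raise ParameterError(f"probe {probe!r} missing in control sample")
            c = float(control.loc[probe])
            v = float(row["normalized"])
            if c <= 0:
                ratio = math.inf if v > 0 else math.nan
            elif v <= 0:
                ratio = -math.inf
            else:
                ratio = math.log2(v / c)
            out_rows.append({"sample": sample, "probe": probe, "log2_ratio": ratio})
    return pd.DataFrame(out_rows)


# ---------------------------------------------------------------------------
# Droplet digital PCR
# ---------------------------------------------------------------------------


def droplet_allele_fraction(
    droplets: pd.DataFrame | dict[str, tuple[int, int]],
) -> pd.DataFrame:
    """Poisson-corrected concentration and allele fraction per assay.

    lambda = -ln(1 - positive/total) corrects for multiply-occupied droplets;
    the fraction of each allele is its lambda over the summed lambdas.  A
    saturated assay (positive == total) has unbounded lambda and raises.
    """
    if isinstance(droplets, dict):
        droplets = pd.DataFrame(
            [
                {"assay": k, "positive": p, "total": t}
                for k, (p, t) in droplets.items()
            ]
        )
    for col in ("assay", "positive", "total"):
        if col not in droplets.columns:
            raise SchemaError(f"droplet table lacks column {col!r}")
    lams = []
    for _, row in droplets.iterrows():
        pos, tot = int(row["positive"]), int(row["total"])
        if tot <= 0 or pos < 0 or pos > tot:
            raise ParameterError(f"bad droplet counts ({pos}/{tot})")
        if pos == tot:
            raise SaturationError(
                f"assay {row['assay']!r}: all droplets positive; "
                "dilute and re-run"
            )
        lams.append(-math.log1p(-pos / tot))
    out = droplets.copy()
    out["lambda"] = lams
    total = float(sum(lams))
    out["fraction"] = [
        (lam / total) if total > 0 else math.nan for lam in lams
    ]
    return out
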