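"""Fold changes, neighborhood table, correlation scan, ddCt, panel, droplets."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svrecon.core import (
    ExpressionRecord,
    ParameterError,
    SaturationError,
    ScanParams,
    UndefinedValueError,
)
from svrecon.examples import (
    LOW_EXPRESSION_FOOTNOTE_GENES,
    neighborhood_expression_records,
)
from svrecon.expression import (
    droplet_allele_fraction,
    log_fold_change,
    neighborhood_table,
    panel_normalize,
    permutation_null,
    qpcr_relative_expression,
    window_correlation_scan,
)
from svrecon.synthetic import RegionalAnticorrelation, simulate_expression_profiles

fpkms = st.floats(min_value=0.0, max_value=1e5, allow_nan=False)


class TestLogFoldChange:
    @pytest.mark.parametrize(
        "case, control, expected",
        [(17.6, 21.5, 0.29), (53.3, 120.4, 1.18)],
    )
    def test_reported_rows_reproduce_at_2dp(self, case, control, expected):
        assert round(log_fold_change(case, control, 2, 0), 2) == expected

    def test_equal_inputs_give_zero(self):
        assert log_fold_change(7.3, 7.3, 2, 0) == 0
        assert log_fold_change(7.3, 7.3, 10, 1) == 0

    def test_double_zero_with_pseudo_one_is_zero(self):
        assert log_fold_change(0, 0, 2, 1) == 0

    def test_zero_denominator_without_pseudo_raises(self):
        with pytest.raises(UndefinedValueError):
            log_fold_change(0, 5, 2, 0)

    def test_zero_numerator_is_negative_infinity(self):
        assert log_fold_change(5, 0, 2, 0) == -math.inf

    @given(a=fpkms, b=fpkms, pseudo=st.floats(min_value=0.1, max_value=10))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_antisymmetry(self, a, b, pseudo):
        assert log_fold_change(a, b, 2, pseudo) == pytest.approx(
            -log_fold_change(b, a, 2, pseudo), abs=1e-9
        )

    @given(
        a=st.floats(min_value=0.01, max_value=1e4),
        b=st.floats(min_value=0.01, max_value=1e4),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_pseudo_count_shrinks_fold_changes(self, a, b):
        with_pseudo = abs(log_fold_change(a, b, 2, 1.0))
        without = abs(log_fold_change(a, b, 2, 0.0))
        assert with_pseudo <= without + 1e-12


class TestNeighborhoodTable:
    def test_reported_footnote_set_and_significance(self):
        table = neighborhood_table(
            neighborhood_expression_records(), low_fpkm_threshold=5.0, alpha=0.05
        )
        footnoted = set(table.loc[table["low_expression"], "gene"])
        assert footnoted == LOW_EXPRESSION_FOOTNOTE_GENES
        assert list(table.loc[table["significant"], "gene"]) == ["HSPA2"]
        hspa2 = table.set_index("gene").loc["HSPA2"]
        assert hspa2["log_fc"] == pytest.approx(1.18, abs=0.005)

    def test_equal_expression_nothing_significant(self):
        records = [
            ExpressionRecord(f"g{i}", "chr1", i * 1_000, 10.0, 10.0, p_value=1.0)
            for i in range(10)
        ]
        table = neighborhood_table(records)
        assert not table["significant"].any()
        assert not table["low_expression"].any()

    def test_strong_clean_change_is_significant_without_footnote(self):
        records = [
            ExpressionRecord("hit", "chr1", 1_000, 100.0, 10.0, p_value=1e-6)
        ] + [
            ExpressionRecord(f"g{i}", "chr1", (i + 2) * 1_000, 10.0, 10.0, p_value=0.9)
            for i in range(9)
        ]
        table = neighborhood_table(records).set_index("gene")
        assert bool(table.loc["hit", "significant"])
        assert not bool(table.loc["hit", "low_expression"])

    def test_empty_input_gives_empty_table(self):
        assert len(neighborhood_table([])) == 0


GENES = [(f"g{i}", "chr1", (i + 1) * 1_000) for i in range(30)]


def _table(case, control):
    return pd.DataFrame(
        {
            "gene": [g[0] for g in GENES[: len(case)]],
            "chrom": "chr1",
            "position": [g[2] for g in GENES[: len(case)]],
            "fpkm_case": case,
            "fpkm_control": control,
        }
    )


class TestWindowScan:
    def test_identical_tables_scan_at_plus_one(self):
        table, _ = simulate_expression_profiles(GENES, None, 0.0, seed=1)
        scan = window_correlation_scan(table, ScanParams(n_permutations=100))
        assert np.allclose(scan.window_r, 1.0)
        assert scan.candidates == []

    def test_reflected_block_scans_at_minus_one(self):
        table, _ = simulate_expression_profiles(
            GENES, RegionalAnticorrelation(10, 19, -1.0), 0.0, seed=1
        )
        # pseudo-count 0: the reflection is exact on the raw log scale
        scan = window_correlation_scan(
            table, ScanParams(n_permutations=100, pseudo_count=0.0)
        )
        inside = scan.window_r[10:17]  # windows fully inside the block
        assert np.allclose(inside, -1.0)
        assert any(a <= 10 <= b or a <= 17 <= b for a, b in scan.candidates)

    def test_pair_matrix_is_symmetric_with_unit_diagonal(self):
        t1, _ = simulate_expression_profiles(GENES, None, 0.0, seed=3)
        t2, _ = simulate_expression_profiles(GENES, None, 0.0, seed=4)
        table = t1.assign(fpkm_control=t2["fpkm_control"].to_numpy())
        scan = window_correlation_scan(table, ScanParams(n_permutations=100))
        m = scan.pair_matrix
        assert np.allclose(m, m.T, equal_nan=True)
        assert np.allclose(np.diag(m), 1.0)
        finite = m[np.isfinite(m)]
        assert (finite >= -1).all() and (finite <= 1).all()

    def test_zero_variance_window_recorded_missing(self):
        case = [5.0] * 6 + [1.0, 9.0, 2.0, 8.0]
        control = [5.0] * 6 + [2.0, 7.0, 1.0, 9.0]
        scan = window_correlation_scan(
            _table(case, control), ScanParams(n_permutations=100, pseudo_count=1.0)
        )
        assert np.isnan(scan.window_r[0])
        assert all(0 not in range(a, b + 1) for a, b in scan.candidates)

    def test_too_few_genes_raises(self):
        with pytest.raises(ParameterError):
            window_correlation_scan(_table([1.0, 2.0], [1.0, 2.0]))


class TestPermutationNull:
    def test_injected_region_attains_minimum_p(self):
        table, _ = simulate_expression_profiles(
            GENES, RegionalAnticorrelation(10, 19, -1.0), 0.0, seed=5
        )
        params = ScanParams(n_permutations=100)
        p, reject = permutation_null(table, params, seed=0)
        assert p == pytest.approx(1 / 101)
        assert reject

    def test_p_value_formula_lower_bound(self):
        # p can never be smaller than 1/(1+n) by construction
        table, _ = simulate_expression_profiles(
            GENES, RegionalAnticorrelation(5, 24, -1.0), 0.0, seed=6
        )
        p, _ = permutation_null(table, ScanParams(n_permutations=100), seed=1)
        assert p >= 1 / 101


class TestQpcr:
    def _ct(self, rows):
        return pd.DataFrame(rows, columns=["sample", "gene", "ct"])

    def test_all_equal_cts_give_unity(self):
        rows = [
            (s, g, 20.0)
            for s in ("case", "control")
            for g in ("TCF4", "GAPDH")
        ]
        out = qpcr_relative_expression(self._ct(rows), "GAPDH", "control")
        assert np.allclose(out["relative_expression"], 1.0)

    def test_one_cycle_earlier_doubles_expression(self):
        rows = [
            ("case", "TCF4", 19.0),
            ("case", "GAPDH", 20.0),
            ("control", "TCF4", 20.0),
            ("control", "GAPDH", 20.0),
        ]
        out = qpcr_relative_expression(self._ct(rows), "GAPDH", "control")
        val = out.set_index("sample").loc["case", "relative_expression"]
        assert val == pytest.approx(2.0)

    def test_ddct_arithmetic(self):
        # case dCt 3.2 vs calibrator dCt 5.2 -> 2^2 = 4
        rows = [
            ("case", "TCF4", 23.2),
            ("case", "GAPDH", 20.0),
            ("control", "TCF4", 25.2),
            ("control", "GAPDH", 20.0),
        ]
        out = qpcr_relative_expression(self._ct(rows), "GAPDH", "control")
        val = out.set_index("sample").loc["case", "relative_expression"]
        assert val == pytest.approx(4.0)

    def test_missing_reference_raises(self):
        rows = [("case", "TCF4", 20.0), ("control", "TCF4", 20.0),
                ("control", "GAPDH", 20.0)]
        with pytest.raises(ParameterError):
            qpcr_relative_expression(self._ct(rows), "GAPDH", "control")


class TestPanelNormalize:
    def _counts(self, rows):
        return pd.DataFrame(rows, columns=["sample", "probe", "count"])

    BASE = [
        ("control", "GAPDH", 1_000.0),
        ("control", "p1", 10.0),
        ("case", "GAPDH", 1_000.0),
        ("case", "p1", 160.0),
    ]

    def test_probe_ratio_arithmetic(self):
        out = panel_normalize(self._counts(self.BASE), ["GAPDH"], "control")
        assert out.set_index("probe").loc["p1", "log2_ratio"] == pytest.approx(4.0)

    def test_lane_scaling_invariance(self):
        doubled = [
            (s, p, c * (2.0 if s == "case" else 1.0)) for s, p, c in self.BASE
        ]
        a = panel_normalize(self._counts(self.BASE), ["GAPDH"], "control")
        b = panel_normalize(self._counts(doubled), ["GAPDH"], "control")
        pd.testing.assert_frame_equal(a, b)

    def test_equal_normalized_counts_give_zero(self):
        rows = [
            ("control", "GAPDH", 500.0),
            ("control", "p1", 80.0),
            ("case", "GAPDH", 1_000.0),
            ("case", "p1", 160.0),
        ]
        out = panel_normalize(self._counts(rows), ["GAPDH"], "control")
        assert out["log2_ratio"].abs().max() == pytest.approx(0.0)

    def test_zero_housekeeping_raises(self):
        rows = [("control", "GAPDH", 0.0), ("case", "GAPDH", 10.0)]
        with pytest.raises(ParameterError):
            panel_normalize(self._counts(rows), ["GAPDH"], "control")


class TestDroplets:
    def test_zero_positives_zero_lambda(self):
        out = droplet_allele_fraction({"A": (0, 1_000), "B": (100, 1_000)})
        a = out.set_index("assay")
        assert a.loc["A", "lambda"] == 0 and a.loc["A", "fraction"] == 0

    def test_equal_positive_fractions_split_half_and_half(self):
        out = droplet_allele_fraction({"A": (250, 1_000), "B": (250, 1_000)})
        assert np.allclose(out["fraction"], 0.5)

    def test_poisson_occupancy_closed_form(self):
        total = 1_000_000
        positive = round(total * (1 - math.exp(-1)))
        out = droplet_allele_fraction({"A": (positive, total), "B": (0, total)})
        assert out.set_index("assay").loc["A", "lambda"] == pytest.approx(1.0, abs=1e-5)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            droplet_allele_fraction({"A": (1_000, 1_000), "B": (10, 1_000)})
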