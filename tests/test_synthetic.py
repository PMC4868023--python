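"""Synthetic generator: determinism, conservation laws and effect injection."""

import numpy as np
import pandas as pd
import pytest

from svrecon.core import Interval, ParameterError, RearrangementSpecError
from svrecon.detection import classify_pairs, estimate_insert_stats
from svrecon.reconstruction import junction_reference_sequence
from svrecon.synthetic import (
    BreakpointShift,
    InversionSpec,
    RearrangementSpec,
    RegionalAnticorrelation,
    ToyReference,
    TranslocationSpec,
    apply_rearrangement,
    build_toy_genome,
    generate_filter_tracks,
    identity_derived,
    simulate_expression_profiles,
    simulate_read_pairs,
    simulate_transcript_panel,
)


def _tiny_ref(seq_a: str, seq_b: str) -> ToyReference:
    n = len(seq_a)
    bands = []
    for name, seq in (("chrA", seq_a), ("chrB", seq_b)):
        half = len(seq) // 2
        bands += [(name, 1, half, "p1"), (name, half + 1, len(seq), "q1")]
    return ToyReference({"chrA": seq_a, "chrB": seq_b}, bands)


class TestToyGenome:
    def test_fixed_seed_is_deterministic(self):
        a = build_toy_genome(2, 10_000, 0.4, seed=7)
        b = build_toy_genome(2, 10_000, 0.4, seed=7)
        assert a.chromosomes == b.chromosomes
        assert a.band_map == b.band_map

    def test_different_seeds_differ(self):
        a = build_toy_genome(2, 10_000, 0.4, seed=7)
        b = build_toy_genome(2, 10_000, 0.4, seed=8)
        assert a.chromosomes != b.chromosomes

    def test_gc_zero_contains_no_gc(self):
        ref = build_toy_genome(2, 10_000, 0.0, seed=1)
        for seq in ref.chromosomes.values():
            assert set(seq) <= {"A", "T"}

    def test_band_map_tiles_chromosomes(self):
        ref = build_toy_genome(3, 12_000, 0.5, seed=3)
        ref.validate()
        per_chrom = {}
        for chrom, *_ in ref.band_map:
            per_chrom[chrom] = per_chrom.get(chrom, 0) + 1
        assert all(n >= 4 for n in per_chrom.values())

    @pytest.mark.parametrize(
        "kwargs",
        [dict(length_bp=5_000), dict(n_chroms=1), dict(gc=1.5)],
    )
    def test_parameter_errors(self, kwargs):
        args = dict(n_chroms=2, length_bp=10_000, gc=0.4, seed=0)
        args.update(kwargs)
        with pytest.raises(ParameterError):
            build_toy_genome(**args)


class TestApplyRearrangement:
    def test_three_break_topology_has_three_junctions(self, derived_truth):
        _, truth = derived_truth
        assert len(truth.junctions) == 3
        classes = sorted(c.svclass for c in truth.junctions)
        assert classes == ["inter_chromosomal", "inter_chromosomal", "inversion_like"]

    def test_length_conservation(self, toy_ref, derived_truth):
        derived, truth = derived_truth
        total_ref = sum(toy_ref.lengths.values())
        total_der = sum(d.total_length for d in truth.derivatives)
        assert total_der + sum(truth.deleted_bases.values()) == total_ref

    def test_zero_width_deletions_conserve_length(self, toy_ref):
        spec = RearrangementSpec(
            translocation=TranslocationSpec("chrA", 250_000, "chrB", 300_000)
        )
        derived, truth = apply_rearrangement(toy_ref, spec)
        assert sum(truth.deleted_bases.values()) == 0
        assert sum(d.total_length for d in truth.derivatives) == sum(
            toy_ref.lengths.values()
        )

    def test_translocation_only_20bp_hand_enumeration(self):
        # Hand-derived oracle on two 20 bp chromosomes: break A after base 10,
        # break B after base 12, no deletions.
        a, b = "ACGTACGTACGTACGTACGT", "TTTTCCCCGGGGAAAATTTT"
        ref = _tiny_ref(a, b)
        spec = RearrangementSpec(
            translocation=TranslocationSpec("chrA", 10, "chrB", 12)
        )
        derived, truth = apply_rearrangement(ref, spec)
        assert derived.sequences["der(A)"] == a[:10] + b[12:]
        assert derived.sequences["der(B)"] == b[:12] + a[10:]
        assert len(truth.junctions) == 2
        ends = {
            frozenset(
                (be.chrom, be.pos, be.orientation)
                for be in (j.breakend_1, j.breakend_2)
            )
            for j in truth.junctions
        }
        assert ends == {
            frozenset({("chrA", 10, "head"), ("chrB", 13, "tail")}),
            frozenset({("chrB", 12, "head"), ("chrA", 11, "tail")}),
        }

    def test_truth_junction_flanks_match_derivative_sequence(
        self, toy_ref, derived_truth
    ):
        # reading 2*flank bases across each truth junction from the derivative
        # sequence must equal the oriented reference flank concatenation
        derived, truth = derived_truth
        flank = 25
        for d in truth.derivatives:
            seq = derived.sequences[d.name]
            offset = 0
            for j, seg in enumerate(d.segments[:-1]):
                offset += seg.length
                expected = seq[offset - flank : offset + flank]
                got = junction_reference_sequence(toy_ref.chromosomes, d, j, flank)
                assert got == expected

    def test_overlapping_deletions_rejected(self, toy_ref):
        spec = RearrangementSpec(
            translocation=TranslocationSpec(
                "chrA", 250_000, "chrB", deletion_a=Interval("chrA", 250_001, 250_100)
            ),
            inversion=InversionSpec(
                "chrB",
                200_000,
                300_000,
                deletion_centromeric=Interval("chrB", 196_000, 199_999),
                deletion_telomeric=Interval("chrB", 300_001, 300_050),
            ),
        )
        # mis-anchored deletion: does not abut break_a
        bad = RearrangementSpec(
            translocation=TranslocationSpec(
                "chrA", 250_000, "chrB", deletion_a=Interval("chrA", 250_500, 250_600)
            ),
            inversion=spec.inversion,
        )
        with pytest.raises(RearrangementSpecError):
            apply_rearrangement(toy_ref, bad)


class TestReadSimulation:
    def test_unrearranged_genome_pairs_all_concordant(self, toy_ref):
        derived = identity_derived(toy_ref)
        pairs = simulate_read_pairs(derived, 2_000, seed=5)
        stats = estimate_insert_stats(pairs, k=4.0)
        labels = classify_pairs(pairs, stats)
        assert (labels == "concordant").all()

    def test_fixed_seed_reproduces_pair_table(self, toy_ref):
        derived = identity_derived(toy_ref)
        a = simulate_read_pairs(derived, 500, seed=3)
        b = simulate_read_pairs(derived, 500, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_each_truth_junction_covered_by_discordant_cluster(
        self, scored_calls_30x, derived_truth
    ):
        # at 30x with a 308 +/- 30 insert, >= 1 cluster of discordant pairs
        # spans each of the three truth junctions
        _, truth = derived_truth
        big = [c for c in scored_calls_30x if c.support >= 12]
        assert len(big) == 3

    def test_parameter_errors(self, toy_ref):
        derived = identity_derived(toy_ref)
        with pytest.raises(ParameterError):
            simulate_read_pairs(derived, 0)
        with pytest.raises(ParameterError):
            simulate_read_pairs(derived, 10, insert_mean=150, read_len=100)

    def test_background_rate_adds_spurious_pairs(self, toy_ref):
        derived = identity_derived(toy_ref)
        pairs = simulate_read_pairs(
            derived, 1_000, seed=4, background_discordant_rate=0.1
        )
        assert len(pairs) == 1_100


class TestExpressionSimulation:
    GENES = [(f"g{i}", "chrB", (i + 1) * 1_000) for i in range(20)]

    def test_no_effect_no_noise_equals_control(self):
        table, truth = simulate_expression_profiles(self.GENES, None, 0.0, seed=2)
        np.testing.assert_allclose(table["fpkm_case"], table["fpkm_control"])
        assert truth["effect"] == "none"

    def test_breakpoint_shift_halves_fpkm_exactly(self):
        table, _ = simulate_expression_profiles(
            self.GENES, BreakpointShift(("g3",), -1.0), 0.0, seed=2
        )
        row = table.set_index("gene")
        assert row.loc["g3", "fpkm_case"] == pytest.approx(
            row.loc["g3", "fpkm_control"] / 2
        )
        others = row.drop("g3")
        np.testing.assert_allclose(others["fpkm_case"], others["fpkm_control"])

    def test_regional_anticorrelation_reflects_about_mean(self):
        table, _ = simulate_expression_profiles(
            self.GENES, RegionalAnticorrelation(5, 14, -1.0), 0.0, seed=2
        )
        lc = np.log2(table["fpkm_case"].to_numpy())
        lk = np.log2(table["fpkm_control"].to_numpy())
        r = np.corrcoef(lc[5:15], lk[5:15])[0, 1]
        assert r == pytest.approx(-1.0)

    def test_region_outside_gene_list_is_an_error(self):
        with pytest.raises(ParameterError):
            simulate_expression_profiles(
                self.GENES, RegionalAnticorrelation(15, 25), 0.0, seed=0
            )


class TestFilterTracks:
    def test_zero_intervals_gives_empty_tracks(self, toy_ref):
        tracks = generate_filter_tracks(toy_ref, 0, seed=0)
        assert all(len(t) == 0 for t in tracks.values())
        assert len(tracks) == 3

    def test_fixed_seed_reproduces_tracks(self, toy_ref):
        a = generate_filter_tracks(toy_ref, 10, seed=9)
        b = generate_filter_tracks(toy_ref, 10, seed=9)
        assert a == b

    def test_tracks_sorted_and_merged(self, toy_ref):
        tracks = generate_filter_tracks(toy_ref, 200, seed=1)
        for ivs in tracks.values():
            for a, b in zip(ivs, ivs[1:]):
                if a.chrom == b.chrom:
                    assert b.start > a.end + 1


class TestTranscriptPanelSimulation:
    def test_unit_folds_give_zero_ratios(self, demo_spec):
        from svrecon.core import HEAD, Breakend
        from svrecon.synthetic import demo_transcript_models

        models = [m for m in demo_transcript_models(demo_spec) if m.chrom == "chrB"]
        bp = demo_spec.inversion.end
        panel, ct, droplets = simulate_transcript_panel(
            models,
            [Breakend("chrB", bp, HEAD)],
            [demo_spec.inversion.deletion_telomeric],
            {"interrupted": 1.0, "intact_distal": 1.0},
            seed=0,
        )
        ratios = np.log2(panel["count_case"] / panel["count_control"])
        np.testing.assert_allclose(ratios, 0.0)
        assert set(ct.columns) == {"sample", "gene", "ct"}
        assert (droplets["positive"] <= droplets["total"]).all()

    def test_unknown_status_key_rejected(self, demo_spec):
        from svrecon.core import HEAD, Breakend
        from svrecon.synthetic import demo_transcript_models

        models = [m for m in demo_transcript_models(demo_spec) if m.chrom == "chrB"]
        with pytest.raises(ParameterError):
            simulate_transcript_panel(
                models,
                [Breakend("chrB", demo_spec.inversion.end, HEAD)],
                [],
                {"bogus": 2.0},
                seed=0,
            )
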