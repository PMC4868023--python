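"""Shared fixtures: one toy genome with the three-break rearrangement and a
30x read-pair simulation, reused across the detection/reconstruction tests."""

from __future__ import annotations

import pandas as pd
import pytest

from svrecon.core import FilterParams
from svrecon.detection import cluster_discordant, estimate_insert_stats, score_calls
from svrecon.synthetic import (
    apply_rearrangement,
    build_toy_genome,
    demo_rearrangement_spec,
    pairs_for_depth,
    simulate_read_pairs,
)


@pytest.fixture(scope="session")
def toy_ref():
    return build_toy_genome(2, 500_000, 0.4, seed=7, names=["chrA", "chrB"])


@pytest.fixture(scope="session")
def demo_spec(toy_ref):
    return demo_rearrangement_spec(toy_ref)


@pytest.fixture(scope="session")
def derived_truth(toy_ref, demo_spec):
    return apply_rearrangement(toy_ref, demo_spec)


@pytest.fixture(scope="session")
def pair_table_30x(derived_truth):
    derived, _ = derived_truth
    n = pairs_for_depth(derived, 30.0)
    return simulate_read_pairs(derived, n, insert_mean=308, insert_sd=30, seed=11)


@pytest.fixture(scope="session")
def insert_stats_30x(pair_table_30x):
    return estimate_insert_stats(pair_table_30x)


@pytest.fixture(scope="session")
def scored_calls_30x(pair_table_30x, insert_stats_30x):
    calls = cluster_discordant(pair_table_30x, insert_stats_30x)
    score_calls(calls, background_rate=0.1)
    return calls


def make_pair_table(rows: list[tuple]) -> pd.DataFrame:
    """Rows: (chrom, pos, strand, mate_chrom, mate_pos, mate_strand, mapq)."""
    return pd.DataFrame(
        [
            {
                "read_id": f"r{i}",
                "chrom": c,
                "pos": p,
                "strand": s,
                "mate_chrom": mc,
                "mate_pos": mp,
                "mate_strand": ms,
                "mapq": q,
            }
            for i, (c, p, s, mc, mp, ms, q) in enumerate(rows)
        ]
    )


def breakend_pair_set(call):
    """Order-free representation of a junction call's two breakends."""
    return frozenset(
        (be.chrom, be.pos, be.orientation)
        for be in (call.breakend_1, call.breakend_2)
    )


DEFAULT_PARAMS = FilterParams()
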