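"""Shared fixtures: hand-built SAM scenarios and small simulated libraries."""

from __future__ import annotations

import pytest

from paircraft import ParseConfig, SimConfig, simulate_genome, simulate_library
from paircraft.sort_merge import ChromOrder

CHROMSIZES = [("chr1", 100_000), ("chr2", 100_000)]


def sam(qname, flag, chrom, pos, mapq, cigar, *tags, seq="*"):
    """One SAM alignment line (mate fields blanked)."""
    fields = [qname, str(flag), chrom, str(pos), str(mapq), cigar,
              "*", "0", "0", seq, "*", *tags]
    return "\t".join(fields)


UNMAPPED_FLAG1 = 0x1 | 0x4 | 0x40
UNMAPPED_FLAG2 = 0x1 | 0x4 | 0x80
F1 = 0x1 | 0x40  # first mate, forward
F1R = F1 | 0x10
F2 = 0x1 | 0x80
F2R = F2 | 0x10
SUP = 0x800


@pytest.fixture
def chrom_order():
    return ChromOrder.from_chromsizes(CHROMSIZES)


@pytest.fixture
def parse_config():
    return ParseConfig()


def sam_text(lines):
    header = [
        "@SQ\tSN:chr1\tLN:100000",
        "@SQ\tSN:chr2\tLN:100000",
    ]
    return iter(line + "\n" for line in header + list(lines))


# --- the eight chimeric-read scenarios (single contact, unmapped, multi,
# --- rescue, unrescuable walk, 3-junction walk, readthrough, null 5' end)

def scenario_single_contact():
    return [
        sam("a", F1, "chr1", 100, 60, "50M"),
        sam("a", F2R, "chr1", 5000, 60, "50M"),
    ]


def scenario_one_side_unmapped():
    return [
        sam("b", UNMAPPED_FLAG1, "*", 0, 0, "*"),
        sam("b", F2, "chr1", 5000, 60, "50M"),
    ]


def scenario_both_unmapped():
    return [
        sam("b2", UNMAPPED_FLAG1, "*", 0, 0, "*"),
        sam("b2", UNMAPPED_FLAG2, "*", 0, 0, "*"),
    ]


def scenario_multi():
    return [
        sam("c", F1, "chr1", 100, 0, "50M"),
        sam("c", F2, "chr1", 5000, 60, "50M"),
    ]


def scenario_rescue():
    # side 1: red (5') + green (3'); side 2: blue reads the green fragment
    # from its other end (opposite strand, nearby, non-overlapping spans)
    return [
        sam("d", F1, "chr1", 100, 60, "40M60S"),
        sam("d", F1R | SUP, "chr1", 4941, 60, "60M40S"),  # green, 5' end 5000
        sam("d", F2, "chr1", 5010, 60, "100M"),  # blue, 5' end 5010
    ]


def scenario_walk_trans_green():
    # green in trans: cannot be rescued -> two-contact walk
    return [
        sam("e", F1, "chr1", 100, 60, "40M60S"),
        sam("e", F1R | SUP, "chr2", 4941, 60, "60M40S"),
        sam("e", F2, "chr1", 5010, 60, "100M"),
    ]


def scenario_three_junction_walk():
    # side 1 reads fragments A, B; side 2 reads D, C (reverse of molecule)
    return [
        sam("f", F1, "chr1", 1000, 60, "100M100S"),
        sam("f", F1 | SUP, "chr1", 3000, 60, "100S100M"),
        sam("f", F2, "chr2", 7000, 60, "100M100S"),
        sam("f", F2 | SUP, "chr2", 500, 60, "100S100M"),
    ]


def scenario_readthrough():
    # molecule A-B-C-D; both reads (300 bp) cross junctions so B and C are
    # sequenced twice; six alignments in total
    return [
        sam("g", F1, "chr1", 1000, 60, "100M200S"),
        sam("g", F1 | SUP, "chr1", 3000, 60, "100S100M100S"),
        sam("g", F1 | SUP, "chr2", 500, 60, "200S100M"),
        sam("g", F2R, "chr2", 7000, 60, "200S100M"),
        sam("g", F2R | SUP, "chr2", 500, 60, "100S100M100S"),
        sam("g", F2R | SUP, "chr1", 3000, 60, "100M200S"),
    ]


def scenario_null_five_prime():
    # the 5'-most 100 bp of side 1 are unmapped; green aligns at [100,200)
    return [
        sam("h", F1, "chr1", 4000, 60, "100S100M"),
        sam("h", F2, "chr2", 600, 60, "100M"),
    ]


@pytest.fixture
def small_library():
    config = SimConfig(
        seed=11,
        n_molecules=2000,
        duplication_rate=0.5,
        walk_fraction=0.05,
        byproduct_rates=(0.02, 0.02, 0.01),
    )
    genome = simulate_genome(config)
    truths, sam_lines = simulate_library(config, genome)
    return config, genome, truths, sam_lines
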