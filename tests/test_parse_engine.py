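"""Chimeric-read scenarios: simple contacts, rescue, readthrough, walk policies."""

import pytest

from paircraft import ParseConfig
from paircraft.alignment_ingest import read_sam
from paircraft.parse_engine import (
    WALK_POLICIES,
    build_chains,
    collapse_readthrough,
    parse_bundle,
    parse_stream,
)
from paircraft.sort_merge import ChromOrder
from tests.conftest import (
    CHROMSIZES,
    sam,
    sam_text,
    F1,
    F2,
    scenario_both_unmapped,
    scenario_multi,
    scenario_null_five_prime,
    scenario_one_side_unmapped,
    scenario_readthrough,
    scenario_rescue,
    scenario_single_contact,
    scenario_three_junction_walk,
    scenario_walk_trans_green,
)


def parse_lines(lines, **config_kwargs):
    config = ParseConfig(**config_kwargs)
    _, records = parse_stream(sam_text(lines), CHROMSIZES, config)
    return list(records)


def first_bundle(lines):
    _, bundles = read_sam(sam_text(lines))
    return next(bundles)


class TestSimplePairs:
    def test_single_contact_uu(self):
        (record,) = parse_lines(scenario_single_contact())
        assert record.pair_type == "UU"
        assert (record.chrom1, record.pos1, record.strand1) == ("chr1", 100, "+")
        # reverse-strand side reports its 5' end, the rightmost ref base
        assert (record.chrom2, record.pos2, record.strand2) == ("chr1", 5049, "-")

    def test_one_side_unmapped_nu(self):
        (record,) = parse_lines(scenario_one_side_unmapped())
        assert record.pair_type == "NU"
        assert (record.chrom1, record.pos1, record.strand1) == ("!", 0, ".")

    def test_both_unmapped_nn(self):
        (record,) = parse_lines(scenario_both_unmapped())
        assert record.pair_type == "NN"

    def test_low_mapq_mu(self):
        (record,) = parse_lines(scenario_multi())
        assert record.pair_type == "MU"
        assert record.chrom1 == "chr1" and record.pos1 == 100


class TestRescue:
    def test_rescued_pair_red_blue(self):
        (record,) = parse_lines(scenario_rescue())
        assert record.pair_type == "RU"
        assert (record.pos1, record.strand1) == (100, "+")
        # the contact is reported at the blue (mate) alignment, not green
        assert (record.chrom2, record.pos2, record.strand2) == ("chr1", 5010, "+")

    def test_trans_green_is_walk_not_rescue(self):
        records = parse_lines(scenario_walk_trans_green(), walk_policy="mask")
        assert [r.pair_type for r in records] == ["WW"]

    def test_same_strand_green_blue_not_rescued(self):
        lines = [
            sam("d", F1, "chr1", 100, 60, "40M60S"),
            sam("d", F1 | 0x800, "chr1", 4941, 60, "60M40S"),  # green +
            sam("d", F2, "chr1", 4900, 60, "100M"),  # blue + (same strand)
        ]
        records = parse_lines(lines, walk_policy="mask")
        assert [r.pair_type for r in records] == ["WW"]

    def test_distance_bound(self):
        lines = scenario_rescue()
        records = parse_lines(lines, max_molecule_size=5, walk_policy="mask")
        assert [r.pair_type for r in records] == ["WW"]  # 10 bp > 5


class TestWalkPolicies:
    def test_mask_single_ww_record(self):
        records = parse_lines(scenario_three_junction_walk(), walk_policy="mask")
        assert len(records) == 1
        assert records[0].pair_type == "WW"
        assert records[0].chrom1 == "!" and records[0].pos1 == 0

    def test_all_reports_every_junction(self):
        records = parse_lines(scenario_three_junction_walk(), walk_policy="all")
        assert len(records) == 3
        assert all(r.read_id == "f" for r in records)
        indices = {r.extras[-1] for r in records}
        assert indices == {"1", "2", "3"}

    def test_five_unique_takes_five_prime_most_of_each_side(self):
        (record,) = parse_lines(scenario_three_junction_walk(), walk_policy="5unique")
        coords = {(record.chrom1, record.pos1), (record.chrom2, record.pos2)}
        assert coords == {("chr1", 1000), ("chr2", 7000)}

    def test_three_unique_takes_three_prime_most(self):
        (record,) = parse_lines(scenario_three_junction_walk(), walk_policy="3unique")
        coords = {(record.chrom1, record.pos1), (record.chrom2, record.pos2)}
        assert coords == {("chr1", 3000), ("chr2", 500)}

    def test_null_five_prime_5any_vs_5unique(self):
        (any_rec,) = parse_lines(scenario_null_five_prime(), walk_policy="5any")
        assert any_rec.pair_type == "NU"
        (uniq_rec,) = parse_lines(scenario_null_five_prime(), walk_policy="5unique")
        assert uniq_rec.pair_type == "UU"
        coords = {(uniq_rec.chrom1, uniq_rec.pos1), (uniq_rec.chrom2, uniq_rec.pos2)}
        assert coords == {("chr1", 4000), ("chr2", 600)}

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError, match="policy"):
            ParseConfig(walk_policy="7flexible")

    @pytest.mark.parametrize("policy", WALK_POLICIES)
    def test_policy_consistency_on_single_junction(self, policy):
        """All six policies agree on molecules with exactly one junction."""
        (record,) = parse_lines(scenario_single_contact(), walk_policy=policy)
        assert record.pair_type == "UU"
        assert (record.pos1, record.pos2) == (100, 5049)


class TestReadthrough:
    def test_six_alignments_collapse_to_three_junctions(self):
        records = parse_lines(scenario_readthrough(), walk_policy="all")
        assert len(records) == 3  # four distinct fragments, three ligations

    def test_collapsed_fragments_each_reported_once(self):
        records = parse_lines(scenario_readthrough(), walk_policy="all")
        sides = []
        for r in records:
            sides.append((r.chrom1, r.pos1))
            sides.append((r.chrom2, r.pos2))
        # terminal fragments A and D are present once each; D is read on the
        # reverse strand so it reports its 5' (rightmost) base
        assert sides.count(("chr1", 1000)) == 1
        assert sides.count(("chr2", 7099)) == 1

    def test_full_readthrough_mirror_collapses_to_nothing(self):
        lines = [
            sam("m", F1, "chr1", 1000, 60, "100M"),
            sam("m", F2 | 0x10, "chr1", 1000, 60, "100M"),
        ]
        assert parse_lines(lines) == []

    def test_no_overlap_leaves_chains_unchanged(self):
        bundle = first_bundle(scenario_single_contact())
        config = ParseConfig()
        c1, c2 = build_chains(bundle, config)
        d1, d2 = collapse_readthrough(c1, c2, config)
        assert d1.segments == c1.segments and d2.segments == c2.segments


class TestBuildChains:
    def test_gap_threshold_inserts_null(self):
        lines = [
            sam("x", F1, "chr1", 100, 60, "40M60S"),
            sam("x", F1 | 0x800, "chr1", 9000, 60, "70S30M"),  # gap 30 > 20
            sam("x", F2, "chr2", 600, 60, "100M"),
        ]
        bundle = first_bundle(lines)
        chain1, _ = build_chains(bundle, ParseConfig())
        assert [s is None for s in chain1.segments] == [False, True, False]

    def test_small_gap_no_null(self):
        lines = [
            sam("x", F1, "chr1", 100, 60, "40M60S"),
            sam("x", F1 | 0x800, "chr1", 9000, 60, "50S50M"),  # gap 10 <= 20
            sam("x", F2, "chr2", 600, 60, "100M"),
        ]
        bundle = first_bundle(lines)
        chain1, _ = build_chains(bundle, ParseConfig())
        assert all(s is not None for s in chain1.segments)

    def test_unmapped_side_is_null_chain(self):
        bundle = first_bundle(scenario_one_side_unmapped())
        chain1, chain2 = build_chains(bundle, ParseConfig())
        assert chain1.segments == [None]
        assert len(chain2.mapped()) == 1

    def test_overlapping_read_spans_keep_higher_mapq(self):
        lines = [
            sam("x", F1, "chr1", 100, 10, "60M40S"),
            sam("x", F1 | 0x800, "chr1", 5000, 60, "30S70M"),  # overlaps, higher mapq
            sam("x", F2, "chr2", 600, 60, "100M"),
        ]
        bundle = first_bundle(lines)
        chain1, _ = build_chains(bundle, ParseConfig())
        assert [a.mapq for a in chain1.mapped()] == [60]


class TestFlipBehaviour:
    def test_flip_idempotent_on_parse_output(self, chrom_order):
        records = parse_lines(scenario_single_contact())
        from paircraft.sort_merge import flip_pair

        for r in records:
            assert flip_pair(r, chrom_order) == r

    def test_records_canonically_oriented(self):
        lines = [
            sam("y", F1, "chr2", 100, 60, "50M"),
            sam("y", F2, "chr1", 5000, 60, "50M"),
        ]
        (record,) = parse_lines(lines)
        assert (record.chrom1, record.chrom2) == ("chr1", "chr2")


def test_truth_recovery_without_artifacts():
    """Parse recovers every planted pair exactly on a clean simulated library."""
    from paircraft import SimConfig, simulate_genome, simulate_library

    config = SimConfig(seed=5, n_molecules=1000)
    genome = simulate_genome(config)
    truths, sam_lines = simulate_library(config, genome)
    parse_config = ParseConfig(walk_policy="5unique")
    _, records = parse_stream(
        iter(l + "\n" for l in sam_lines), genome.chromsizes, parse_config
    )
    got = {
        (r.chrom1, r.pos1, r.strand1, r.chrom2, r.pos2, r.strand2)
        for r in records
    }
    want = {t.pair for t in truths}
    assert len(got & want) >= 0.99 * len(want)


def test_junction_count_conservation_policy_all():
    """Under policy `all`, records per read equal segments - 1 after collapse."""
    from paircraft import SimConfig, simulate_genome, simulate_library

    config = SimConfig(seed=6, n_molecules=400, walk_fraction=1.0)
    genome = simulate_genome(config)
    truths, sam_lines = simulate_library(config, genome)
    _, records = parse_stream(
        iter(l + "\n" for l in sam_lines),
        genome.chromsizes,
        ParseConfig(walk_policy="all"),
    )
    per_read: dict[str, int] = {}
    for r in records:
        per_read[r.read_id] = per_read.get(r.read_id, 0) + 1
    # reads never cover fewer than one junction, and no more than planted
    truth_by_read = {t.read_id: t for t in truths}
    for read_id, n in per_read.items():
        assert 1 <= n <= truth_by_read[read_id].n_junctions
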