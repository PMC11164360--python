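import numpy as np
import pytest

from paircraft.pairs_format import PairRecord, RESERVED_COLUMNS
from paircraft.protocol_tools import (
    RESTRICTION_EXTRA_COLUMNS,
    CoverageFilterConfig,
    PhaseConfig,
    annotate_restriction,
    classify_byproduct,
    digest_genome,
    filter_by_coverage,
    phase_pairs,
    phase_side,
    reverse_complement,
)

ANNOTATED_COLUMNS = list(RESERVED_COLUMNS) + list(RESTRICTION_EXTRA_COLUMNS)


def rec(c1, p1, c2, p2, s1="+", s2="-", t="UU", rid="r", extras=()):
    return PairRecord(rid, c1, p1, c2, p2, s1, s2, t, list(extras))


class TestDigest:
    def test_palindromic_site_toy_chromosome(self):
        frags = digest_genome({"c": "AAGATCAA"}, "GATC")
        assert list(frags.starts["c"]) == [1, 3]
        assert frags.locate("c", 5) == (1, 3, 9)
        assert frags.locate("c", 1) == (0, 1, 3)

    def test_no_matches_single_fragment(self):
        frags = digest_genome({"c": "AAAAAA"}, "GATC")
        assert list(frags.starts["c"]) == [1]
        assert frags.locate("c", 6) == (0, 1, 7)

    def test_non_palindromic_site_cuts_both_strands(self):
        # CCTC on the forward strand, GAGG = revcomp match at offset 6
        frags = digest_genome({"c": "ACCTCAGAGGAA"}, "CCTC")
        assert list(frags.starts["c"]) == [1, 2, 7]

    def test_iupac_ambiguity_codes(self):
        frags = digest_genome({"c": "AAGACTCAA"}, "GANTC")  # N matches any base
        assert list(frags.starts["c"]) == [1, 3]

    def test_invalid_letter_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            digest_genome({"c": "ACGT"}, "GAT?")

    def test_matches_naive_scan_on_random_sequence(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=100_000))
        frags = digest_genome({"c": seq}, "GATC")
        naive = {1}
        for i in range(len(seq) - 3):
            if seq[i : i + 4] == "GATC":
                naive.add(i + 1)
        assert list(frags.starts["c"]) == sorted(naive)

    def test_reverse_complement(self):
        assert reverse_complement("GATC") == "GATC"
        assert reverse_complement("CCTC") == "GAGG"
        assert reverse_complement("GANTC") == "GANTC"


class TestAnnotate:
    @pytest.fixture
    def frags(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=100_000))
        return digest_genome({"chr1": seq}, "GATC"), seq

    def test_matches_linear_scan(self, frags):
        frag_map, seq = frags
        starts = list(frag_map.starts["chr1"])
        bounds = starts + [len(seq) + 1]
        rng = np.random.default_rng(2)
        for pos in rng.integers(1, len(seq) + 1, size=10_000):
            idx, start, end = frag_map.locate("chr1", int(pos))
            # linear scan oracle
            oracle = max(i for i, s in enumerate(starts) if s <= pos)
            assert idx == oracle
            assert bounds[idx] <= pos < bounds[idx + 1]
            assert (start, end) == (bounds[idx], bounds[idx + 1])

    def test_annotation_extras_appended(self, frags):
        frag_map, _ = frags
        out = annotate_restriction(rec("chr1", 10, "chr1", 5000), frag_map)
        assert len(out.extras) == 6
        idx1 = int(out.extras[0])
        assert int(out.extras[1]) <= 10 < int(out.extras[2])
        assert idx1 >= 0

    def test_null_side_sentinel(self, frags):
        frag_map, _ = frags
        out = annotate_restriction(rec("!", 0, "chr1", 10, ".", "+", t="NU"), frag_map)
        assert out.extras[:3] == ["-1", "-1", "-1"]

    def test_position_beyond_length_rejected(self, frags):
        frag_map, _ = frags
        with pytest.raises(ValueError):
            annotate_restriction(rec("chr1", 10, "chr1", 10**7), frag_map)


class TestClassifyByproduct:
    def _annotated(self, s1, s2, same_frag=True):
        extras = ["5", "100", "200", "5" if same_frag else "6", "100", "200"]
        return rec("chr1", 120, "chr1", 150, s1, s2, extras=extras)

    def test_convergent_same_fragment_is_dangling_end(self):
        r = self._annotated("+", "-")
        assert classify_byproduct(r, ANNOTATED_COLUMNS) == "dangling_end"

    def test_divergent_same_fragment_is_self_circle(self):
        r = self._annotated("-", "+")
        assert classify_byproduct(r, ANNOTATED_COLUMNS) == "self_circle"

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_equal_strands_same_fragment_is_mirror(self, strand):
        r = self._annotated(strand, strand)
        assert classify_byproduct(r, ANNOTATED_COLUMNS) == "mirror"

    def test_different_fragments_valid(self):
        r = self._annotated("+", "-", same_frag=False)
        assert classify_byproduct(r, ANNOTATED_COLUMNS) == "valid"

    def test_missing_annotation_rejected(self):
        with pytest.raises(ValueError, match="annotation"):
            classify_byproduct(rec("chr1", 1, "chr1", 2), list(RESERVED_COLUMNS))

    def test_simulated_byproducts_match_planted_labels(self):
        from paircraft import ParseConfig, SimConfig, parse_stream
        from paircraft import simulate_genome, simulate_library

        config = SimConfig(
            seed=13,
            n_molecules=600,
            byproduct_rates=(0.25, 0.25, 0.25),
            restriction_site="GATC",
            chromosomes=[("chr1", 400_000), ("chr2", 300_000)],
        )
        genome = simulate_genome(config)
        truths, sam_lines = simulate_library(config, genome)
        frag_map = digest_genome(genome.sequences, "GATC")
        _, records = parse_stream(
            iter(l + "\n" for l in sam_lines),
            genome.chromsizes,
            ParseConfig(walk_policy="5unique"),
        )
        got = {
            r.read_id: classify_byproduct(
                annotate_restriction(r, frag_map), ANNOTATED_COLUMNS
            )
            for r in records
        }
        for t in truths:
            want = t.kind if t.kind != "contact" else "valid"
            assert got[t.read_id] == want


class TestPhase:
    CONFIG = PhaseConfig()

    def test_tied_homolog_is_unresolved(self):
        status, base = phase_side(
            "chr1#0", 60, [(60, "chr1#1", 500, "+")], self.CONFIG
        )
        assert (status, base) == (".", "chr1")

    def test_clear_winner_resolves_to_haplotype(self):
        status, base = phase_side(
            "chr1#1", 60, [(40, "chr1#0", 500, "+")], self.CONFIG
        )
        assert (status, base) == ("1", "chr1")

    def test_tie_elsewhere_is_multi(self):
        status, _ = phase_side("chr1#0", 60, [(60, "chr2#0", 9, "+")], self.CONFIG)
        assert status == "!"

    def test_no_subopt_resolves(self):
        assert phase_side("chr1#0", 60, [], self.CONFIG) == ("0", "chr1")

    def test_unrecognized_suffix_rejected(self):
        with pytest.raises(ValueError, match="suffix"):
            phase_side("chr1", 60, [], self.CONFIG)

    def test_tie_margin(self):
        config = PhaseConfig(score_tie_margin=5)
        status, _ = phase_side("chr1#0", 60, [(57, "chr1#1", 5, "+")], config)
        assert status == "."

    def _diploid_run(self, snv_rate, seed=21, n=1500):
        from paircraft import ParseConfig, SimConfig, parse_stream
        from paircraft import simulate_genome, simulate_library

        config = SimConfig(seed=seed, n_molecules=n, snv_rate=snv_rate)
        genome = simulate_genome(config)
        truths, sam_lines = simulate_library(config, genome)
        cols = ["score1", "score2", "alt1", "alt2"]
        header, records = parse_stream(
            iter(l + "\n" for l in sam_lines),
            genome.chromsizes,
            ParseConfig(walk_policy="5unique", extra_columns=cols),
        )
        pre = list(records)
        new_columns, phased = phase_pairs(pre, header.columns)
        return truths, header, pre, new_columns, list(phased)

    def test_zero_snvs_all_unresolved(self):
        _, _, _, cols, phased = self._diploid_run(snv_rate=1e-9, n=300)
        i1, i2 = cols[8:].index("phase1"), cols[8:].index("phase2")
        for r in phased:
            assert r.extras[i1] == "." and r.extras[i2] == "."

    def test_snv_covered_sides_resolve_to_planted_haplotype(self):
        truths, header, pre, cols, phased = self._diploid_run(snv_rate=0.01)
        names = header.columns[8:]
        i_s1, i_x1 = names.index("score1"), names.index("alt1")
        i_s2, i_x2 = names.index("score2"), names.index("alt2")
        i_p1, i_p2 = cols[8:].index("phase1"), cols[8:].index("phase2")
        n_resolved = {"0": 0, "1": 0}
        for before, after in zip(pre, phased):
            for chrom, i_s, i_x, i_p in (
                (before.chrom1, i_s1, i_x1, i_p1),
                (before.chrom2, i_s2, i_x2, i_p2),
            ):
                alt = before.extras[i_x]
                score = int(before.extras[i_s])
                phase = after.extras[i_p]
                subopt = (
                    max(int(h.split(",")[3]) for h in alt.rstrip(";").split(";"))
                    if alt != "."
                    else None
                )
                if subopt is not None and subopt < score:
                    # a distinguishing variant: must resolve to the suffix
                    assert phase == chrom.rpartition("#")[2]
                    n_resolved[phase] += 1
                elif subopt == score:
                    assert phase == "."
        # symmetric homolog treatment: balance within 3 binomial SD of 1:1
        total = n_resolved["0"] + n_resolved["1"]
        assert total > 100
        assert abs(n_resolved["0"] - n_resolved["1"]) <= 3 * np.sqrt(total)


class TestFilterByCoverage:
    def _pairs_in_bin(self, n, bin_pos=100):
        return [
            rec("chr1", bin_pos + i, "chr1", bin_pos + 50 + i, rid=f"r{i}")
            for i in range(n)
        ]

    def test_boundary_is_strict(self):
        records = self._pairs_in_bin(4)  # 8 sides in one bin
        kept, removed, _ = filter_by_coverage(
            records, CoverageFilterConfig(bin_size=1000, max_coverage=8)
        )
        assert len(kept) == 4 and not removed

    def test_above_threshold_all_removed(self):
        records = self._pairs_in_bin(5)  # 10 sides in one bin
        kept, removed, _ = filter_by_coverage(
            records, CoverageFilterConfig(bin_size=1000, max_coverage=8)
        )
        assert not kept and len(removed) == 5

    def test_matches_two_pass_oracle_and_order_independence(self):
        rng = np.random.default_rng(3)
        records = [
            rec(
                "chr1",
                int(rng.integers(1, 20_000)),
                "chr1",
                int(rng.integers(1, 20_000)),
                rid=f"r{i}",
            )
            for i in range(500)
        ]
        config = CoverageFilterConfig(bin_size=500, max_coverage=15)
        kept, removed, coverage = filter_by_coverage(records, config)
        # brute-force recomputation
        cov = {}
        for r in records:
            for pos in (r.pos1, r.pos2):
                key = ("chr1", (pos - 1) // 500)
                cov[key] = cov.get(key, 0) + 1
        expected_removed = {
            r.read_id
            for r in records
            if cov[("chr1", (r.pos1 - 1) // 500)] > 15
            or cov[("chr1", (r.pos2 - 1) // 500)] > 15
        }
        assert {r.read_id for r in removed} == expected_removed
        # shuffled input removes the same set
        shuffled = list(records)
        rng.shuffle(shuffled)
        _, removed2, _ = filter_by_coverage(shuffled, config)
        assert {r.read_id for r in removed2} == expected_removed
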