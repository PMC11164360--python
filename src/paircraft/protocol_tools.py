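"""Protocol-specific processing: restriction annotation, phasing, coverage filter.

Restriction-based protocols (classic Hi-C) should ligate only between
restriction fragments; annotating each pair side with its fragment exposes
the classic by-products — dangling ends (unligated fragments, convergent
orientation on one fragment), self-circles (divergent) and mirror pairs
(equal orientations, putative PCR artifacts). Haplotype-resolved protocols
map reads against a diploid reference carrying both homologs and use the
best suboptimal alignment scores to separate resolved sides from
unresolvable ones (no covering variant) and true multi-mappers. Single-cell
protocols require masking genomic bins whose coverage exceeds what the
chromosome copy number allows.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .pairs_format import NULL_CHROM, PairRecord

IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "[AG]",
    "Y": "[CT]",
    "S": "[CG]",
    "W": "[AT]",
    "K": "[GT]",
    "M": "[AC]",
    "B": "[CGT]",
    "D": "[AGT]",
    "H": "[ACT]",
    "V": "[ACG]",
    "N": "[ACGT]",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

RESTRICTION_EXTRA_COLUMNS = (
    "rfrag1_idx",
    "rfrag1_start",
    "rfrag1_end",
    "rfrag2_idx",
    "rfrag2_start",
    "rfrag2_end",
)


def reverse_complement(pattern: str) -> str:
    return pattern.translate(_COMPLEMENT)[::-1]


def _iupac_regex(pattern: str) -> re.Pattern:
    try:
        body = "".join(IUPAC[ch] for ch in pattern.upper())
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC letter in pattern {pattern!r}") from exc
    return re.compile(f"(?={body})")  # lookahead: overlapping matches allowed


@dataclass
class FragmentMap:
    """Per-chromosome sorted restriction-fragment start positions.

    Fragment i of a chromosome is the half-open interval
    [start_i, start_{i+1}), 1-based, with the first start at 1 and a virtual
    end boundary at chromosome length + 1.
    """

    starts: dict[str, np.ndarray]
    lengths: dict[str, int]

    def n_fragments(self, chrom: str) -> int:
        return len(self.starts[chrom])

    def locate(self, chrom: str, pos: int) -> tuple[int, int, int]:
        """(fragment ordinal, start, exclusive end) containing a 1-based pos."""
        if chrom not in self.starts:
            raise KeyError(f"chromosome {chrom!r} not in fragment map")
        if pos < 1 or pos > self.lengths[chrom]:
            raise ValueError(
                f"position {pos} outside chromosome {chrom} "
                f"(length {self.lengths[chrom]})"
            )
        starts = self.starts[chrom]
        idx = int(np.searchsorted(starts, pos, side="right")) - 1
        start = int(starts[idx])
        end = int(starts[idx + 1]) if idx + 1 < len(starts) else self.lengths[chrom] + 1
        return idx, start, end

    def to_bed_rows(self) -> Iterable[tuple[str, int, int]]:
        """BED3-compatible (chrom, 0-based start, end) fragment rows."""
        for chrom, starts in self.starts.items():
            bounds = list(starts) + [self.lengths[chrom] + 1]
            for a, b in zip(bounds, bounds[1:]):
                yield chrom, int(a) - 1, int(b) - 1


def digest_genome(
    sequences: Mapping[str, str], recognition: str
) -> FragmentMap:
    """Digest sequences at every match of an IUPAC recognition pattern.

    A fragment boundary is placed at position 1 and at the first base of
    every match of the pattern or of its reverse complement (palindromic
    sites are counted once). Matching is overlapping and case-insensitive.
    """
    fwd = _iupac_regex(recognition)
    rc = reverse_complement(recognition.upper())
    patterns = [fwd]
    if rc != recognition.upper():
        patterns.append(_iupac_regex(rc))
    starts: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    for chrom, seq in sequences.items():
        seq_u = seq.upper()
        cuts = {1}
        for pat in patterns:
            cuts.update(m.start() + 1 for m in pat.finditer(seq_u))
        starts[chrom] = np.array(sorted(cuts), dtype=np.int64)
        lengths[chrom] = len(seq)
    return FragmentMap(starts=starts, lengths=lengths)


def annotate_restriction(record: PairRecord, frags: FragmentMap) -> PairRecord:
    """Append restriction-fragment extras (idx, start, end per side).

    Null sides are annotated with the sentinel -1.
    """
    out = record.copy()
    for chrom, pos in ((record.chrom1, record.pos1), (record.chrom2, record.pos2)):
        if chrom == NULL_CHROM:
            out.extras.extend(["-1", "-1", "-1"])
        else:
            idx, start, end = frags.locate(chrom, pos)
            out.extras.extend([str(idx), str(start), str(end)])
    return out


def classify_byproduct(record: PairRecord, columns: Sequence[str]) -> str:
    """Classify an annotated pair as valid or a same-fragment by-product.

    For a flipped record (side 1 genomically first): pairs on the same
    restriction fragment in convergent (+,-) orientation are dangling ends,
    divergent (-,+) are self-circles and equal-strand pairs are mirrors;
    pairs joining different fragments are valid contacts.
    """
    extras_names = list(columns[8:])
    try:
        i1 = extras_names.index("rfrag1_idx")
        i2 = extras_names.index("rfrag2_idx")
    except ValueError:
        raise ValueError(
            "record lacks restriction annotations; run annotate_restriction first"
        ) from None
    if record.chrom1 != record.chrom2:
        return "valid"
    if record.extras[i1] == "-1" or record.extras[i2] == "-1":
        raise ValueError("cannot classify a pair with a null side")
    if record.extras[i1] != record.extras[i2]:
        return "valid"
    strands = (record.strand1, record.strand2)
    if strands == ("+", "-"):
        return "dangling_end"
    if strands == ("-", "+"):
        return "self_circle"
    return "mirror"


@dataclass
class PhaseConfig:
    """Haplotype-suffix convention and score-tie margin for phasing.

    Chromosome names in the diploid reference are ``base + separator +
    suffix``, e.g. ``chr1#0`` / ``chr1#1``. Two alignments are considered
    tied when their scores differ by at most ``score_tie_margin``.
    """

    haplotype_suffixes: tuple[str, str] = ("0", "1")
    separator: str = "#"
    score_tie_margin: int = 0

    def __post_init__(self) -> None:
        if self.haplotype_suffixes[0] == self.haplotype_suffixes[1]:
            raise ValueError("haplotype suffixes must be distinct")

    def split(self, chrom: str) -> tuple[str, str]:
        base, sep, suffix = chrom.rpartition(self.separator)
        if not sep or suffix not in self.haplotype_suffixes:
            raise ValueError(
                f"chromosome {chrom!r} carries no recognized haplotype suffix"
            )
        return base, suffix


PHASE_UNRESOLVED = "."
PHASE_MULTI = "!"


def phase_side(
    chrom: str,
    best: int,
    subopt: Sequence[tuple[int, str, int, str]] | Sequence[tuple[int, str, int]],
    config: PhaseConfig,
) -> tuple[str, str]:
    """Phase one aligned side from its best and suboptimal alignment scores.

    Returns (phase, base chromosome name) where phase is "0"/"1" for a side
    resolved to the first/second haplotype, "." for an unresolved side (the
    only tied alternative is the homologous locus — no covering variant) and
    "!" for a true multi-mapper (a tied alternative elsewhere).
    """
    base, suffix = config.split(chrom)
    ties = [hit for hit in subopt if hit[0] >= best - config.score_tie_margin]
    if not ties:
        phase = "0" if suffix == config.haplotype_suffixes[0] else "1"
        return phase, base
    for hit in ties:
        alt_chrom = hit[1]
        try:
            alt_base, alt_suffix = config.split(alt_chrom)
        except ValueError:
            return PHASE_MULTI, base
        if alt_base != base or alt_suffix == suffix:
            return PHASE_MULTI, base
    return PHASE_UNRESOLVED, base


def _parse_alt(text: str) -> list[tuple[int, str, int, str]]:
    if not text or text == ".":
        return []
    hits = []
    for item in text.split(";"):
        if not item:
            continue
        chrom, pos, strand, score = item.split(",")
        hits.append((int(score), chrom, int(pos), strand))
    return hits


def phase_pairs(
    records: Iterable[PairRecord],
    columns: Sequence[str],
    config: PhaseConfig | None = None,
) -> tuple[list[str], Iterable[PairRecord]]:
    """Phase both sides of every record; returns (new columns, record stream).

    Requires the score1/score2 and alt1/alt2 extra columns emitted by parse.
    Chromosome names are rewritten to their base (suffix-free) names and
    ``phase1``/``phase2`` extras are appended, enabling downstream dedup to
    match on phase and stats to stratify by it.
    """
    if config is None:
        config = PhaseConfig()
    extras_names = list(columns[8:])
    for required in ("score1", "score2", "alt1", "alt2"):
        if required not in extras_names:
            raise ValueError(f"phasing requires the extra column {required!r}")
    i_score1 = extras_names.index("score1")
    i_score2 = extras_names.index("score2")
    i_alt1 = extras_names.index("alt1")
    i_alt2 = extras_names.index("alt2")
    new_columns = list(columns) + ["phase1", "phase2"]

    def _stream() -> Iterable[PairRecord]:
        for rec in records:
            out = rec.copy()
            phases = []
            for side, (chrom, i_score, i_alt) in enumerate(
                ((rec.chrom1, i_score1, i_alt1), (rec.chrom2, i_score2, i_alt2)), 1
            ):
                if chrom == NULL_CHROM:
                    phases.append(PHASE_UNRESOLVED)
                    continue
                best = int(rec.extras[i_score])
                subopt = _parse_alt(rec.extras[i_alt])
                phase, base = phase_side(chrom, best, subopt, config)
                phases.append(phase)
                if side == 1:
                    out.chrom1 = base
                else:
                    out.chrom2 = base
            out.extras.extend(phases)
            yield out

    return new_columns, _stream()


@dataclass
class CoverageFilterConfig:
    bin_size: int = 1000
    max_coverage: int = 10

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if self.max_coverage < 1:
            raise ValueError("max_coverage must be >= 1")


def filter_by_coverage(
    records: Sequence[PairRecord],
    config: CoverageFilterConfig | None = None,
) -> tuple[list[PairRecord], list[PairRecord], dict[tuple[str, int], int]]:
    """Two-pass single-cell coverage filter.

    Pass one counts pair *sides* per genomic bin; pass two removes every
    record either side of which falls in a bin whose coverage strictly
    exceeds ``max_coverage``. Returns (kept, removed, coverage track).
    """
    if config is None:
        config = CoverageFilterConfig()
    coverage: dict[tuple[str, int], int] = {}
    for rec in records:
        for chrom, pos in ((rec.chrom1, rec.pos1), (rec.chrom2, rec.pos2)):
            if chrom == NULL_CHROM:
                continue
            key = (chrom, (pos - 1) // config.bin_size)
            coverage[key] = coverage.get(key, 0) + 1
    kept: list[PairRecord] = []
    removed: list[PairRecord] = []
    for rec in records:
        high = False
        for chrom, pos in ((rec.chrom1, rec.pos1), (rec.chrom2, rec.pos2)):
            if chrom == NULL_CHROM:
                continue
            if coverage[(chrom, (pos - 1) // config.bin_size)] > config.max_coverage:
                high = True
                break
        (removed if high else kept).append(rec)
    return kept, removed, coverage
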