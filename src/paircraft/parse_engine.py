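"""Conversion of read bundles into contact pairs.

A chimeric 3C+ molecule is sequenced from both ends; each mate may align in
several pieces (reported by a local aligner as a primary alignment plus
supplementary records). This module orders those pieces along each read,
inserts null segments for unaligned gaps, removes readthrough-duplicated
3' copies, rescues single-ligation three-alignment molecules, and expands
multi-junction molecules ("walks") according to a configurable policy.

Per-side mapping classes: N (null/unmapped), M (mapped but below the mapq
threshold), U (unique), R (rescued), W (masked walk), D (duplicate,
assigned downstream by dedup). The reported position of a side is the 5'
end of its chosen alignment on the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .alignment_ingest import Alignment, ReadBundle, read_sam
from .pairs_format import NULL_CHROM, PairRecord, PairsHeader, RESERVED_COLUMNS
from .sort_merge import ChromOrder, flip_pair

WALK_POLICIES = ("mask", "all", "5unique", "5any", "3unique", "3any")

#: extra columns parse can emit, in canonical order
KNOWN_EXTRA_COLUMNS = (
    "mapq1",
    "mapq2",
    "algn_ref_span1",
    "algn_ref_span2",
    "score1",
    "score2",
    "subopt_score1",
    "subopt_score2",
    "alt1",
    "alt2",
    "walk_pair_index",
)

Segment = Alignment | None  # None encodes a null (unaligned-gap) segment


@dataclass(slots=True)
class ParseConfig:
    """Tunables of contact extraction.

    ``min_mapq`` separates unique (U) from multi (M) alignments;
    ``max_molecule_size`` bounds the genomic separation allowed when rescuing
    a three-alignment single ligation; ``max_inter_align_gap`` is the length
    of unaligned read sequence tolerated between chained segments before a
    null segment is inserted.
    """

    min_mapq: int = 1
    max_molecule_size: int = 750
    max_inter_align_gap: int = 20
    walk_policy: str = "mask"
    flip: bool = True
    extra_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")
        if self.max_molecule_size <= 0:
            raise ValueError("max_molecule_size must be > 0")
        if self.walk_policy not in WALK_POLICIES:
            raise ValueError(
                f"unknown walk policy {self.walk_policy!r}; "
                f"choose one of {WALK_POLICIES}"
            )
        for name in self.extra_columns:
            if name not in KNOWN_EXTRA_COLUMNS:
                raise ValueError(f"unknown extra column {name!r}")

    def output_columns(self) -> list[str]:
        cols = list(RESERVED_COLUMNS) + list(self.extra_columns)
        if self.walk_policy == "all" and "walk_pair_index" not in cols:
            cols.append("walk_pair_index")
        return cols


@dataclass(slots=True)
class SegmentChain:
    """Ordered (5'->3' in read coordinates) segments of one read side."""

    side: int
    segments: list[Segment]

    def mapped(self) -> list[Alignment]:
        return [s for s in self.segments if s is not None]

    def __len__(self) -> int:
        return len(self.segments)


def classify(segment: Segment, config: ParseConfig) -> str:
    if segment is None or not segment.is_mapped:
        return "N"
    if segment.mapq < config.min_mapq:
        return "M"
    return "U"


def build_chains(bundle: ReadBundle, config: ParseConfig) -> tuple[SegmentChain, SegmentChain]:
    """Order each side's alignments along the read and insert null segments.

    Secondary alignments are excluded from chains. Overlapping read spans are
    resolved deterministically: higher mapq wins, then the longer span, then
    the 5'-most. Null segments mark unaligned stretches (leading, internal or
    trailing) longer than ``max_inter_align_gap``, and fully unmapped sides.
    """
    return (
        _build_side_chain(bundle.side1, 1, config),
        _build_side_chain(bundle.side2, 2, config),
    )


def _build_side_chain(
    alignments: Sequence[Alignment], side: int, config: ParseConfig
) -> SegmentChain:
    mapped = [a for a in alignments if a.is_mapped and not a.is_secondary]
    read_len = max((a.read_len for a in alignments), default=0)
    if not mapped:
        return SegmentChain(side=side, segments=[None])
    mapped.sort(key=lambda a: (a.read_start, a.read_end))
    kept: list[Alignment] = []
    for aln in mapped:
        if kept and aln.read_start < kept[-1].read_end:
            prev = kept[-1]
            # overlap: keep higher mapq, then longer read span, then 5'-most
            key = lambda a: (a.mapq, a.read_end - a.read_start, -a.read_start)
            if key(aln) > key(prev):
                kept[-1] = aln
        else:
            kept.append(aln)
    gap = config.max_inter_align_gap
    segments: list[Segment] = []
    if kept[0].read_start > gap:
        segments.append(None)
    for prev, cur in zip(kept, kept[1:]):
        segments.append(prev)
        if cur.read_start - prev.read_end > gap:
            segments.append(None)
    segments.append(kept[-1])
    if read_len - kept[-1].read_end > gap:
        segments.append(None)
    return SegmentChain(side=side, segments=segments)


def _same_fragment(a: Segment, b: Segment) -> bool:
    """Do two alignments (from opposite mates) represent one genomic fragment?

    True when they share a chromosome, have opposite strands (as expected for
    copies read from opposite molecule ends) and their reference spans
    overlap by at least one bp.
    """
    if a is None or b is None or not a.is_mapped or not b.is_mapped:
        return False
    return (
        a.chrom == b.chrom
        and a.strand != b.strand
        and max(a.ref_start, b.ref_start) <= min(a.ref_end, b.ref_end)
    )


def collapse_readthrough(
    chain1: SegmentChain, chain2: SegmentChain, config: ParseConfig
) -> tuple[SegmentChain, SegmentChain]:
    """Remove readthrough-duplicated 3' copies so each fragment appears once.

    When sequencing reads past a ligation junction on both mates, the same
    genomic fragments appear at the 3' ends of both sides. The maximal
    overlap between side 1's 3' end and side 2's 3' end (compared in merged
    molecule order) is detected, and within each duplicated pair the copy
    starting more 3' in its own read is dropped.
    """
    segs1 = list(chain1.segments)
    segs2 = list(chain2.segments)
    rev2 = segs2[::-1]
    best_k = 0
    for k in range(min(len(segs1), len(rev2)), 0, -1):
        if all(_same_fragment(segs1[len(segs1) - k + i], rev2[i]) for i in range(k)):
            best_k = k
            break
    if best_k == 0:
        return chain1, chain2
    drop1: set[int] = set()
    drop2: set[int] = set()
    for i in range(best_k):
        i1 = len(segs1) - best_k + i
        i2 = len(segs2) - 1 - i
        a, b = segs1[i1], segs2[i2]
        if a.read_start > b.read_start:
            drop1.add(i1)
        else:
            drop2.add(i2)
    new1 = [s for i, s in enumerate(segs1) if i not in drop1]
    new2 = [s for i, s in enumerate(segs2) if i not in drop2]
    return (
        SegmentChain(side=1, segments=new1),
        SegmentChain(side=2, segments=new2),
    )


def rescue_single_ligation(
    chain1: SegmentChain, chain2: SegmentChain, config: ParseConfig
) -> tuple[Segment, Segment, int] | None:
    """Rescue a three-alignment molecule into a single contact pair.

    One side holds two unique segments (5' "red", 3' "green"), the mate a
    single unique segment ("blue"). When green and blue lie on the same
    chromosome, on opposite strands, with 5' positions separated by at most
    ``max_molecule_size``, they are two reads of the same sequenced fragment
    and the true contact is (red, blue). Returns (seg_side1, seg_side2,
    rescued_side) or None when the molecule is a genuine walk.
    """
    m1, m2 = chain1.mapped(), chain2.mapped()
    if len(m1) + len(m2) != 3 or not (len(m1) in (1, 2)):
        return None
    if None in chain1.segments or None in chain2.segments:
        return None
    if len(m1) == 2:
        red, green, blue, rescued_side = m1[0], m1[1], m2[0], 1
    else:
        red, green, blue, rescued_side = m2[0], m2[1], m1[0], 2
    for seg in (red, green, blue):
        if classify(seg, config) != "U":
            return None
    if green.chrom != blue.chrom or green.strand == blue.strand:
        return None
    if abs(green.pos5 - blue.pos5) > config.max_molecule_size:
        return None
    if rescued_side == 1:
        return (red, blue, 1)
    return (blue, red, 2)


def _first_of_class(segments: Sequence[Segment], config: ParseConfig, unique: bool) -> Segment:
    for seg in segments:
        if not unique or classify(seg, config) == "U":
            return seg
    return None


def expand_walk(
    merged: Sequence[Segment],
    chain1: SegmentChain,
    chain2: SegmentChain,
    config: ParseConfig,
) -> list[tuple[Segment, Segment, int | None, str | None]]:
    """Expand a multi-junction molecule per the configured walk policy.

    Returns (segment1, segment2, junction_index, type_override) tuples.
    ``mask`` emits a single null-coordinate record typed "WW"; ``all`` emits
    one record per adjacent segment pair; the 5/3 policies report the two
    extreme segments, one per side for the *unique variants, possibly both
    from one side for the *any variants when the mate is fully unmapped.
    """
    policy = config.walk_policy
    if policy == "mask":
        return [(None, None, None, "WW")]
    if policy == "all":
        return [
            (merged[j], merged[j + 1], j + 1, None)
            for j in range(len(merged) - 1)
        ]
    from_5prime = policy.startswith("5")
    unique = policy.endswith("unique")
    segs1 = chain1.segments if from_5prime else chain1.segments[::-1]
    segs2 = chain2.segments if from_5prime else chain2.segments[::-1]
    s1 = _first_of_class(segs1, config, unique)
    s2 = _first_of_class(segs2, config, unique)
    if not unique:
        # a fully unmapped mate lets the *any policies take both extreme
        # segments from the mapped side
        if not chain2.mapped() and len(segs1) >= 2:
            s1, s2 = segs1[0], segs1[1]
        elif not chain1.mapped() and len(segs2) >= 2:
            s1, s2 = segs2[0], segs2[1]
    return [(s1, s2, None, None)]


def assign_pair_type(
    seg1: Segment, seg2: Segment, config: ParseConfig
) -> str:
    """Two-letter pair-type code from per-side mapping classes."""
    return classify(seg1, config) + classify(seg2, config)


def _seg_fields(seg: Segment) -> tuple[str, int, str]:
    if seg is None or not seg.is_mapped:
        return NULL_CHROM, 0, "."
    return seg.chrom, seg.pos5, seg.strand


def _extra_value(name: str, seg1: Segment, seg2: Segment, junction: int | None) -> str:
    if name == "walk_pair_index":
        return str(junction if junction is not None else 1)
    side = 1 if name.endswith("1") else 2
    seg = seg1 if side == 1 else seg2
    base = name[:-1]
    if seg is None or not seg.is_mapped:
        return "0" if base in ("mapq", "algn_ref_span", "score", "subopt_score") else "."
    if base == "mapq":
        return str(seg.mapq)
    if base == "algn_ref_span":
        return str(seg.ref_span)
    if base == "score":
        return str(seg.score if seg.score is not None else 0)
    if base == "subopt_score":
        return str(seg.subopt_score if seg.subopt_score is not None else 0)
    if base == "alt":
        if not seg.subopt:
            return "."
        return ";".join(
            f"{chrom},{pos},{strand},{score}" for score, chrom, pos, strand in seg.subopt
        )
    raise ValueError(f"unknown extra column {name!r}")


def parse_bundle(
    bundle: ReadBundle,
    config: ParseConfig,
    order: ChromOrder,
) -> list[PairRecord]:
    """Extract the contact pair(s) of one read bundle.

    Composition: build chains -> collapse readthrough -> emit a simple pair
    (single junction), rescue the three-alignment case, or expand the walk;
    then assign the pair type and flip into canonical orientation.
    """
    chain1, chain2 = build_chains(bundle, config)
    chain1, chain2 = collapse_readthrough(chain1, chain2, config)
    merged: list[Segment] = list(chain1.segments) + list(chain2.segments)[::-1]

    picks: list[tuple[Segment, Segment, int | None, str | None]]
    if len(merged) <= 1:
        return []  # fully collapsed single fragment: no ligation junction
    if len(merged) == 2:
        picks = [(merged[0], merged[1], None, None)]
    else:
        rescued = rescue_single_ligation(chain1, chain2, config)
        if rescued is not None:
            s1, s2, rescued_side = rescued
            type_override = "RU" if rescued_side == 1 else "UR"
            picks = [(s1, s2, None, type_override)]
        else:
            picks = expand_walk(merged, chain1, chain2, config)

    columns = config.output_columns()
    extra_names = columns[8:]
    records = []
    for s1, s2, junction, type_override in picks:
        chrom1, pos1, strand1 = _seg_fields(s1)
        chrom2, pos2, strand2 = _seg_fields(s2)
        pair_type = type_override or assign_pair_type(s1, s2, config)
        extras = [_extra_value(name, s1, s2, junction) for name in extra_names]
        record = PairRecord(
            read_id=bundle.read_id,
            chrom1=chrom1,
            pos1=pos1,
            chrom2=chrom2,
            pos2=pos2,
            strand1=strand1,
            strand2=strand2,
            pair_type=pair_type,
            extras=extras,
        )
        if config.flip:
            record = flip_pair(record, order, columns)
        records.append(record)
    return records


def parse_stream(
    sam_stream: Iterable[str],
    chromsizes: Sequence[tuple[str, int]],
    config: ParseConfig | None = None,
    command: str | None = None,
) -> tuple[PairsHeader, Iterator[PairRecord]]:
    """Parse a name-grouped SAM text stream into a ``.pairs`` header + records."""
    if config is None:
        config = ParseConfig()
    sam_header, bundles = read_sam(sam_stream)
    header = PairsHeader(
        chromsizes=list(chromsizes),
        columns=config.output_columns(),
        samheader_lines=sam_header,
        provenance=[command] if command else [],
    )
    order = ChromOrder.from_chromsizes(chromsizes)

    def _records() -> Iterator[PairRecord]:
        for bundle in bundles:
            yield from parse_bundle(bundle, config, order)

    return header, _records()
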