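"""Distilling SAM text records into alignments grouped per sequenced read pair.

The input is name-grouped SAM text, as produced by a local aligner run on the
two mates of each read pair independently (for bwa mem, the ``-SP`` flags).
Each SAM line is reduced to an :class:`Alignment`: the reference span
(computed by walking the CIGAR), the strand, the mapping quality, the aligned
portion of the read in original read orientation (clip-aware), and the
alignment scores needed downstream for uniqueness classification and
haplotype phasing.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

NULL_CHROM = "!"

FLAG_PAIRED = 0x1
FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = frozenset("MDN=X")
_QUERY_CONSUMING = frozenset("MI=X")


class SamFormatError(ValueError):
    """A line that does not parse as a SAM alignment record."""


@dataclass(slots=True)
class Alignment:
    """One SAM entry distilled to what contact extraction needs.

    ``ref_start``/``ref_end`` are a 1-based closed span on the reference;
    ``read_start``/``read_end`` are a 0-based half-open span of the aligned
    portion within the original read, reported in read orientation (i.e. for
    a reverse-strand alignment the soft/hard clips are swapped before the
    span is computed).
    """

    read_id: str
    is_mapped: bool
    chrom: str
    ref_start: int
    ref_end: int
    strand: str
    mapq: int
    read_start: int
    read_end: int
    read_len: int
    side: int
    score: int | None = None
    subopt_score: int | None = None
    subopt: list[tuple[int, str, int, str]] = field(default_factory=list)
    is_supplementary: bool = False
    is_secondary: bool = False

    @property
    def pos5(self) -> int:
        """5' end of the alignment on the reference (strand-dependent)."""
        return self.ref_start if self.strand == "+" else self.ref_end

    @property
    def pos3(self) -> int:
        return self.ref_end if self.strand == "+" else self.ref_start

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start + 1 if self.is_mapped else 0


@dataclass(slots=True)
class ReadBundle:
    """All alignments of one sequenced read pair, split by mate."""

    read_id: str
    side1: list[Alignment] = field(default_factory=list)
    side2: list[Alignment] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.side1) + len(self.side2)


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = _CIGAR_RE.findall(cigar)
    if not ops or "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise SamFormatError(f"malformed CIGAR {cigar!r}")
    return [(int(n), op) for n, op in ops]


def parse_sam_record(line: str) -> Alignment:
    """Distill one SAM alignment line into an :class:`Alignment`.

    The reference span is computed from the reference-consuming CIGAR
    operations (M/D/N/=/X), the read span from clips and query-consuming
    operations, flipped into original read orientation for reverse-strand
    alignments. AS/XS/XA tags feed the score fields used for uniqueness and
    phasing.
    """
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 11:
        raise SamFormatError(f"SAM line has {len(fields)} fields, expected >= 11")
    qname, flag_s, rname, pos_s, mapq_s = fields[:5]
    cigar = fields[5]
    try:
        flag = int(flag_s)
        pos = int(pos_s)
        mapq = int(mapq_s)
    except ValueError as exc:
        raise SamFormatError(f"non-integer SAM field in line: {line[:80]!r}") from exc

    side = 2 if flag & FLAG_SECOND else 1
    strand = "-" if flag & FLAG_REVERSE else "+"
    is_mapped = not (flag & FLAG_UNMAPPED) and rname != "*"
    if is_mapped and cigar == "*":
        warnings.warn(
            f"mapped SAM record {qname!r} lacks a CIGAR; treated as unmapped",
            stacklevel=2,
        )
        is_mapped = False

    score: int | None = None
    subopt_score: int | None = None
    xa_hits: list[tuple[str, int, str]] = []
    for tag in fields[11:]:
        if tag.startswith("AS:i:"):
            score = int(tag[5:])
        elif tag.startswith("XS:i:"):
            subopt_score = int(tag[5:])
        elif tag.startswith("XA:Z:"):
            for hit in tag[5:].rstrip(";").split(";"):
                if not hit:
                    continue
                parts = hit.split(",")
                if len(parts) >= 2:
                    xa_chrom = parts[0]
                    xa_strand = parts[1][0]
                    xa_pos = int(parts[1][1:])
                    xa_hits.append((xa_chrom, xa_pos, xa_strand))

    if not is_mapped:
        read_len = len(fields[9]) if fields[9] != "*" else 0
        return Alignment(
            read_id=qname,
            is_mapped=False,
            chrom=NULL_CHROM,
            ref_start=0,
            ref_end=0,
            strand=".",
            mapq=mapq,
            read_start=0,
            read_end=0,
            read_len=read_len,
            side=side,
            score=score,
            subopt_score=subopt_score,
            is_supplementary=bool(flag & FLAG_SUPPLEMENTARY),
            is_secondary=bool(flag & FLAG_SECONDARY),
        )

    ops = _parse_cigar(cigar)
    ref_span = sum(n for n, op in ops if op in _REF_CONSUMING)
    query_len = sum(n for n, op in ops if op in _QUERY_CONSUMING)
    clip_left = 0
    for n, op in ops:
        if op in "SH":
            clip_left += n
        else:
            break
    clip_right = 0
    for n, op in reversed(ops):
        if op in "SH":
            clip_right += n
        else:
            break
    read_len = clip_left + query_len + clip_right
    # clips are reported in reference orientation; flip for reverse strand
    if strand == "-":
        read_start = clip_right
    else:
        read_start = clip_left
    read_end = read_start + query_len

    # the best-subopt score (XS) is paired with the reported alternative
    # locations (XA); bwa-style XA entries carry no score of their own
    subopt: list[tuple[int, str, int, str]] = []
    if xa_hits:
        assigned = subopt_score if subopt_score is not None else (score or 0)
        for xa_chrom, xa_pos, xa_strand in xa_hits[:2]:
            subopt.append((assigned, xa_chrom, xa_pos, xa_strand))

    return Alignment(
        read_id=qname,
        is_mapped=True,
        chrom=rname,
        ref_start=pos,
        ref_end=pos + ref_span - 1,
        strand=strand,
        mapq=mapq,
        read_start=read_start,
        read_end=read_end,
        read_len=read_len,
        side=side,
        score=score,
        subopt_score=subopt_score,
        subopt=subopt,
        is_supplementary=bool(flag & FLAG_SUPPLEMENTARY),
        is_secondary=bool(flag & FLAG_SECONDARY),
    )


def iter_sam_lines(stream: Iterable[str]) -> Iterator[tuple[str | None, str]]:
    """Yield (header_line, None) / (None, alignment_line) split of SAM text."""
    for line in stream:
        if not line.strip():
            continue
        if line.startswith("@"):
            yield line.rstrip("\n"), ""
        else:
            yield None, line


def group_by_read(
    alignments: Iterable[Alignment],
) -> Iterator[ReadBundle]:
    """Group a name-grouped alignment stream into one bundle per read id.

    Raises when a read id reappears after a different one, i.e. when the
    input is not name-grouped.
    """
    seen: set[str] = set()
    bundle: ReadBundle | None = None
    for aln in alignments:
        if bundle is None or aln.read_id != bundle.read_id:
            if bundle is not None:
                yield bundle
            if aln.read_id in seen:
                raise ValueError(
                    f"input not name-grouped: read id {aln.read_id!r} reappears"
                )
            seen.add(aln.read_id)
            bundle = ReadBundle(read_id=aln.read_id)
        (bundle.side1 if aln.side == 1 else bundle.side2).append(aln)
    if bundle is not None:
        yield bundle


def read_sam(
    stream: Iterable[str],
) -> tuple[list[str], Iterator[ReadBundle]]:
    """Split SAM text into header lines and a lazy stream of read bundles."""
    it = iter(stream)
    header_lines: list[str] = []
    first_aln: str | None = None
    for line in it:
        if not line.strip():
            continue
        if line.startswith("@"):
            header_lines.append(line.rstrip("\n"))
        else:
            first_aln = line
            break

    def _alignments() -> Iterator[Alignment]:
        if first_aln is not None:
            yield parse_sam_record(first_aln)
        for line in it:
            if line.strip():
                yield parse_sam_record(line)

    return header_lines, group_by_read(_alignments())
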