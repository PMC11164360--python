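"""Canonical orientation (flipping), genomic sorting and k-way merging of pairs.

Sorting pairs on (chrom1, chrom2, pos1, pos2) arranges the table in blocks of
chromosome pairs, separates cis from trans contacts and puts duplicated
molecules on adjacent rows. Flipping first — placing the genomically lower
side of each pair first — makes the sort order reproducible and is a
precondition for duplicate detection.
"""

from __future__ import annotations

import heapq
import itertools
import tempfile
from typing import Iterable, Iterator, Sequence

from .pairs_format import (
    NULL_CHROM,
    PairRecord,
    PairsHeader,
    read_pairs,
)

# pair-type letters ordered for flipping: null < multi < walk/dup < unique-ish
_CLASS_RANK = {"N": 0, "M": 1, "W": 2, "D": 3, "X": 3, "R": 4, "U": 4}


class ChromOrder:
    """Chromosome name -> rank mapping; the null chromosome ranks last."""

    def __init__(self, chrom_names: Sequence[str]):
        self._rank = {name: i for i, name in enumerate(chrom_names)}
        self._null_rank = len(self._rank)

    @classmethod
    def from_chromsizes(cls, chromsizes: Sequence[tuple[str, int]]) -> "ChromOrder":
        return cls([name for name, _ in chromsizes])

    def rank(self, chrom: str) -> int:
        if chrom == NULL_CHROM:
            return self._null_rank
        try:
            return self._rank[chrom]
        except KeyError:
            raise ValueError(f"chromosome {chrom!r} not in chromosome order") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom == NULL_CHROM or chrom in self._rank

    def __len__(self) -> int:
        return len(self._rank)


def _side_extra_swaps(columns: Sequence[str]) -> list[tuple[int, int]]:
    """Indices (into extras) of side-paired extra columns to swap on flip."""
    extras = list(columns[8:])
    swaps = []
    for i, name in enumerate(extras):
        if name.endswith("1"):
            partner = name[:-1] + "2"
            if partner in extras:
                swaps.append((i, extras.index(partner)))
    return swaps


def flip_pair(
    record: PairRecord,
    order: ChromOrder,
    columns: Sequence[str] | None = None,
) -> PairRecord:
    """Return the record in canonical (upper-triangular) orientation.

    Sides are ordered primarily by mapping class (null < multi < unique, read
    from the pair-type letters) so that e.g. "UN" becomes "NU", then by
    (chromosome rank, position) for same-class sides. Strands, pair-type
    letters and side-paired extra columns (names ending in 1/2) are swapped
    consistently. Idempotent.
    """
    t = record.pair_type
    c1 = _CLASS_RANK.get(t[0], 4) if len(t) == 2 else 4
    c2 = _CLASS_RANK.get(t[1], 4) if len(t) == 2 else 4
    key1 = (c1, order.rank(record.chrom1), record.pos1)
    key2 = (c2, order.rank(record.chrom2), record.pos2)
    if key1 <= key2:
        return record
    flipped = record.copy()
    flipped.chrom1, flipped.chrom2 = record.chrom2, record.chrom1
    flipped.pos1, flipped.pos2 = record.pos2, record.pos1
    flipped.strand1, flipped.strand2 = record.strand2, record.strand1
    if len(t) == 2:
        flipped.pair_type = t[1] + t[0]
    if columns is not None and flipped.extras:
        for i, j in _side_extra_swaps(columns):
            flipped.extras[i], flipped.extras[j] = flipped.extras[j], flipped.extras[i]
    return flipped


def sort_key(record: PairRecord, order: ChromOrder) -> tuple:
    return (
        order.rank(record.chrom1),
        order.rank(record.chrom2),
        record.pos1,
        record.pos2,
        record.strand1,
        record.strand2,
        record.to_line(),
    )


def _check_flipped(record: PairRecord, order: ChromOrder) -> None:
    t = record.pair_type
    if len(t) == 2 and t[0] == t[1]:
        r1, r2 = order.rank(record.chrom1), order.rank(record.chrom2)
        if r1 > r2 or (r1 == r2 and record.pos1 > record.pos2):
            raise ValueError(
                f"unflipped record for read {record.read_id!r}: "
                f"({record.chrom1}:{record.pos1} | {record.chrom2}:{record.pos2})"
            )


def sort_pairs(
    records: Iterable[PairRecord],
    order: ChromOrder,
    chunk_size: int = 500_000,
    auto_flip: bool = False,
    tmpdir: str | None = None,
) -> Iterator[PairRecord]:
    """Sort records by (chrom1, chrom2, pos1, pos2, strands, line text).

    The final whole-line tie-break makes the order fully deterministic.
    Inputs larger than ``chunk_size`` are sorted externally: sorted runs are
    spilled to temporary files and merged with a k-way heap merge.
    """
    runs: list = []
    chunk: list[tuple[tuple, PairRecord]] = []

    def _keyed(record: PairRecord) -> tuple[tuple, PairRecord]:
        if auto_flip:
            record = flip_pair(record, order)
        else:
            _check_flipped(record, order)
        return (sort_key(record, order), record)

    spill_files = []
    for record in records:
        chunk.append(_keyed(record))
        if len(chunk) >= chunk_size:
            chunk.sort(key=lambda kv: kv[0])
            fh = tempfile.TemporaryFile("w+t", dir=tmpdir)
            for _, rec in chunk:
                fh.write(rec.to_line() + "\n")
            fh.seek(0)
            spill_files.append(fh)
            chunk = []
    chunk.sort(key=lambda kv: kv[0])

    if not spill_files:
        for _, rec in chunk:
            yield rec
        return

    def _run_from_file(fh) -> Iterator[tuple[tuple, PairRecord]]:
        for line in fh:
            rec = PairRecord.from_line(line)
            yield (sort_key(rec, order), rec)

    runs = [_run_from_file(fh) for fh in spill_files]
    runs.append(iter(chunk))
    try:
        for _, rec in heapq.merge(*runs, key=lambda kv: kv[0]):
            yield rec
    finally:
        for fh in spill_files:
            fh.close()


def merge_sorted(
    inputs: Sequence[Iterable[str]],
    strict_headers: bool = True,
) -> tuple[PairsHeader, Iterator[PairRecord]]:
    """K-way merge of sorted ``.pairs`` sources into one sorted stream.

    All inputs must be sorted under the same chromosome order; the merged
    header carries the shared chromsizes and the union of provenance entries.
    An unsorted input is detected mid-stream and reported with its index and
    line number.
    """
    headers = []
    record_iters = []
    for stream in inputs:
        header, records = read_pairs(stream)
        headers.append(header)
        record_iters.append(records)
    base = headers[0]
    for i, header in enumerate(headers[1:], start=2):
        if strict_headers and header.chromsizes != base.chromsizes:
            raise ValueError(
                f"input {i} has different chromosomes/order than input 1; "
                "merge requires identical chromsizes"
            )
    merged_header = base.copy()
    seen_prov = set(base.provenance)
    for header in headers[1:]:
        for entry in header.provenance:
            if entry not in seen_prov:
                merged_header.provenance.append(entry)
                seen_prov.add(entry)
    order = ChromOrder.from_chromsizes(base.chromsizes)

    def _checked(records: Iterator[PairRecord], input_idx: int):
        prev_key = None
        for line_no, rec in enumerate(records, start=1):
            key = sort_key(rec, order)
            if prev_key is not None and key < prev_key:
                raise ValueError(
                    f"input {input_idx} is not sorted at record {line_no}"
                )
            prev_key = key
            yield (key, rec)

    streams = [
        _checked(records, i) for i, records in enumerate(record_iters, start=1)
    ]

    def _merged() -> Iterator[PairRecord]:
        for _, rec in heapq.merge(*streams, key=lambda kv: kv[0]):
            yield rec

    return merged_header, _merged()
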