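"""Reading, writing and validating ``.pairs`` contact tables.

A ``.pairs`` file is a tab-separated text table in which each row records a
single observed genomic contact: the read id, the two genomic sides
(chromosome, 1-based position, strand) and a two-character pair-type code,
optionally followed by extra columns. A ``#``-prefixed header carries the
chromosome order and sizes, the column names, the alignment (SAM) header of
the source file, and the complete processing provenance with one entry per
command applied to the file.

Coordinates are 1-based; an unmapped ("null") side is encoded with
chromosome ``!``, position ``0`` and strand ``.``.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator, Sequence

PAIRS_FORMAT_VERSION = "1.0.0"
RESERVED_COLUMNS = (
    "readID",
    "chrom1",
    "pos1",
    "chrom2",
    "pos2",
    "strand1",
    "strand2",
    "pair_type",
)
NULL_CHROM = "!"
VALID_STRANDS = ("+", "-", ".")


class PairsFormatError(ValueError):
    """Malformed ``.pairs`` header or body line."""


class PairsValidationError(ValueError):
    """A record violates the invariants declared by the header."""


@dataclass(slots=True)
class PairRecord:
    """One contact: a read id, two genomic sides and a pair-type code."""

    read_id: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    strand1: str
    strand2: str
    pair_type: str
    extras: list[str] = field(default_factory=list)

    def to_line(self) -> str:
        fields = [
            self.read_id,
            self.chrom1,
            str(self.pos1),
            self.chrom2,
            str(self.pos2),
            self.strand1,
            self.strand2,
            self.pair_type,
        ]
        fields.extend(self.extras)
        return "\t".join(fields)

    @classmethod
    def from_line(cls, line: str) -> "PairRecord":
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 8:
            raise PairsFormatError(
                f"pairs body line has {len(fields)} fields, expected at least 8: {line!r}"
            )
        try:
            pos1 = int(fields[2])
            pos2 = int(fields[4])
        except ValueError as exc:
            raise PairsFormatError(f"non-integer position in line: {line!r}") from exc
        return cls(
            read_id=fields[0],
            chrom1=fields[1],
            pos1=pos1,
            chrom2=fields[3],
            pos2=pos2,
            strand1=fields[5],
            strand2=fields[6],
            pair_type=fields[7],
            extras=fields[8:],
        )

    def copy(self) -> "PairRecord":
        return replace(self, extras=list(self.extras))


@dataclass
class PairsHeader:
    """Metadata of a ``.pairs`` file.

    ``chromsizes`` fixes the canonical chromosome order used for flipping and
    sorting. ``samheader_lines`` preserves the header of the alignment file
    the pairs were extracted from, and ``provenance`` holds one entry per
    command applied to the file, in order of application.
    """

    format_version: str = PAIRS_FORMAT_VERSION
    chromsizes: list[tuple[str, int]] = field(default_factory=list)
    columns: list[str] = field(default_factory=lambda: list(RESERVED_COLUMNS))
    samheader_lines: list[str] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)
    other_lines: list[str] = field(default_factory=list)

    @property
    def chrom_names(self) -> list[str]:
        return [name for name, _ in self.chromsizes]

    def chromsizes_dict(self) -> dict[str, int]:
        return dict(self.chromsizes)

    def copy(self) -> "PairsHeader":
        return PairsHeader(
            format_version=self.format_version,
            chromsizes=list(self.chromsizes),
            columns=list(self.columns),
            samheader_lines=list(self.samheader_lines),
            provenance=list(self.provenance),
            other_lines=list(self.other_lines),
        )

    def to_lines(self) -> list[str]:
        lines = [f"## pairs format v{self.format_version}"]
        for name, size in self.chromsizes:
            lines.append(f"#chromsize: {name} {size}")
        for sam_line in self.samheader_lines:
            lines.append(f"#samheader: {sam_line}")
        for cmd in self.provenance:
            lines.append(f"#command: {cmd}")
        lines.extend(self.other_lines)
        lines.append("#columns: " + " ".join(self.columns))
        return lines

    def validate(self) -> list[str]:
        """Return a list of violated invariants (empty when valid)."""
        violations: list[str] = []
        if not self.columns:
            violations.append("header lacks a #columns line")
        elif tuple(self.columns[:8]) != RESERVED_COLUMNS:
            violations.append(
                "first eight columns must be "
                + " ".join(RESERVED_COLUMNS)
                + ", got "
                + " ".join(self.columns[:8])
            )
        names = self.chrom_names
        if len(set(names)) != len(names):
            violations.append("duplicate chromosome names in #chromsize lines")
        for name, size in self.chromsizes:
            if size <= 0:
                violations.append(f"chromosome {name} has non-positive length {size}")
        return violations


def _validate_record(record: PairRecord, header: PairsHeader, line_no: int) -> None:
    n_expected = len(header.columns)
    if 8 + len(record.extras) != n_expected:
        raise PairsValidationError(
            f"line {line_no}: record has {8 + len(record.extras)} columns, "
            f"header declares {n_expected}"
        )
    sizes = header.chromsizes_dict()
    for chrom, pos, strand, side in (
        (record.chrom1, record.pos1, record.strand1, 1),
        (record.chrom2, record.pos2, record.strand2, 2),
    ):
        if strand not in VALID_STRANDS:
            raise PairsValidationError(f"line {line_no}: invalid strand {strand!r}")
        if chrom == NULL_CHROM:
            if pos != 0 or strand != ".":
                raise PairsValidationError(
                    f"line {line_no}: null side {side} must have pos 0 and strand '.'"
                )
            continue
        if sizes and chrom not in sizes:
            raise PairsValidationError(
                f"line {line_no}: chromosome {chrom!r} not declared in header"
            )
        if pos < 1:
            raise PairsValidationError(
                f"line {line_no}: mapped side {side} has position {pos} < 1"
            )
        if sizes and pos > sizes[chrom]:
            raise PairsValidationError(
                f"line {line_no}: position {pos} exceeds length of {chrom}"
            )


def parse_header_lines(lines: Sequence[str]) -> PairsHeader:
    header = PairsHeader(columns=[])
    for raw in lines:
        line = raw.rstrip("\n")
        if line.startswith("## pairs format"):
            header.format_version = line.rsplit("v", 1)[-1].strip()
        elif line.startswith("#chromsize:"):
            parts = line[len("#chromsize:"):].split()
            if len(parts) != 2:
                raise PairsFormatError(f"malformed #chromsize line: {line!r}")
            try:
                size = int(parts[1])
            except ValueError as exc:
                raise PairsFormatError(f"malformed #chromsize line: {line!r}") from exc
            header.chromsizes.append((parts[0], size))
        elif line.startswith("#samheader:"):
            header.samheader_lines.append(line[len("#samheader:"):].strip())
        elif line.startswith("#command:"):
            header.provenance.append(line[len("#command:"):].strip())
        elif line.startswith("#columns:"):
            header.columns = line[len("#columns:"):].split()
        elif line.startswith("#"):
            header.other_lines.append(line)
        else:
            raise PairsFormatError(f"not a header line: {line!r}")
    return header


def read_pairs(
    stream: Iterable[str], strict: bool = False
) -> tuple[PairsHeader, Iterator[PairRecord]]:
    """Parse a ``.pairs`` text stream into a header and a lazy record iterator.

    The header is fully parsed before the first record is yielded. In strict
    mode every record is checked against the header invariants (column count,
    declared chromosomes, coordinate bounds) and violations raise
    :class:`PairsValidationError` naming the offending line number.
    """
    it = iter(stream)
    header_lines: list[str] = []
    first_body: str | None = None
    n_header = 0
    for raw in it:
        if raw.startswith("#"):
            header_lines.append(raw)
            n_header += 1
        else:
            if raw.strip():
                first_body = raw
            break
    header = parse_header_lines(header_lines)

    def _records() -> Iterator[PairRecord]:
        line_no = n_header
        if first_body is not None:
            line_no += 1
            record = PairRecord.from_line(first_body)
            if strict:
                _validate_record(record, header, line_no)
            yield record
        for raw in it:
            line_no += 1
            if not raw.strip():
                continue
            record = PairRecord.from_line(raw)
            if strict:
                _validate_record(record, header, line_no)
            yield record

    return header, _records()


def write_pairs(
    header: PairsHeader,
    records: Iterable[PairRecord],
    stream: IO[str],
    command: str | None = None,
) -> int:
    """Serialize a header and records as ``.pairs`` text; returns record count.

    When ``command`` is given it is appended to the provenance trail of the
    emitted header (the in-memory header object is left untouched). A record
    whose width disagrees with the header raises before any partial line is
    written for it.
    """
    out_header = header.copy()
    if command is not None:
        out_header.provenance.append(command)
    for line in out_header.to_lines():
        stream.write(line + "\n")
    n_expected = len(out_header.columns)
    n = 0
    for record in records:
        if 8 + len(record.extras) != n_expected:
            raise PairsValidationError(
                f"record {record.read_id!r} has {8 + len(record.extras)} columns, "
                f"header declares {n_expected}"
            )
        stream.write(record.to_line() + "\n")
        n += 1
    return n


def open_pairs_path(path: str, mode: str = "rt") -> IO[str]:
    """Open a ``.pairs`` path, transparently gzip-compressed when it ends ``.gz``."""
    if path == "-":
        import sys

        return sys.stdin if "r" in mode else sys.stdout
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_chromsizes(path: str) -> list[tuple[str, int]]:
    """Read a two-column (name, length) chromsizes TSV."""
    chromsizes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            name, size = line.split()[:2]
            chromsizes.append((name, int(size)))
    return chromsizes


def header_update(
    action: str,
    header: PairsHeader | None = None,
    donor: PairsHeader | None = None,
    columns: Sequence[str] | None = None,
    chromsizes: Sequence[tuple[str, int]] | None = None,
    body_width: int | None = None,
):
    """Generate, validate, transfer or rename the columns of a header.

    ``generate`` builds a minimal valid header from ``chromsizes`` and
    ``columns``; ``validate`` returns the list of violations of ``header``
    (never raises); ``transfer`` attaches ``donor`` to a body of
    ``body_width`` columns; ``set_columns`` replaces the column names of
    ``header`` preserving the count.
    """
    if action == "generate":
        if chromsizes is None:
            raise ValueError("generate requires chromsizes")
        return PairsHeader(
            chromsizes=list(chromsizes),
            columns=list(columns) if columns else list(RESERVED_COLUMNS),
        )
    if action == "validate":
        if header is None:
            raise ValueError("validate requires a header")
        return header.validate()
    if action == "transfer":
        if donor is None:
            raise ValueError("transfer requires a donor header")
        if body_width is not None and body_width != len(donor.columns):
            raise PairsValidationError(
                f"body has {body_width} columns but donor header declares "
                f"{len(donor.columns)}"
            )
        return donor.copy()
    if action == "set_columns":
        if header is None or columns is None:
            raise ValueError("set_columns requires header and columns")
        if len(columns) != len(header.columns):
            raise PairsValidationError(
                f"set_columns must preserve the column count "
                f"({len(header.columns)}), got {len(columns)}"
            )
        new = header.copy()
        new.columns = list(columns)
        return new
    raise ValueError(f"unknown header action {action!r}")


def pairs_to_string(header: PairsHeader, records: Iterable[PairRecord]) -> str:
    buf = io.StringIO()
    write_pairs(header, records, buf)
    return buf.getvalue()
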