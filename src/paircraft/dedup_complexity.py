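"""PCR/optical duplicate detection and library-complexity estimation.

Duplicates of one DNA molecule land at identical — or, for protocols that
amplify before sonication, nearly identical — genomic coordinates. Two pairs
are considered neighbours when they share chromosomes, strands and any
requested extra columns, and both positions differ by at most
``max_mismatch`` bp; duplicate clusters are the connected components of the
neighbour graph, found with a KD-tree fixed-radius search (Chebyshev
metric). The first record of each cluster in sort order is kept.

Library complexity — the number C of distinct molecules in the
pre-amplification pool — is estimated from the totals (T reads observed, U
unique) under the model that every read is drawn with replacement from a
finite pool: U = C (1 - exp(-T / C)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .pairs_format import PairRecord, PairsHeader
from .sort_merge import ChromOrder, sort_key

#: pair types eligible for duplicate detection
DEDUP_CANDIDATE_TYPES = frozenset({"UU", "UR", "RU"})


@dataclass(slots=True)
class DedupConfig:
    max_mismatch: int = 3
    method: str = "radius"
    match_extras: list[str] = field(default_factory=list)
    chunk_size: int = 100_000

    def __post_init__(self) -> None:
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        if self.method not in ("exact", "radius"):
            raise ValueError("method must be 'exact' or 'radius'")
        if self.method == "exact":
            self.max_mismatch = 0


@dataclass(slots=True)
class ComplexityEstimate:
    """T reads observed, U distinct molecules, and the inferred pool size C."""

    n_total: int
    n_unique: int
    estimate: float | None

    @property
    def defined(self) -> bool:
        return self.estimate is not None


@dataclass(slots=True)
class DedupStats:
    total: int = 0
    candidates: int = 0
    unique: int = 0
    duplicates: int = 0
    passed_through: int = 0

    def complexity(self) -> ComplexityEstimate:
        return estimate_complexity(self.candidates, self.unique)


def _match_group_key(
    record: PairRecord, extra_idx: Sequence[int]
) -> tuple:
    return (
        record.chrom1,
        record.chrom2,
        record.strand1,
        record.strand2,
        tuple(record.extras[i] for i in extra_idx),
    )


def find_duplicate_clusters(
    block: Sequence[PairRecord],
    config: DedupConfig,
    columns: Sequence[str] | None = None,
) -> list[int]:
    """Label each record of a block with its duplicate-cluster id.

    Neighbours share (chrom1, chrom2, strand1, strand2) and the configured
    match columns, with |dpos1| <= max_mismatch and |dpos2| <= max_mismatch;
    clusters are connected components (transitive closure) of the neighbour
    graph. The label of a cluster is the block index of its first member, so
    labels are deterministic given the input order.
    """
    extra_idx: list[int] = []
    if config.match_extras:
        if columns is None:
            raise ValueError("match_extras requires the column names")
        extras_names = list(columns[8:])
        for name in config.match_extras:
            if name not in extras_names:
                raise ValueError(f"match column {name!r} not in header columns")
            extra_idx.append(extras_names.index(name))

    n = len(block)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            if ri < rj:
                parent[rj] = ri
            else:
                parent[ri] = rj

    groups: dict[tuple, list[int]] = {}
    for i, record in enumerate(block):
        groups.setdefault(_match_group_key(record, extra_idx), []).append(i)

    r = config.max_mismatch
    for indices in groups.values():
        if len(indices) < 2:
            continue
        coords = np.array(
            [(block[i].pos1, block[i].pos2) for i in indices], dtype=float
        )
        if r == 0:
            exact: dict[tuple, int] = {}
            for i in indices:
                key = (block[i].pos1, block[i].pos2)
                if key in exact:
                    union(exact[key], i)
                else:
                    exact[key] = i
            continue
        tree = cKDTree(coords)
        for a, b in tree.query_pairs(r, p=np.inf):
            union(indices[a], indices[b])

    return [find(i) for i in range(n)]


def dedup_stream(
    records: Iterable[PairRecord],
    config: DedupConfig | None = None,
    order: ChromOrder | None = None,
    columns: Sequence[str] | None = None,
) -> tuple[list[PairRecord], list[PairRecord], list[PairRecord], DedupStats]:
    """Split a sorted pair stream into unique, duplicate and passed-through.

    Only mapped unique-class records (UU/UR/RU) are duplicate candidates;
    other classes pass through untouched. Duplicates have their pair type
    rewritten to "DD". Processing is chunked with carry-over of all trailing
    records within ``max_mismatch`` of the chunk boundary, which guarantees
    output identical to whole-input processing for any chunk size.
    """
    if config is None:
        config = DedupConfig()
    stats = DedupStats()
    unique_out: list[PairRecord] = []
    dup_out: list[PairRecord] = []
    passed_out: list[PairRecord] = []

    # per buffered candidate: [record, status(None|"unique"|"dup"), rep_emitted]
    # rep_emitted marks a duplicate whose cluster representative has already
    # been emitted and is no longer in the buffer: any record joining such a
    # cluster later (via the carry-over window) must also become a duplicate.
    buf: list[list] = []
    prev_key = None

    def _emit(entry: list) -> None:
        record, status = entry[0], entry[1]
        if status == "dup":
            record = record.copy()
            record.pair_type = "DD"
            stats.duplicates += 1
            dup_out.append(record)
        else:
            stats.unique += 1
            unique_out.append(record)

    def _flush(final: bool) -> None:
        if not buf:
            return
        labels = find_duplicate_clusters([e[0] for e in buf], config, columns)
        clusters: dict[int, list[int]] = {}
        for i, lab in enumerate(labels):
            clusters.setdefault(lab, []).append(i)
        for members in clusters.values():
            # buffer order is sort order, so members[0] is the earliest; an
            # even earlier, already-emitted representative is signalled by a
            # rep_emitted flag on any member
            if any(buf[i][2] for i in members):
                for i in members:
                    buf[i][1] = "dup"
            else:
                buf[members[0]][1] = "unique"
                for i in members[1:]:
                    buf[i][1] = "dup"
        if final:
            for entry in buf:
                _emit(entry)
            buf.clear()
            return
        last = buf[-1][0]
        r = config.max_mismatch
        cut = len(buf)
        for i in range(len(buf) - 1, -1, -1):
            rec = buf[i][0]
            if (
                rec.chrom1 == last.chrom1
                and rec.chrom2 == last.chrom2
                and last.pos1 - rec.pos1 <= r
            ):
                cut = i
            else:
                break
        for entry in buf[:cut]:
            _emit(entry)
        for members in clusters.values():
            has_prior = any(buf[i][2] for i in members)
            rep_stays = not has_prior and members[0] >= cut
            for i in members:
                if i >= cut and buf[i][1] == "dup" and not rep_stays:
                    buf[i][2] = True
        buf[:] = buf[cut:]

    for record in records:
        stats.total += 1
        if record.pair_type in DEDUP_CANDIDATE_TYPES:
            stats.candidates += 1
            if order is not None:
                key = sort_key(record, order)
                if prev_key is not None and key < prev_key:
                    raise ValueError("dedup requires sorted input")
                prev_key = key
            buf.append([record, None, False])
            if len(buf) >= config.chunk_size:
                _flush(final=False)
        else:
            stats.passed_through += 1
            passed_out.append(record)
    _flush(final=True)
    return unique_out, dup_out, passed_out, stats


def estimate_complexity(n_total: int, n_unique: int) -> ComplexityEstimate:
    """Estimate pool size C from U = C (1 - exp(-T/C)).

    Returns an undefined estimate when U = T (no duplicate observed, C is
    unbounded) and errors when U > T. The equation is solved by bracketed
    root finding to relative tolerance 1e-6.
    """
    if n_unique > n_total:
        raise ValueError("n_unique cannot exceed n_total")
    if n_total == 0 or n_unique == 0:
        return ComplexityEstimate(n_total, n_unique, None)
    if n_unique == n_total:
        return ComplexityEstimate(n_total, n_unique, None)

    def f(c: float) -> float:
        return c * (1.0 - math.exp(-n_total / c)) - n_unique

    lo = float(n_unique)
    if f(lo) >= 0:  # saturation: nearly every read is a duplicate, C -> U
        return ComplexityEstimate(n_total, n_unique, lo)
    hi = lo * 2
    while f(hi) < 0:
        hi *= 2
        if hi > 1e18:  # pragma: no cover - U ~ T handled above
            return ComplexityEstimate(n_total, n_unique, None)
    c = brentq(f, lo, hi, rtol=1e-6)
    return ComplexityEstimate(n_total, n_unique, float(c))
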