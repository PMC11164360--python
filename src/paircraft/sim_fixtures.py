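"""Synthetic 3C+ libraries with full ground truth, emitted as aligner-style SAM.

The simulator plants chimeric ligation molecules on a random (optionally
diploid) genome and writes the SAM records a perfect local aligner would
report for exact-substring reads: chimeric pieces as supplementary records
with correct CIGAR soft-clips, readthrough duplication whenever the
molecule is shorter than the combined read span, each mate aligned
independently. Molecule classes cover simple contacts, multi-junction
walks, restriction by-products (dangling ends, self-circles, mirrors),
unmapped and multi-mapped reads, and PCR duplicates with +/-1 bp coordinate
jitter. Every read carries a :class:`TruthRecord` with its intended contact
pair, duplicate group and haplotype labels, so the whole toolchain is
testable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np

from .pairs_format import PairRecord
from .protocol_tools import digest_genome
from .sort_merge import ChromOrder

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class SimConfig:
    """Study conditions of a simulated 3C+ library.

    Fractions are molecule-class probabilities; ``scaling_exponent`` is the
    power-law slope of the cis separation density (P(s) ~ s^-exponent);
    ``duplication_rate`` is the expected number of PCR copies per molecule
    (Poisson); ``byproduct_rates`` are the (dangling end, self-circle,
    mirror) fractions. With ``snv_rate`` > 0 the genome is diploid: two
    suffixed copies per chromosome differing at Bernoulli(snv_rate)
    positions.
    """

    seed: int = 0
    chromosomes: list[tuple[str, int]] = field(
        default_factory=lambda: [("chr1", 1_500_000), ("chr2", 1_000_000)]
    )
    n_molecules: int = 1000
    cis_fraction: float = 0.7
    scaling_exponent: float = 1.0
    read_length: int = 75
    fragment_length_distribution: tuple[float, float] = (150.0, 40.0)
    duplication_rate: float = 0.0
    walk_fraction: float = 0.0
    byproduct_rates: tuple[float, float, float] = (0.0, 0.0, 0.0)
    snv_rate: float = 0.0
    restriction_site: str | None = None
    unmapped_rate: float = 0.0
    multi_rate: float = 0.0
    min_cis_separation: int = 1_000
    min_fragment_length: int = 60
    max_fragment_length: int = 400
    min_segment_length: int = 20
    jitter: int = 1
    jitter_prob: float = 0.5
    haplotype_separator: str = "#"

    def __post_init__(self) -> None:
        for frac in (
            self.cis_fraction,
            self.walk_fraction,
            self.unmapped_rate,
            self.multi_rate,
            *self.byproduct_rates,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")

    @property
    def diploid(self) -> bool:
        return self.snv_rate > 0


@dataclass
class SimGenome:
    """Simulated reference: sequences, chromsizes, planted variants."""

    sequences: dict[str, str]
    chromsizes: list[tuple[str, int]]
    variants: dict[str, np.ndarray] = field(default_factory=dict)  # 0-based, per base chrom

    def write_fasta(self, stream: IO[str], width: int = 80) -> None:
        for name, seq in self.sequences.items():
            stream.write(f">{name}\n")
            for i in range(0, len(seq), width):
                stream.write(seq[i : i + width] + "\n")

    def write_chromsizes(self, stream: IO[str]) -> None:
        for name, size in self.chromsizes:
            stream.write(f"{name}\t{size}\n")


@dataclass
class TruthRecord:
    """Ground truth for one sequenced read (PCR clones share a dup group)."""

    molecule_id: int
    read_id: str
    kind: str  # contact | walk | dangling_end | self_circle | mirror | unmapped | multi
    dup_group: int
    pair: tuple[str, int, str, str, int, str] | None  # flipped (c1,p1,s1,c2,p2,s2)
    is_duplicate: bool = False
    haplotypes: tuple[int, int] | None = None
    n_junctions: int = 1


def simulate_genome(config: SimConfig) -> SimGenome:
    """Uniform-random genome, deterministic per seed; diploid when snv_rate > 0.

    In diploid mode each chromosome is emitted twice with haplotype
    suffixes (e.g. ``chr1#0`` / ``chr1#1``); the second copy carries a
    substituted base at every planted variant position.
    """
    rng = np.random.default_rng(config.seed)
    sequences: dict[str, str] = {}
    chromsizes: list[tuple[str, int]] = []
    variants: dict[str, np.ndarray] = {}
    sep = config.haplotype_separator
    for name, length in config.chromosomes:
        arr = rng.integers(0, 4, size=length, dtype=np.uint8)
        seq = _BASES[arr].tobytes().decode("ascii")
        if not config.diploid:
            sequences[name] = seq
            chromsizes.append((name, length))
            continue
        mask = rng.random(length) < config.snv_rate
        positions = np.flatnonzero(mask)
        shifted = arr.copy()
        shifted[positions] = (
            shifted[positions] + rng.integers(1, 4, size=len(positions))
        ) % 4
        alt_seq = _BASES[shifted].tobytes().decode("ascii")
        sequences[f"{name}{sep}0"] = seq
        sequences[f"{name}{sep}1"] = alt_seq
        chromsizes.append((f"{name}{sep}0", length))
        chromsizes.append((f"{name}{sep}1", length))
        variants[name] = positions
    return SimGenome(sequences=sequences, chromsizes=chromsizes, variants=variants)


# ---------------------------------------------------------------------------
# molecule construction


@dataclass(slots=True)
class _Fragment:
    chrom: str  # reference name as aligned (haplotype-suffixed in diploid mode)
    lo: int  # 1-based inclusive
    hi: int  # 1-based inclusive
    mstrand: str  # orientation of the fragment within the molecule

    @property
    def length(self) -> int:
        return self.hi - self.lo + 1


@dataclass(slots=True)
class _Piece:
    """One aligned piece of a read (one SAM record)."""

    chrom: str
    ref_lo: int
    ref_hi: int
    strand: str
    read_start: int  # 0-based half-open, read orientation
    read_end: int
    read_len: int
    side: int
    mapq: int = 60


class _LibrarySimulator:
    def __init__(self, config: SimConfig, genome: SimGenome):
        self.config = config
        self.genome = genome
        self.rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
        self.order = ChromOrder.from_chromsizes(genome.chromsizes)
        names = [name for name, _ in genome.chromsizes]
        sizes = np.array([size for _, size in genome.chromsizes], dtype=float)
        self.chrom_names = names
        self.chrom_weights = sizes / sizes.sum()
        self.frag_map = (
            digest_genome(genome.sequences, config.restriction_site)
            if config.restriction_site
            else None
        )

    # -- helpers ---------------------------------------------------------

    def _chrom(self) -> str:
        i = self.rng.choice(len(self.chrom_names), p=self.chrom_weights)
        return self.chrom_names[i]

    def _chrom_len(self, chrom: str) -> int:
        return len(self.genome.sequences[chrom])

    def _frag_length(self) -> int:
        mean, sd = self.config.fragment_length_distribution
        l = int(round(self.rng.normal(mean, sd)))
        return int(
            np.clip(l, self.config.min_fragment_length, self.config.max_fragment_length)
        )

    def _strand(self) -> str:
        return "+" if self.rng.random() < 0.5 else "-"

    def _cis_separation(self, s_max: int) -> int:
        a = self.config.scaling_exponent
        s_min = self.config.min_cis_separation
        u = self.rng.random()
        if abs(a - 1.0) < 1e-9:
            s = s_min * (s_max / s_min) ** u
        else:
            p = 1.0 - a
            s = (s_min**p + u * (s_max**p - s_min**p)) ** (1.0 / p)
        return int(s)

    def _snap_to_site(self, chrom: str, pos: int) -> int:
        starts = self.frag_map.starts[chrom]
        i = int(np.searchsorted(starts, pos))
        candidates = [j for j in (i - 1, i) if 0 < j < len(starts)]
        if not candidates:
            return pos
        best = min(candidates, key=lambda j: abs(int(starts[j]) - pos))
        return int(starts[best])

    def _end_fragment(self, chrom: str, pos5: int, strand: str, length: int, terminal: str) -> _Fragment:
        """Fragment whose reported 5' position (per its read) is ``pos5``.

        ``terminal`` says which molecule end the fragment sits at: the read-1
        end ("left": read strand equals the molecule strand) or the read-2
        end ("right": read strand is opposite).
        """
        L = self._chrom_len(chrom)
        if terminal == "left":
            mstrand = strand
            if strand == "+":
                lo, hi = pos5, pos5 + length - 1
            else:
                lo, hi = pos5 - length + 1, pos5
        else:
            mstrand = "-" if strand == "+" else "+"
            if strand == "-":  # read2 reports hi as its 5' position
                lo, hi = pos5 - length + 1, pos5
            else:
                lo, hi = pos5, pos5 + length - 1
        lo = max(1, lo)
        hi = min(L, hi)
        return _Fragment(chrom=chrom, lo=lo, hi=hi, mstrand=mstrand)

    def _truth_sides(self, fragments: Sequence[_Fragment]) -> tuple[tuple[str, int, str], tuple[str, int, str]]:
        first, last = fragments[0], fragments[-1]
        if first.mstrand == "+":
            side1 = (first.chrom, first.lo, "+")
        else:
            side1 = (first.chrom, first.hi, "-")
        # read 2 sees the last fragment reversed
        if last.mstrand == "+":
            side2 = (last.chrom, last.hi, "-")
        else:
            side2 = (last.chrom, last.lo, "+")
        return side1, side2

    def _flip(
        self, side1: tuple[str, int, str], side2: tuple[str, int, str]
    ) -> tuple[str, int, str, str, int, str]:
        c1, p1, s1 = side1
        c2, p2, s2 = side2
        if (self.order.rank(c1), p1) > (self.order.rank(c2), p2):
            c1, p1, s1, c2, p2, s2 = c2, p2, s2, c1, p1, s1
        return (c1, p1, s1, c2, p2, s2)

    # -- molecule classes ------------------------------------------------

    def _contact_fragments(self, n_extra: int = 0) -> list[_Fragment]:
        """A 2-fragment contact, optionally with extra middle fragments (walk)."""
        cfg = self.config
        chrom1 = self._chrom()
        L1 = self._chrom_len(chrom1)
        l1, l2 = self._frag_length(), self._frag_length()
        for _ in range(200):
            if self.rng.random() < cfg.cis_fraction:
                chrom2 = chrom1
                s_max = max(cfg.min_cis_separation * 2, L1 // 2)
                s = self._cis_separation(s_max)
                p1 = int(self.rng.integers(l1 + 1, max(l1 + 2, L1 - s - l2 - 1)))
                p2 = p1 + s
            else:
                chrom2 = self._chrom()
                if chrom2 == chrom1 and len(self.chrom_names) > 1:
                    continue
                L2 = self._chrom_len(chrom2)
                p1 = int(self.rng.integers(l1 + 1, L1 - l1 - 1))
                p2 = int(self.rng.integers(l2 + 1, L2 - l2 - 1))
            if self.frag_map is not None:
                r1 = self.frag_map.locate(chrom1, min(p1, self._chrom_len(chrom1)))[0]
                r2 = self.frag_map.locate(chrom2, min(p2, self._chrom_len(chrom2)))[0]
                if chrom1 == chrom2 and r1 == r2:
                    continue
            strand1, strand2 = self._strand(), self._strand()
            first = self._end_fragment(chrom1, p1, strand1, l1, "left")
            last = self._end_fragment(chrom2, p2, strand2, l2, "right")
            middles = []
            for _ in range(n_extra):
                mc = self._chrom()
                ml = self._frag_length()
                mlo = int(self.rng.integers(1, self._chrom_len(mc) - ml))
                middles.append(
                    _Fragment(chrom=mc, lo=mlo, hi=mlo + ml - 1, mstrand=self._strand())
                )
            return [first, *middles, last]
        raise RuntimeError("could not place contact fragments; genome too small")

    def _byproduct_interval(self) -> tuple[str, int, int]:
        """A single fragment long enough that the two reads do not overlap."""
        cfg = self.config
        need = 2 * cfg.read_length + 10
        for _ in range(500):
            chrom = self._chrom()
            if self.frag_map is not None:
                starts = self.frag_map.starts[chrom]
                L = self._chrom_len(chrom)
                bounds = np.append(starts, L + 1)
                i = int(self.rng.integers(0, len(starts)))
                lo, hi = int(bounds[i]), int(bounds[i + 1]) - 1
                if hi - lo + 1 >= need:
                    return chrom, lo, hi
            else:
                length = int(self.rng.integers(need, need + 250))
                L = self._chrom_len(chrom)
                lo = int(self.rng.integers(1, L - length))
                return chrom, lo, lo + length - 1
        raise RuntimeError("no restriction fragment long enough for a by-product")

    # -- read decomposition ----------------------------------------------

    def _molecule_pieces(
        self, fragments: Sequence[_Fragment]
    ) -> tuple[list[_Piece], list[_Piece], str]:
        """Decompose both reads of a linear molecule into aligned pieces."""
        cfg = self.config
        spans = []
        offset = 0
        for frag in fragments:
            spans.append((offset, offset + frag.length))
            offset += frag.length
        mol_len = offset
        w1 = min(cfg.read_length, mol_len)
        w2 = min(cfg.read_length, mol_len)

        def pieces_for_window(win_lo: int, win_hi: int, side: int) -> list[_Piece]:
            out = []
            for frag, (mstart, mend) in zip(fragments, spans):
                ps, pe = max(win_lo, mstart), min(win_hi, mend)
                if pe - ps < cfg.min_segment_length:
                    continue
                if frag.mstrand == "+":
                    ref_lo = frag.lo + (ps - mstart)
                    ref_hi = frag.lo + (pe - mstart) - 1
                else:
                    ref_hi = frag.hi - (ps - mstart)
                    ref_lo = frag.hi - (pe - mstart) + 1
                if side == 1:
                    strand = frag.mstrand
                    read_start, read_end = ps - win_lo, pe - win_lo
                    read_len = win_hi - win_lo
                else:
                    strand = "-" if frag.mstrand == "+" else "+"
                    read_len = win_hi - win_lo
                    read_start, read_end = win_hi - pe, win_hi - ps
                out.append(
                    _Piece(
                        chrom=frag.chrom,
                        ref_lo=ref_lo,
                        ref_hi=ref_hi,
                        strand=strand,
                        read_start=read_start,
                        read_end=read_end,
                        read_len=read_len,
                        side=side,
                    )
                )
            if side == 2:
                out.sort(key=lambda p: p.read_start)
            return out

        pieces1 = pieces_for_window(0, w1, 1)
        pieces2 = pieces_for_window(mol_len - w2, mol_len, 2)
        mol_seq = "".join(
            self.genome.sequences[f.chrom][f.lo - 1 : f.hi]
            if f.mstrand == "+"
            else _revcomp(self.genome.sequences[f.chrom][f.lo - 1 : f.hi])
            for f in fragments
        )
        read1 = mol_seq[:w1]
        read2 = _revcomp(mol_seq[mol_len - w2 :])
        return pieces1, pieces2, read1 + "\x00" + read2

    # -- SAM emission ----------------------------------------------------

    def _sam_lines(
        self,
        read_id: str,
        pieces1: Sequence[_Piece],
        pieces2: Sequence[_Piece],
        reads: str,
        jitter: tuple[int, int] = (0, 0),
        tags_fn=None,
    ) -> list[str]:
        read1, read2 = reads.split("\x00")
        lines: list[str] = []
        for side, pieces, read_seq in ((1, pieces1, read1), (2, pieces2, read2)):
            shift = jitter[side - 1]
            if not pieces:
                flag = 0x1 | 0x4 | (0x40 if side == 1 else 0x80)
                lines.append(
                    f"{read_id}\t{flag}\t*\t0\t0\t*\t*\t0\t0\t{read_seq or '*'}\t*"
                )
                continue
            primary = max(range(len(pieces)), key=lambda i: pieces[i].read_end - pieces[i].read_start)
            for i, piece in enumerate(pieces):
                ref_lo = piece.ref_lo + shift
                ref_hi = piece.ref_hi + shift
                L = self._chrom_len(piece.chrom)
                if ref_lo < 1 or ref_hi > L:
                    ref_lo, ref_hi = piece.ref_lo, piece.ref_hi
                flag = 0x1 | (0x40 if side == 1 else 0x80)
                if piece.strand == "-":
                    flag |= 0x10
                if i != primary:
                    flag |= 0x800
                lclip = piece.read_start
                rclip = piece.read_len - piece.read_end
                if piece.strand == "-":
                    lclip, rclip = rclip, lclip
                cigar = ""
                if lclip:
                    cigar += f"{lclip}S"
                cigar += f"{piece.read_end - piece.read_start}M"
                if rclip:
                    cigar += f"{rclip}S"
                seq = read_seq if piece.strand == "+" else _revcomp(read_seq)
                score = piece.read_end - piece.read_start
                tags = [f"AS:i:{score}"]
                if tags_fn is not None:
                    tags.extend(tags_fn(piece, score))
                lines.append(
                    f"{read_id}\t{flag}\t{piece.chrom}\t{ref_lo}\t{piece.mapq}\t"
                    f"{cigar}\t*\t0\t0\t{seq}\t*\t" + "\t".join(tags)
                )
        return lines

    def _phase_tags(self, piece: _Piece, score: int) -> list[str]:
        if not self.config.diploid:
            return []
        sep = self.config.haplotype_separator
        base, _, suffix = piece.chrom.rpartition(sep)
        variants = self.genome.variants.get(base)
        if variants is None:
            return []
        k = int(
            np.searchsorted(variants, piece.ref_hi)
            - np.searchsorted(variants, piece.ref_lo - 1)
        )
        other = f"{base}{sep}{1 - int(suffix)}"
        xs = score - 2 * k if k else score
        mlen = piece.read_end - piece.read_start
        return [
            f"XS:i:{xs}",
            f"XA:Z:{other},{piece.strand}{piece.ref_lo},{mlen}M,{k};",
        ]

    # -- main loop -------------------------------------------------------

    def run(self) -> tuple[list[TruthRecord], list[str]]:
        cfg = self.config
        truths: list[TruthRecord] = []
        sam: list[str] = []
        for name, size in self.genome.chromsizes:
            sam.append(f"@SQ\tSN:{name}\tLN:{size}")
        sam.append("@PG\tID:paircraft-sim\tPN:paircraft-sim")

        de, sc, mi = cfg.byproduct_rates
        thresholds = np.cumsum(
            [de, sc, mi, cfg.walk_fraction, cfg.unmapped_rate, cfg.multi_rate]
        )
        kinds = ["dangling_end", "self_circle", "mirror", "walk", "unmapped", "multi"]
        rl = cfg.read_length

        for mol_id in range(cfg.n_molecules):
            r = self.rng.random()
            kind = "contact"
            for t, k in zip(thresholds, kinds):
                if r < t:
                    kind = k
                    break

            n_junctions = 1
            pieces1: list[_Piece]
            pieces2: list[_Piece]
            side1 = side2 = None  # unflipped truth sides (chrom, pos, strand)
            if kind == "contact" or kind == "multi" or kind == "unmapped":
                fragments = self._contact_fragments()
                pieces1, pieces2, reads = self._molecule_pieces(fragments)
                side1, side2 = self._truth_sides(fragments)
                if kind == "multi" and pieces1:
                    pieces1[0].mapq = 0
                    side1 = side2 = None
                if kind == "unmapped":
                    pieces1 = []
                    side1 = side2 = None
            elif kind == "walk":
                n_extra = int(self.rng.integers(1, 3))  # 2-3 junctions
                fragments = self._contact_fragments(n_extra=n_extra)
                n_junctions = n_extra + 1
                pieces1, pieces2, reads = self._molecule_pieces(fragments)
                side1, side2 = self._truth_sides(fragments)
            elif kind == "dangling_end":
                chrom, lo, hi = self._byproduct_interval()
                fragments = [_Fragment(chrom=chrom, lo=lo, hi=hi, mstrand="+")]
                pieces1, pieces2, reads = self._molecule_pieces(fragments)
                side1, side2 = (chrom, lo, "+"), (chrom, hi, "-")
            elif kind == "self_circle":
                chrom, lo, hi = self._byproduct_interval()
                p1 = _Piece(chrom, lo, lo + rl - 1, "-", 0, rl, rl, 1)
                p2 = _Piece(chrom, hi - rl + 1, hi, "+", 0, rl, rl, 2)
                pieces1, pieces2 = [p1], [p2]
                seq1 = _revcomp(self.genome.sequences[chrom][lo - 1 : lo + rl - 1])
                seq2 = self.genome.sequences[chrom][hi - rl : hi]
                reads = seq1 + "\x00" + seq2
                side1, side2 = (chrom, lo + rl - 1, "-"), (chrom, hi - rl + 1, "+")
            else:  # mirror
                chrom, lo, hi = self._byproduct_interval()
                delta = int(self.rng.integers(5, 30))
                p1 = _Piece(chrom, lo, lo + rl - 1, "+", 0, rl, rl, 1)
                p2 = _Piece(chrom, lo + delta, lo + delta + rl - 1, "+", 0, rl, rl, 2)
                pieces1, pieces2 = [p1], [p2]
                seq1 = self.genome.sequences[chrom][lo - 1 : lo + rl - 1]
                seq2 = self.genome.sequences[chrom][lo + delta - 1 : lo + delta + rl - 1]
                reads = seq1 + "\x00" + seq2
                side1, side2 = (chrom, lo, "+"), (chrom, lo + delta, "+")

            haplotypes = None
            if cfg.diploid:
                sep = cfg.haplotype_separator

                def _hap(pieces):
                    if not pieces:
                        return -1
                    return int(pieces[0].chrom.rpartition(sep)[2])

                haplotypes = (_hap(pieces1), _hap(pieces2))

            n_copies = 1 + int(self.rng.poisson(cfg.duplication_rate))
            for copy in range(n_copies):
                read_id = f"m{mol_id}" if copy == 0 else f"m{mol_id}d{copy}"
                if copy == 0:
                    jit = (0, 0)
                else:
                    jit = tuple(
                        int(self.rng.choice([-cfg.jitter, cfg.jitter]))
                        if self.rng.random() < cfg.jitter_prob
                        else 0
                        for _ in range(2)
                    )
                sam.extend(
                    self._sam_lines(
                        read_id, pieces1, pieces2, reads, jit, self._phase_tags
                    )
                )
                if side1 is None:
                    pair = None
                else:
                    j1 = self._jitter_side(side1, pieces1, jit[0])
                    j2 = self._jitter_side(side2, pieces2, jit[1])
                    pair = self._flip(j1, j2)
                truths.append(
                    TruthRecord(
                        molecule_id=mol_id,
                        read_id=read_id,
                        kind=kind,
                        dup_group=mol_id,
                        pair=pair,
                        is_duplicate=copy > 0,
                        haplotypes=haplotypes,
                        n_junctions=n_junctions,
                    )
                )
        return truths, sam

    def _jitter_side(self, side, side_pieces, shift):
        """Apply clone jitter to one truth side (clamped like SAM emission)."""
        chrom, pos, strand = side
        if shift == 0:
            return side
        # the shift is suppressed piece-wise when it would leave the
        # chromosome; only the piece containing the truth position matters
        for piece in side_pieces:
            if piece.chrom == chrom and piece.ref_lo <= pos <= piece.ref_hi:
                L = self._chrom_len(piece.chrom)
                if piece.ref_lo + shift < 1 or piece.ref_hi + shift > L:
                    return side
                return (chrom, pos + shift, strand)
        return side


def simulate_library(
    config: SimConfig, genome: SimGenome
) -> tuple[list[TruthRecord], list[str]]:
    """Simulate a 3C+ library; returns (truth records, SAM text lines)."""
    return _LibrarySimulator(config, genome).run()


def expected_unique_pairs(truths: Iterable[TruthRecord], order: ChromOrder) -> set:
    """The exact pair set a perfect parse+dedup should output.

    Per duplicate group, the surviving record is the clone whose flipped
    coordinates sort first — deterministic keep-first semantics.
    """
    groups: dict[int, list[TruthRecord]] = {}
    for t in truths:
        if t.pair is not None:
            groups.setdefault(t.dup_group, []).append(t)
    expected = set()
    for members in groups.values():
        best = min(
            members,
            key=lambda t: (
                order.rank(t.pair[0]),
                order.rank(t.pair[3]),
                t.pair[1],
                t.pair[4],
                t.pair[2],
                t.pair[5],
            ),
        )
        expected.add(best.pair)
    return expected


def simulate_oriented_cis_pairs(
    n: int,
    chrom: str = "chr1",
    chrom_length: int = 10_000_000,
    s_star: int = 2_000,
    probs_below: Sequence[float] = (0.1, 0.7, 0.1, 0.1),
    s_min: int = 100,
    s_max: int = 1_000_000,
    seed: int = 0,
) -> list[PairRecord]:
    """Cis pairs with a planted orientation asymmetry below separation s*.

    Separations are log-uniform on [s_min, s_max]. Below ``s_star`` the four
    strand orientations (++, +-, -+, --) follow ``probs_below`` (a
    convergent excess emulates ligation by-products); above it they are
    equiprobable, as expected of genuine contacts.
    """
    rng = np.random.default_rng(seed)
    s = (s_min * (s_max / s_min) ** rng.random(n)).astype(np.int64)
    pos1 = rng.integers(1, chrom_length - s_max - 1, size=n)
    orientations = ("++", "+-", "-+", "--")
    below = s < s_star
    o_idx = np.empty(n, dtype=np.int64)
    o_idx[below] = rng.choice(4, size=int(below.sum()), p=list(probs_below))
    o_idx[~below] = rng.integers(0, 4, size=int((~below).sum()))
    records = []
    for i in range(n):
        o = orientations[o_idx[i]]
        records.append(
            PairRecord(
                read_id=f"p{i}",
                chrom1=chrom,
                pos1=int(pos1[i]),
                chrom2=chrom,
                pos2=int(pos1[i] + s[i]),
                strand1=o[0],
                strand2=o[1],
                pair_type="UU",
            )
        )
    return records
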