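"""QC summaries: pair-type totals, cis/trans tiers, P(s) scalings, convergence.

The decay of contact frequency with genomic separation s — the P(s) curve,
or "scaling" — is computed in geometric (log-spaced) distance bins,
separately for the four strand orientations (++, +-, -+, --). At short range
the orientations differ because of ligation by-products (dangling ends peak
in convergent +-, self-circles in divergent -+, mirror artifacts in equal
orientations); beyond the *orientation convergence distance* all four curves
coincide and pairs can be read as genuine contacts. Summaries serialize to
a nested YAML mapping or a flattened "path<TAB>value" TSV table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
import yaml

from .dedup_complexity import ComplexityEstimate, estimate_complexity
from .pairs_format import NULL_CHROM, PairRecord, PairsHeader

ORIENTATIONS = ("++", "+-", "-+", "--")
DIST_TIERS = (1_000, 2_000, 4_000, 10_000, 20_000, 40_000)
MAPPED_CLASSES = frozenset("UR")


@dataclass
class ScalingCurve:
    """Contact counts in geometric separation bins x four strand orientations."""

    bin_edges: np.ndarray  # (n_bins + 1,)
    counts: np.ndarray  # (n_bins, 4), orientation order as ORIENTATIONS
    n_trans: int = 0
    avg_trans_frequency: float = 0.0

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    @property
    def bin_widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def normalized(self) -> np.ndarray:
        """Counts per bp of bin width."""
        return self.counts / self.bin_widths[:, None]


def geometric_edges(min_dist: int, max_dist: int, bins_per_decade: int) -> np.ndarray:
    """Log-spaced bin edges from min_dist with bins_per_decade edges per decade."""
    if min_dist <= 0:
        raise ValueError("min_dist must be > 0")
    if max_dist <= min_dist:
        raise ValueError("max_dist must exceed min_dist")
    n = math.ceil(bins_per_decade * math.log10(max_dist / min_dist))
    edges = min_dist * 10 ** (np.arange(n + 1) / bins_per_decade)
    return edges


def compute_scaling(
    records: Iterable[PairRecord],
    chromsizes: Sequence[tuple[str, int]] | None = None,
    min_dist: int = 10,
    max_dist: int | None = None,
    bins_per_decade: int = 8,
) -> ScalingCurve:
    """Bin cis pairs by genomic separation and strand orientation.

    Separation is s = pos2 - pos1 of the flipped pair. Trans pairs only
    contribute to the average trans contact frequency, normalized by the
    total number of trans locus pairs, sum over chromosome pairs of
    len_i * len_j.
    """
    if max_dist is None:
        if chromsizes:
            max_dist = max(size for _, size in chromsizes)
        else:
            max_dist = 1_000_000_000
    edges = geometric_edges(min_dist, max_dist, bins_per_decade)
    counts = np.zeros((len(edges) - 1, 4), dtype=np.int64)
    orient_idx = {o: i for i, o in enumerate(ORIENTATIONS)}
    log_min = math.log10(min_dist)
    n_trans = 0
    for rec in records:
        if rec.chrom1 == NULL_CHROM or rec.chrom2 == NULL_CHROM:
            continue
        if rec.chrom1 != rec.chrom2:
            n_trans += 1
            continue
        s = rec.pos2 - rec.pos1
        if s < min_dist or s >= edges[-1]:
            continue
        b = int((math.log10(s) - log_min) * bins_per_decade)
        b = min(b, len(edges) - 2)
        if s < edges[b]:  # guard against float rounding at edges
            b -= 1
        elif s >= edges[b + 1]:
            b += 1
        o = orient_idx.get(rec.strand1 + rec.strand2)
        if o is not None:
            counts[b, o] += 1
    avg_trans = 0.0
    if n_trans and chromsizes:
        sizes = [size for _, size in chromsizes]
        total = sum(sizes)
        loci_pairs = (total * total - sum(s * s for s in sizes)) / 2
        if loci_pairs > 0:
            avg_trans = n_trans / loci_pairs
    return ScalingCurve(
        bin_edges=edges, counts=counts, n_trans=n_trans, avg_trans_frequency=avg_trans
    )


def convergence_distance(
    curve: ScalingCurve,
    rel_tol: float = 0.25,
    min_count: int = 100,
) -> float | None:
    """Rightmost genomic separation below which orientations still differ.

    Scanning bins from the largest separation downward, the first bin whose
    four orientation frequencies are *not* similar — relative spread
    (max - min) / mean above ``rel_tol``, judged only on bins holding at
    least ``min_count`` pairs — marks the convergence distance; its upper
    edge is returned. When every judged bin is similar the first bin edge is
    returned; when every judged bin is dissimilar the orientations never
    converge and None is returned.
    """
    norm = curve.normalized
    totals = curve.counts.sum(axis=1)
    dissimilar: list[int] = []
    judged = 0
    for b in range(curve.n_bins):
        if totals[b] < min_count:
            continue
        judged += 1
        vals = norm[b]
        mean = vals.mean()
        if mean <= 0:
            continue
        if (vals.max() - vals.min()) / mean > rel_tol:
            dissimilar.append(b)
    if not dissimilar:
        return float(curve.bin_edges[0])
    if judged and len(dissimilar) == judged:
        return None
    return float(curve.bin_edges[max(dissimilar) + 1])


@dataclass
class StatsSummary:
    """Single-pass counting summary of a pairs stream."""

    total: int = 0
    total_unmapped: int = 0
    total_single_sided_mapped: int = 0
    total_mapped: int = 0
    total_dups: int = 0
    total_nodups: int = 0
    cis: int = 0
    trans: int = 0
    pair_types: dict[str, int] = field(default_factory=dict)
    cis_at_distance: dict[int, int] = field(default_factory=dict)
    chrom_freq: dict[tuple[str, str], int] = field(default_factory=dict)
    convergence_dist: float | None = None
    complexity: ComplexityEstimate | None = None
    scaling: ScalingCurve | None = None

    def to_dict(self) -> dict:
        d: dict = {
            "total": self.total,
            "total_unmapped": self.total_unmapped,
            "total_single_sided_mapped": self.total_single_sided_mapped,
            "total_mapped": self.total_mapped,
            "total_dups": self.total_dups,
            "total_nodups": self.total_nodups,
            "cis": self.cis,
            "trans": self.trans,
            "pair_types": dict(sorted(self.pair_types.items())),
        }
        for tier in DIST_TIERS:
            d[f"cis_{tier // 1000}kb+"] = self.cis_at_distance.get(tier, 0)
        d["chrom_freq"] = {
            c1: {c2: n for (cc1, c2), n in sorted(self.chrom_freq.items()) if cc1 == c1}
            for c1 in sorted({c1 for c1, _ in self.chrom_freq})
        }
        summary: dict = {
            "dist_freq_convergence": {
                "convergence_dist": (
                    self.convergence_dist if self.convergence_dist is not None else -1
                ),
                "convergence_rel_tol": 0.25,
            }
        }
        if self.complexity is not None:
            summary["complexity"] = {
                "n_total": self.complexity.n_total,
                "n_unique": self.complexity.n_unique,
                "estimate": (
                    round(self.complexity.estimate, 3)
                    if self.complexity.estimate is not None
                    else -1
                ),
            }
        if self.scaling is not None:
            dist_freq: dict[str, dict[str, int]] = {}
            edges = self.scaling.bin_edges
            for b in range(self.scaling.n_bins):
                key = f"{edges[b]:.0f}-{edges[b + 1]:.0f}"
                row = {
                    o: int(self.scaling.counts[b, i])
                    for i, o in enumerate(ORIENTATIONS)
                }
                if any(row.values()):
                    dist_freq[key] = row
            d["dist_freq"] = dist_freq
            summary["avg_trans_frequency"] = float(self.scaling.avg_trans_frequency)
        d["summary"] = summary
        return d


def _side_mapped(pair_type_char: str) -> bool:
    return pair_type_char in MAPPED_CLASSES


def compute_stats(
    records: Iterable[PairRecord],
    header: PairsHeader | None = None,
    with_scaling: bool = True,
    min_dist: int = 10,
    bins_per_decade: int = 8,
    rel_tol: float = 0.25,
    min_count: int = 100,
) -> StatsSummary:
    """Count pair types, cis/trans tiers, scalings and convergence in one pass."""
    s = StatsSummary()
    chromsizes = list(header.chromsizes) if header is not None else []
    scaling_records: list[PairRecord] = []
    for rec in records:
        s.total += 1
        t = rec.pair_type
        s.pair_types[t] = s.pair_types.get(t, 0) + 1
        if t == "DD":
            s.total_dups += 1
            s.total_mapped += 1
            continue
        m1 = _side_mapped(t[0]) if len(t) == 2 else False
        m2 = _side_mapped(t[1]) if len(t) == 2 else False
        if m1 and m2:
            s.total_mapped += 1
            s.total_nodups += 1
            if rec.chrom1 == rec.chrom2:
                s.cis += 1
                dist = abs(rec.pos2 - rec.pos1)
                for tier in DIST_TIERS:
                    if dist >= tier:
                        s.cis_at_distance[tier] = s.cis_at_distance.get(tier, 0) + 1
            else:
                s.trans += 1
            key = (rec.chrom1, rec.chrom2)
            s.chrom_freq[key] = s.chrom_freq.get(key, 0) + 1
            if with_scaling:
                scaling_records.append(rec)
        elif m1 or m2:
            s.total_single_sided_mapped += 1
        else:
            s.total_unmapped += 1
    for tier in DIST_TIERS:
        s.cis_at_distance.setdefault(tier, 0)
    s.complexity = estimate_complexity(
        s.total_nodups + s.total_dups, s.total_nodups
    )
    if with_scaling:
        s.scaling = compute_scaling(
            scaling_records,
            chromsizes=chromsizes,
            min_dist=min_dist,
            bins_per_decade=bins_per_decade,
        )
        s.convergence_dist = convergence_distance(
            s.scaling, rel_tol=rel_tol, min_count=min_count
        )
    return s


def _flatten(d: dict, prefix: str = "") -> list[tuple[str, object]]:
    rows: list[tuple[str, object]] = []
    for key, value in d.items():
        path = f"{prefix}/{key}" if prefix else str(key)
        if isinstance(value, dict):
            rows.extend(_flatten(value, path))
        else:
            rows.append((path, value))
    return rows


def _unflatten(rows: Iterable[tuple[str, object]]) -> dict:
    root: dict = {}
    for path, value in rows:
        parts = path.split("/")
        node = root
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = value
    return root


def write_stats(summary: StatsSummary | dict, stream: IO[str], format: str = "yaml") -> None:
    """Serialize a stats summary as nested YAML or a flat path<TAB>value TSV.

    The TSV flattens nested keys with "/" so that e.g. the convergence
    distance appears on the grep-able row
    ``summary/dist_freq_convergence/convergence_dist``.
    """
    d = summary.to_dict() if isinstance(summary, StatsSummary) else summary
    if format == "yaml":
        yaml.safe_dump(d, stream, default_flow_style=False, sort_keys=False)
    elif format == "tsv":
        for path, value in _flatten(d):
            stream.write(f"{path}\t{value}\n")
    else:
        raise ValueError(f"unknown stats format {format!r}")


def read_stats(stream: IO[str], format: str = "yaml") -> dict:
    """Parse a stats document written by :func:`write_stats` back to a dict."""
    if format == "yaml":
        return yaml.safe_load(stream) or {}
    if format == "tsv":
        rows = []
        for line in stream:
            if not line.strip():
                continue
            path, _, raw = line.rstrip("\n").partition("\t")
            value: object
            try:
                value = int(raw)
            except ValueError:
                try:
                    value = float(raw)  # YAML 1.1 misses bare "1e-12" floats
                except ValueError:
                    value = yaml.safe_load(raw)
            rows.append((path, value))
        return _unflatten(rows)
    raise ValueError(f"unknown stats format {format!r}")
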