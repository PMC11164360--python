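# Methods

This note documents the models, conventions and numerical choices behind
`paircraft`, and what the synthetic-data tests do and do not establish
about real data.

## Data model and conventions

A contact pair is a read id, two genomic sides (chromosome, 1-based
position, strand) and a two-letter pair type. The reported position of a
side is always the **5' end of its chosen alignment on the reference**
(strand-dependent): this choice is junction-independent and stable under
readthrough, whereas the 3' end moves with the sequenced length. A null
(unmapped) side is encoded as chromosome `!`, position 0, strand `.`.

Per-side mapping classes are `N` (null), `M` (mapped below the mapq
threshold), `U` (unique), plus `R` (rescued), `W` (masked walk) and `D`
(duplicate, assigned by dedup). Pairs are *flipped* into a canonical
orientation by comparing per-side keys (class rank with N < M < U, then
chromosome rank, then position). Flipping by class first makes the pair
type codes read `NU`/`MU` (null or multi side first) while the null
chromosome still ranks after all real chromosomes in the sort comparator,
so unmapped classes cluster at the end of a sorted file. Flipping is
idempotent, and side-paired extra columns (names ending `1`/`2`) are
swapped together with the coordinates.

## Parsing chimeric reads

Per read side, mapped primary and supplementary alignments are ordered by
their clip-aware span within the read; secondary alignments are excluded
from chains (they carry no independent molecule segment; they are only a
source of scores). Overlapping read spans keep the higher-mapq alignment,
then the longer span, then the 5'-most — an arbitrary but deterministic
tie-break. A null segment is inserted wherever more than
`max_inter_align_gap` (default 20 bp) of read sequence is unaligned,
including leading and trailing stretches, and for fully unmapped sides.

**Readthrough collapse.** When sequencing reads past ligation junctions
from both ends of a short molecule, the same genomic fragments appear in
both mates. The maximal overlap between side 1's chain suffix and the
reversed side-2 chain is found by requiring, element-wise, the same
chromosome, opposite strands and ≥ 1 bp reference overlap. Within each
matched pair of copies, the copy starting more 3' within its own read is
dropped. This keeps the mate-side copy in the single-ligation geometry, so
a rescued contact is reported with the mate's 5' coordinates, and keeps
the 5'-most copies in the symmetric multi-junction layout. A fully
readthrough single fragment (mate is an exact mirror) collapses to a
single segment and yields no record.

**Rescue.** A molecule with exactly three mapped unique segments — two on
one side (5' and 3') and one on the mate — is a single ligation whenever
the 3' segment and the mate segment are two reads of the same sequenced
fragment: same chromosome, opposite strands, 5' positions within
`max_molecule_size` (default 750 bp, an upper bound on sonicated fragment
length). The reported contact joins the 5' segment of the two-alignment
side with the mate segment, typed `RU`/`UR` with `R` on the rescued side.
Otherwise the molecule is a two-contact walk.

**Walk policies.** Molecules with ≥ 2 junctions after collapse are
expanded per policy: `mask` emits one null record typed `WW`; `all` emits
one record per adjacent segment pair, tagged with a 1-based junction index
in the `walk_pair_index` column; `5unique`/`3unique` report the 5'-/3'-most
*unique* segment of each side; `5any`/`3any` the extreme segments
regardless of class. For the `*any` policies, a mate with no mapped
segment at all lets both reported segments come from the mapped side (its
two extreme segments); the `*unique` policies always take one segment per
side, falling back to a null side when no unique segment exists. The
rationale: the `*any` policies are defined positionally ("the two extreme
alignments of the molecule"), which remains meaningful when one read is
entirely unalignable, while the `*unique` policies are defined per side.
On single-junction molecules all six policies emit the identical record.

Defaults `min_mapq = 1`, `max_molecule_size = 750`, `max_inter_align_gap
= 20` make the documented chimeric-read scenarios behave as described and
are all configurable.

## Sorting, merging, deduplication

Sorting uses the total key (rank1, rank2, pos1, pos2, strand1, strand2,
whole line) — the final whole-line tie-break makes output fully
deterministic. Inputs beyond the in-memory chunk size are sorted
externally via spilled runs and a k-way heap merge; `merge` applies the
same heap merge across files and verifies sortedness mid-stream.

Two candidate pairs (types `UU`, `UR`, `RU`; rescued and plain pairs may
co-cluster since coordinates govern) are duplicates when they share
chromosomes, strands and any configured match columns, and both positions
differ by at most `max_mismatch` (default 3 bp, accommodating trimming
jitter in protocols that amplify before sonication; 0 reproduces exact
matching). Duplicate clusters are connected components of this neighbour
graph, computed per (chromosome, strand, match-column) group with a
KD-tree fixed-radius query under the Chebyshev metric; the first record in
sort order is kept, the rest are rewritten to type `DD`. Chunked
processing carries over every trailing record within `max_mismatch` of the
chunk's final (chrom1, chrom2, pos1) key, together with its provisional
status and a flag marking clusters whose representative has already been
emitted; this makes the output provably independent of the chunk size,
which the tests verify against whole-input processing down to chunk size 1.

Library complexity solves U = C·(1 − e^(−T/C)) for the pool size C by
bracketed root finding (relative tolerance 1e−6). U = T yields an
undefined estimate (no duplicate evidence); U ≪ T saturates to C → U. The
model assumes uniform sampling with replacement — amplification bias makes
real estimates lower bounds.

## Statistics and scalings

`stats` counts pair types, both-side-unique totals, cis/trans and cis
distance tiers at {1, 2, 4, 10, 20, 40} kb (bracketing the range where
ligation by-products live) in a single pass. P(s) scalings bin the cis
separation s = pos2 − pos1 geometrically (default 8 bins per decade from
10 bp to the longest chromosome) per strand orientation; normalized values
are counts per bp of bin width. The average trans frequency divides the
trans pair count by the number of trans locus pairs, Σ_{i<j} len_i·len_j.

The **orientation convergence distance** scans bins from the largest
separation downward and returns the upper edge of the first (i.e.
rightmost) bin whose four orientation frequencies are not similar —
relative spread (max − min)/mean above `rel_tol` (default 0.25), judged
only on bins with at least `min_count` (default 100) pairs. If every
judged bin is similar the first bin edge is returned; if all are
dissimilar the curve never converges (serialized as −1). The tolerance
pair is a declared design choice: raw counts are multinomial-noisy, and on
sparse libraries (≲ 10⁴ pairs per decade) a bin holding ~100 pairs has
~25 counts per orientation, whose sampling spread alone can exceed 0.25 —
the statistic is then conservative, flagging short-separation bins as
unconverged. It is reliable from roughly 10⁵ cis pairs upward, where the
tests recover a planted 2 kb asymmetry within one geometric bin in 20/20
seeds.

TSV serialization flattens the nested summary with `/`-joined key paths
(e.g. `summary/dist_freq_convergence/convergence_dist`) so single values
are grep-able; YAML and TSV round-trip losslessly.

## Protocol tools

**Restriction.** A genome is digested at every overlapping match of an
IUPAC recognition pattern on either strand (palindromes counted once);
fragment boundaries sit at the first base of each match (enzyme-specific
cut offsets would shift all boundaries uniformly and do not change
same-fragment classification, so the default offset is 0). Sides are
located by binary search. Same-fragment pairs partition into dangling ends
(convergent `+-` after flipping), self-circles (divergent `-+`) and
mirrors (equal strands); different fragments are valid contacts.

**Phasing.** Reads are mapped to a concatenated diploid reference whose
chromosomes carry haplotype suffixes (`chr1#0`/`chr1#1`, separator and
suffixes configurable). Parse exports per side the best alignment score
(`AS`) and the best suboptimal score with its locations (`XS` + `XA`,
bwa-mem conventions; all reported alternative locations share the XS score
because bwa prints no per-location score). A side with no tie within
`score_tie_margin` (default 0: only exact ties are ambiguous) resolves to
its suffix's haplotype; a tie on the homologous chromosome means no
covering variant (unresolved, `.`); a tie anywhere else is a true
multi-mapper (`!`) — including a side unique across haplotypes but
ambiguous within one, a conservative choice. Both homologs pass through
identical code paths, so no haplotype is favoured; the tests verify the
resolved hap1:hap2 balance within 3 binomial standard deviations of 1:1.

**Coverage filter.** Two passes: count pair *sides* per genomic bin
(default 1 kb), then drop every record either side of which falls in a bin
whose count strictly exceeds `max_coverage`. Counting sides rather than
molecules makes the track independent of pairing, and the two-pass
contract makes the result independent of input order. The threshold is
dataset-specific (chromosome copy number × expected contacts per bin) and
has no universal default.

## Filter expressions

`select` compiles expressions over declared column names into a
whitelisted AST (comparisons, `and/or/not`, `+`/`-`, `abs`,
`regex(column, pattern)`, membership over literal collections). Arbitrary
code execution is deliberately impossible in the CLI; the Python API
accepts any callable predicate for full generality. Column types are
inferred from the fixed schema (positions, mapqs, scores integer) —
comparing a string column to a number raises naming the offending record.

## The simulator: what it emulates, and what it does not

The generator plants linear chimeric molecules on a uniform-random genome
(default two chromosomes of 1.5 and 1 Mb — large enough that coordinate
collisions between distinct molecules are negligible at 10⁵ molecules):

- simple contacts (default 70 % cis) with separations drawn from a power
  law P(s) ∝ s^(−1) between 1 kb and half the chromosome, fragment lengths
  normal (150 ± 40 bp, clipped to [60, 400]);
- walks with 2–3 junctions; restriction by-products as whole fragments
  (dangling end, self-circle, mirror) long enough that the two reads do
  not overlap; optional unmapped and mapq-0 molecules;
- PCR duplicates: Poisson-distributed copies per molecule, each side
  independently shifted ±1 bp with probability 0.5 (trimming jitter);
- diploid mode: two genome copies differing at Bernoulli(snv_rate)
  positions, with `XS`/`XA` tags emitted per alignment from the planted
  variant table.

Reads of 75 bp are taken from both molecule ends and decomposed
mechanically into the SAM records a perfect local aligner would report:
split pieces ≥ 20 bp as supplementary alignments with exact-match CIGARs
and correct soft clips, readthrough duplication whenever the molecule is
shorter than the combined read span, mates aligned independently. The
truth table records, per sequenced read, the intended contact (the pair of
5'-most fragments, i.e. what the `5unique` policy reports), its duplicate
group, class and haplotypes; the expected output of a perfect
parse–sort–dedup run is computed from the truth as the sort-order-first
clone of each duplicate group, making exact-coordinate comparisons
well-defined even under planted jitter.

Not emulated: sequencing errors and base qualities, indels, repetitive
sequence and genuine multi-mapping ambiguity, chimeric artifacts of the
aligner itself, insert-size mixtures, or chromatin structure beyond a
single power law. Passing the end-to-end tests therefore shows that the
toolchain is *algorithmically* correct on well-formed local-aligner output
— not that any aligner's quirks on repetitive real genomes are handled.

## Problem sizes and determinism

The test suite and the acceptance script run everything at desk scale,
chosen as the smallest sizes at which the statistical checks are stable:
10⁵ molecules for end-to-end recovery (≈ 15 s), 50 instances ≤ 2 000 pairs
for the duplicate-clustering oracle, 20 seeds × 10⁵ cis pairs for
convergence recovery, 10⁴ random positions for restriction oracles. All
randomness flows from explicit seeds (numpy `default_rng`); reruns are
byte-identical.
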