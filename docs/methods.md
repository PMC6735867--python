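# Methods

## Counting model

The unit of counting is the *transposase unit*: a maximal set of assigned
hit segments that plausibly derive from one insertion event. The
procedure is deliberately conservative about double counting — a decayed
element hit by several database transposases in several pieces is counted
once — while remaining a pure function of the hit table, so identical
inputs always yield identical annotations.

**Footprints.** Retained hits (E ≤ `evalue_cutoff`, default 1e-4,
inclusive) are merged per contig into footprints: connected components of
the interval-overlap graph. Merging is strand-agnostic, since a footprint
is defined only as a region containing hits. Two design points are fixed
here and matter for reproducibility:

* *Inclusive threshold*: a hit at exactly E = 1e-4 is retained.
* *Strict overlap*: intervals must share ≥ 1 bp to merge; abutting
  intervals (gap 0 shared bases) form separate footprints. No gap
  bridging happens at this stage — bridging is the joining stage's job,
  where it is subject to the strand and subject-consecutiveness checks.

**Assignment.** Each footprint is covered greedily by its own member
hits: the highest-bitscore hit is clipped to the footprint; each
uncovered remainder of length ≥ `min_remainder` is covered recursively by
the best hit overlapping it. Ties on bitscore break on lower e-value,
then longer nucleotide span, then lexicographically smaller protein id —
an arbitrary but fixed order. Clipping a segment trims its subject
(protein) interval by one amino acid per three nucleotides removed
(integer division, so the clipped subject interval never exceeds the
original). `min_remainder` defaults to 30 nt (10 aa): remainders below it
stay unassigned. Some floor is required for termination on slivers no hit
can meaningfully cover; 10 aa is roughly the shortest stretch a local
protein alignment can support. Unassigned slivers are permitted — a
footprint does not have to be exhausted when no hit overlaps a remainder.

**Joining.** Segments are scanned per contig in genomic order; a segment
extends the open chain when, relative to the chain's last segment:

1. genomic gap ≤ `max_gap_nt` (default 1000; measured end-to-start
   exclusive, so abutting segments have gap 0);
2. same strand;
3. subject consecutiveness within `consecutive_tolerance_aa` (default
   50): on the plus strand `|sstart_next − send_prev − 1| ≤ 50`; on the
   minus strand the protein runs right-to-left along the genome, so the
   comparison reverses to `|sstart_prev − send_next − 1| ≤ 50`.

Fragments are *not* required to match the same database protein — closely
related transposases routinely split a single element's hits — only
consecutive parts of transposases. Chains are maximal; each chain or
singleton is one unit.

**Fraction of transposase.** Singleton: covered nt divided by the full
coding nt length (3 × aa length, stop codon excluded — protein FASTA
readers strip a trailing `*` by default) of the matched transposase.
Joined: summed fragment coverage divided by the *shortest* originating
transposase. The ratio can exceed 1 for joined units; such values are
reported and logged, not clamped, because they are informative (they flag
over-joining or tandem remnants). Every unit counts once in density
statistics regardless of fraction; a `min_fraction` filter exists but
defaults to 0.

## Built-in translated search

`tnfoot.search` makes the pipeline self-contained at desk scale: six-frame
translation (ambiguous codons → X) and affine-gap local Smith–Waterman of
each frame against each database protein (BLOSUM62; BLAST-style gap cost
`open + k·extend`, defaults 11/1), one best alignment per (frame,
protein). E-values use the ungapped Karlin–Altschul correction with fixed
BLOSUM62 constants (λ = 0.3176, K = 0.134) and per-pair search space
m·n. This calibration is approximate by construction; it is adequate
because downstream logic only thresholds at 1e-4 and hermetic tests
control hit generation. The reported optimum is the aligner's
deterministic leftmost traceback. Production-scale runs should ingest
external translated-search tables instead; the two routes meet at the
identical 12-column format.

## Inverted repeats

The screen reports maximal arm pairs where one arm matches the reverse
complement of the other under a per-window rule: every `window`-bp
(default 12) window within the pairing must match with identity ≥
`min_identity` (default 0.92). Because mismatch budgets are integral,
floor(12 × 0.08) = 0: the defaults demand exact reverse-complement arms
of length ≥ 12. Geometrically, valid window pairs lie on anti-diagonals
of the complement-match matrix, and maximal arms are maximal runs of
consecutive valid windows along one anti-diagonal; the implementation
seeds runs by hashing forward 12-mers against reverse-complement 12-mers
(exact case) or scans anti-diagonals directly (mismatch-tolerant case).
Arm distance is the exclusive gap between arm1 end and arm2 start
(minimum 0 = abutting); pairs whose maximal arms would overlap
(palindrome centres) are suppressed rather than trimmed. Each pair is
reported once with arm1 upstream, ordered by (arm1 start, arm2 start).
Expected chance hits: in L bp of background with per-position pairing
probability p (≈ 0.29 at GC 0.69), about L²p¹²/2 exact 12-mer pairs —
a handful per 10 kb — so screen output is interpreted jointly with the
transposase annotation, not alone.

## Statistics

Density = units / assembly size in Mb. The externally reported assembly
size takes precedence over the contig-length sum when both are available
(a ≥ 1 % discrepancy is logged); joined units count once. Group
comparisons exclude complete assemblies by default: assembly condenses
repeated elements into single contigs, so repeat counts are only
comparable within one assembly status.

The rank-sum test is exact (conventional doubled one-tail, capped at 1)
for untied pooled samples with n₁ + n₂ ≤ 20, and otherwise uses mid-ranks
with the tie-corrected normal approximation and continuity correction;
the method used is always reported, since exact-with-ties conventions
vary across software. The genome-size summary is the mean and sample
standard deviation (n − 1); rounding happens only at the presentation
layer.

The bundled metadata table records the published cluster-2 panel
(15 genomes: 10 Eurasian, 4 North American, 1 Southern-hemisphere; one
complete assembly). The nine single-dominant-strain assembly sizes
summarise to 5.2 ± 0.3 Mb at one-decimal rounding. Per-genome transposase
counts are not bundled; reproducing the published Eurasian vs
North-American draft comparison requires the original per-genome
annotation files (see `tests/test_acceptance.py` for the expected input).

## Synthetic data

The generator emulates what the pipeline must be correct about, not IS
biology in full. Background is i.i.d. nucleotide sequence at a GC target
(default 0.69, the high-GC actinobacterial regime). Planted elements are
exact synonymous reverse-translations of database proteins: N-terminal
truncations (keeping subject coordinates deterministic for join tests),
optional fragmentation with background gaps, either strand, optional
`CTAGCTAGCTAG` flanks. Gap/background segments are rejected if any
reading frame contains an exact 12-aa match to a database protein, so
ideal-mode hit tables cannot contain spurious hits. The bundled protein
set is 10 synthetic stand-in "transposases" (120–450 aa, fixed seed) —
random sequences with no real transposase motifs. Everything is
bit-reproducible given (seed, specs).

Consequences for interpretation: passing recovery tests demonstrates the
counting logic (footprints, assignment, joining, fractions) under clean
hits. It does not measure search sensitivity on diverged real elements,
nor robustness to terminal inverted repeats, target-site duplications or
nested insertions, none of which are modelled.

Test and acceptance problem sizes (hit sets ≤ 100 intervals, contigs of
0.8–24 kb, 40-plant recovery panels, 50 × 2-kb repeat-oracle contigs,
rank-sum enumeration at n ≤ 10) were chosen so every brute-force oracle
runs comfortably while still exercising each code path; all scale knobs
are plain function arguments.

## Known limitations

* No IS-family classification, boundary (TIR/TSD) validation, or
  autonomous-vs-defective calling beyond the fraction statistic.
* The greedy footprint cover is a heuristic: it is deterministic and
  matches the intended highest-score-first semantics, but it does not
  globally optimise coverage.
* E-value calibration of the built-in search is ungapped-approximate.
* The exact rank-sum path requires untied samples; tied densities fall
  back to the normal approximation (reported as such).
* GFF3 is the only annotation output format; GenBank flat files are out
  of scope.
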