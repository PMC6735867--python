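"""Footprint construction, transposase assignment, fragment joining and the
fraction-of-transposase statistic.

This is the heart of the package.  Translated-search hits against a
transposase database are first thresholded on e-value; per contig, every
maximal genomic interval covered by at least one retained hit becomes a
*footprint*.  Each footprint is then covered greedily: the highest-scoring
member hit claims its interval, and uncovered remainders are covered
recursively by the best hit overlapping them.  Nearby assigned segments are
joined into single transposase units when (1) they lie within 1 kb of each
other, (2) they are on the same strand, and (3) they match consecutive
(+/- 50 aa) parts of database transposases.  Every unit finally receives a
fraction-of-transposase value: nucleotides covered divided by the full
coding nucleotide length of the matched transposase (for joined units, the
summed coverage divided by the shortest originating transposase).  A
fraction near 1 flags a potentially intact, transposition-capable element.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .io import GenomeRecord, TransposaseHit, TransposaseProtein

logger = logging.getLogger(__name__)

DEFAULT_EVALUE_CUTOFF = 1e-4
DEFAULT_MIN_REMAINDER = 30  # nt; remainder slivers below this stay unassigned


@dataclass(frozen=True)
class JoinCriteria:
    """The three fragment-joining criteria.

    max_gap_nt: largest allowed gap (end-to-start, exclusive; adjacent
        segments have gap 0) between consecutive fragments.
    require_same_strand: fragments must lie on one strand.
    consecutive_tolerance_aa: allowed discontinuity between the subject
        (protein) intervals of consecutive fragments, in amino acids.
    """

    max_gap_nt: int = 1000
    require_same_strand: bool = True
    consecutive_tolerance_aa: int = 50

    def __post_init__(self) -> None:
        if self.max_gap_nt < 0 or self.consecutive_tolerance_aa < 0:
            raise ValueError("join criteria must be non-negative")


@dataclass
class Footprint:
    """A maximal contig interval covered by >= 1 retained hit."""

    contig_id: str
    start: int
    end: int
    hits: list[TransposaseHit] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AssignedSegment:
    """A hit clipped to the part of a footprint it was assigned to cover."""

    contig_id: str
    start: int
    end: int
    strand: str
    protein_id: str
    sstart: int
    send: int
    source_hit: TransposaseHit

    @property
    def covered_nt(self) -> int:
        return self.end - self.start + 1


@dataclass
class TransposaseUnit:
    """One counted transposase ORF: a single segment or a joined chain."""

    fragments: list[AssignedSegment]
    fraction: float

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValueError("a unit needs >= 1 fragment")

    @property
    def contig_id(self) -> str:
        return self.fragments[0].contig_id

    @property
    def start(self) -> int:
        return self.fragments[0].start

    @property
    def end(self) -> int:
        return self.fragments[-1].end

    @property
    def strand(self) -> str:
        return self.fragments[0].strand

    @property
    def joined(self) -> bool:
        return len(self.fragments) > 1

    @property
    def protein_ids(self) -> list[str]:
        seen: list[str] = []
        for f in self.fragments:
            if f.protein_id not in seen:
                seen.append(f.protein_id)
        return seen

    @property
    def covered_nt(self) -> int:
        return sum(f.covered_nt for f in self.fragments)


# ---------------------------------------------------------------------------
# stage 1: e-value filter
# ---------------------------------------------------------------------------

def filter_hits(hits: Iterable[TransposaseHit],
                evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF) -> list[TransposaseHit]:
    """Retain hits with evalue <= cutoff (inclusive), preserving order."""
    return [h for h in hits if h.evalue <= evalue_cutoff]


# ---------------------------------------------------------------------------
# stage 2: footprints
# ---------------------------------------------------------------------------

def build_footprints(hits: Sequence[TransposaseHit]) -> list[Footprint]:
    """Merge retained hit intervals into maximal disjoint footprints.

    Strand-agnostic: hits on both strands can share a footprint.  Two hits
    belong to the same footprint iff their intervals overlap by >= 1 bp
    (adjacent intervals with a gap of zero shared bases stay separate).
    Returned footprints are sorted by (contig, start).
    """
    by_contig: dict[str, list[TransposaseHit]] = {}
    for h in hits:
        by_contig.setdefault(h.contig_id, []).append(h)

    out: list[Footprint] = []
    for contig in sorted(by_contig):
        chits = sorted(by_contig[contig], key=lambda h: (h.qstart, h.qend))
        current: Optional[Footprint] = None
        for h in chits:
            if current is not None and h.qstart <= current.end:
                current.end = max(current.end, h.qend)
                current.hits.append(h)
            else:
                current = Footprint(contig, h.qstart, h.qend, [h])
                out.append(current)
    return out


# ---------------------------------------------------------------------------
# stage 3: greedy assignment with remainder covering
# ---------------------------------------------------------------------------

def _clip_hit(hit: TransposaseHit, lo: int, hi: int) -> AssignedSegment:
    """Clip a hit to [lo, hi], adjusting the subject interval in step.

    Trimming k nt off the genomic side of an alignment removes about k/3
    aa from the corresponding protein end: the 5' end of a plus-strand hit
    (3' of a minus-strand hit) maps to sstart.  Integer division keeps the
    clipped subject interval inside the original one.
    """
    start = max(hit.qstart, lo)
    end = min(hit.qend, hi)
    if start > end:
        raise ValueError("hit does not overlap the clip interval")
    trim_left = (start - hit.qstart) // 3
    trim_right = (hit.qend - end) // 3
    if hit.strand == "+":
        ss, se = hit.sstart + trim_left, hit.send - trim_right
    else:
        ss, se = hit.sstart + trim_right, hit.send - trim_left
    if ss > se:  # degenerate clip to < 1 codon
        ss = se = min(max(hit.sstart, ss), hit.send)
    return AssignedSegment(
        contig_id=hit.contig_id, start=start, end=end, strand=hit.strand,
        protein_id=hit.protein_id, sstart=ss, send=se, source_hit=hit,
    )


def _hit_rank(h: TransposaseHit) -> tuple:
    # higher bitscore, then lower evalue, then longer span, then lexicographic id
    return (-h.bitscore, h.evalue, -(h.qend - h.qstart + 1), h.protein_id)


def assign_transposases(footprint: Footprint,
                        min_remainder: int = DEFAULT_MIN_REMAINDER
                        ) -> list[AssignedSegment]:
    """Greedy cover of a footprint by its member hits.

    The highest-bitscore hit is clipped to the footprint and claims its
    interval; each uncovered remainder of length >= ``min_remainder`` is
    covered recursively by the best hit overlapping it.  Remainders no hit
    overlaps, or shorter than ``min_remainder``, stay unassigned.  Ties on
    bitscore break on lower evalue, then longer nt span, then the
    lexicographically smaller protein id.
    """
    if not footprint.hits:
        raise ValueError("footprint has no member hits")

    segments: list[AssignedSegment] = []

    def cover(lo: int, hi: int, is_remainder: bool) -> None:
        if lo > hi:
            return
        if is_remainder and (hi - lo + 1) < min_remainder:
            return
        candidates = [h for h in footprint.hits if h.qstart <= hi and h.qend >= lo]
        if not candidates:
            return
        best = min(candidates, key=_hit_rank)
        seg = _clip_hit(best, lo, hi)
        segments.append(seg)
        cover(lo, seg.start - 1, True)
        cover(seg.end + 1, hi, True)

    cover(footprint.start, footprint.end, False)
    segments.sort(key=lambda s: s.start)
    return segments


# ---------------------------------------------------------------------------
# stage 4: fragment joining
# ---------------------------------------------------------------------------

def segments_joinable(a: AssignedSegment, b: AssignedSegment,
                      criteria: JoinCriteria) -> bool:
    """Can segment ``b`` (downstream) extend a chain ending in ``a``?

    Criterion 1: genomic gap (exclusive) <= max_gap_nt.
    Criterion 2: same strand (when required).
    Criterion 3: consecutive subject parts within the aa tolerance; on the
    minus strand the protein runs right-to-left along the genome, so the
    subject order of the comparison is reversed.
    """
    if a.contig_id != b.contig_id:
        return False
    gap = b.start - a.end - 1
    if gap > criteria.max_gap_nt:
        return False
    if criteria.require_same_strand and a.strand != b.strand:
        return False
    if a.strand == "-" and b.strand == "-":
        discontinuity = abs(a.sstart - b.send - 1)
    else:
        discontinuity = abs(b.sstart - a.send - 1)
    return discontinuity <= criteria.consecutive_tolerance_aa


def join_fragments(segments: Sequence[AssignedSegment],
                   criteria: JoinCriteria = JoinCriteria(),
                   proteins: Optional[Mapping[str, TransposaseProtein]] = None,
                   ) -> list[TransposaseUnit]:
    """Chain assigned segments into transposase units.

    Segments are scanned per contig in genomic order; a segment joins the
    open chain when it satisfies all three criteria against the chain's
    last segment, otherwise it opens a new chain.  Each maximal chain (or
    singleton) becomes one unit.  When ``proteins`` is given, fractions are
    computed; otherwise they are left at 0 for later computation.
    Overlapping segments on one contig violate the assignment contract and
    raise ValueError.
    """
    ordered = sorted(segments, key=lambda s: (s.contig_id, s.start, s.end))
    for a, b in zip(ordered, ordered[1:]):
        if a.contig_id == b.contig_id and b.start <= a.end:
            raise ValueError(
                f"overlapping segments on {a.contig_id}: "
                f"[{a.start},{a.end}] and [{b.start},{b.end}]"
            )

    units: list[TransposaseUnit] = []
    chain: list[AssignedSegment] = []

    def flush() -> None:
        if chain:
            units.append(TransposaseUnit(fragments=list(chain), fraction=0.0))
            chain.clear()

    for seg in ordered:
        if chain and chain[-1].contig_id == seg.contig_id and \
                segments_joinable(chain[-1], seg, criteria):
            chain.append(seg)
        else:
            flush()
            chain.append(seg)
    flush()

    if proteins is not None:
        units = [replace(u, fraction=fraction_of_transposase(u, proteins))
                 for u in units]
    return units


# ---------------------------------------------------------------------------
# stage 5: fraction of transposase
# ---------------------------------------------------------------------------

def fraction_of_transposase(unit: TransposaseUnit,
                            proteins: Mapping[str, TransposaseProtein]) -> float:
    """Coverage statistic of one unit.

    Singletons: covered nt divided by the full coding nt length of the
    matched transposase.  Joined units: summed fragment coverage divided by
    the shortest originating transposase.  Values above 1 are possible for
    joined units and are reported as-is (logged), not clamped.
    """
    for f in unit.fragments:
        if f.protein_id not in proteins:
            raise KeyError(f"unknown protein_id {f.protein_id!r}")
    denom = min(proteins[f.protein_id].nt_length for f in unit.fragments)
    frac = unit.covered_nt / denom
    if frac > 1.0:
        logger.info("unit on %s:%d-%d has fraction %.3f > 1",
                    unit.contig_id, unit.start, unit.end, frac)
    return frac


# ---------------------------------------------------------------------------
# full pipeline per genome
# ---------------------------------------------------------------------------

def annotate_genome(genome: GenomeRecord,
                    hits: Sequence[TransposaseHit],
                    proteins: Mapping[str, TransposaseProtein],
                    criteria: JoinCriteria = JoinCriteria(),
                    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
                    min_remainder: int = DEFAULT_MIN_REMAINDER,
                    min_fraction: float = 0.0) -> list[TransposaseUnit]:
    """filter -> footprints -> assignment -> joining -> fractions.

    Returns units sorted by (contig, start).  ``min_fraction`` drops units
    below the threshold; the default 0 counts every unit, fragmentary or
    not, as one transposase ORF.
    """
    if genome.contigs:
        unknown = {h.contig_id for h in hits} - set(genome.contigs)
        if unknown:
            raise ValueError(f"hits reference unknown contigs: {sorted(unknown)}")
    retained = filter_hits(hits, evalue_cutoff)
    segments: list[AssignedSegment] = []
    for fp in build_footprints(retained):
        segments.extend(assign_transposases(fp, min_remainder=min_remainder))
    units = join_fragments(segments, criteria, proteins=proteins)
    if min_fraction > 0:
        units = [u for u in units if u.fraction >= min_fraction]
    units.sort(key=lambda u: (u.contig_id, u.start))
    return units
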