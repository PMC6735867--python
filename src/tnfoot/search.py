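"""Built-in translated homology search.

Six-frame translation of each contig followed by affine-gap local
(Smith-Waterman) alignment of every frame against the transposase protein
set, emitting the same hit records as an external translated search would.
This keeps the whole pipeline runnable without any external aligner at
desk scale; production runs can instead ingest externally produced
12-column hit tables through :mod:`tnfoot.io`.

E-values use the ungapped Karlin-Altschul extreme-value correction with
fixed BLOSUM62 constants (lambda = 0.3176, K = 0.134); downstream logic
only thresholds at 1e-4, so gapped recalibration is deliberately out of
scope.  Only the single best local alignment per (frame, protein) pair is
reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .io import GenomeRecord, TransposaseHit, TransposaseProtein, revcomp

# ungapped Karlin-Altschul constants for BLOSUM62
KA_LAMBDA = 0.3176
KA_K = 0.134

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring and reporting parameters of the built-in search."""

    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    min_bitscore: float = 40.0
    ka_lambda: float = KA_LAMBDA
    ka_k: float = KA_K
    search_space: float | None = None  # default: per-pair m * n

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("need gap_open >= gap_extend >= 0")
        if self.ka_lambda <= 0 or self.ka_k <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")


def bitscore_from_raw(raw: float, params: AlignmentParams) -> float:
    return (params.ka_lambda * raw - math.log(params.ka_k)) / math.log(2.0)


def evalue_from_bitscore(bits: float, m: int, n: int,
                         params: AlignmentParams) -> float:
    space = params.search_space if params.search_space is not None else m * n
    return space * 2.0 ** (-bits)


def six_frame_translate(contig: str) -> dict[int, tuple[str, "FrameMap"]]:
    """Translate a contig in all six frames.

    Returns frame -> (aa string, coordinate map).  Codons containing N
    translate to X; internal stops appear as '*'.  Contigs shorter than
    one codon give an empty result.
    """
    seq = contig.upper()
    n = len(seq)
    if n < 3:
        return {}
    out: dict[int, tuple[str, FrameMap]] = {}
    rc = revcomp(seq)
    for frame in FRAMES:
        src = seq if frame > 0 else rc
        off = abs(frame) - 1
        usable = (n - off) // 3 * 3
        if usable == 0:
            continue
        aa = str(Seq(src[off:off + usable]).translate())
        out[frame] = (aa, FrameMap(frame=frame, contig_length=n))
    return out


@dataclass(frozen=True)
class FrameMap:
    """Converts aa intervals in one frame to forward-strand nt intervals."""

    frame: int
    contig_length: int

    def to_nt(self, aa_start: int, aa_end: int) -> tuple[int, int]:
        """Map a 1-based inclusive aa interval to forward nt coordinates."""
        if not (1 <= aa_start <= aa_end):
            raise ValueError("bad aa interval")
        off = abs(self.frame) - 1
        lo = off + 3 * (aa_start - 1) + 1          # 1-based on the frame strand
        hi = off + 3 * aa_end
        if self.frame > 0:
            return lo, hi
        return self.contig_length - hi + 1, self.contig_length - lo + 1


def _make_aligner(params: AlignmentParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(
        params.substitution_matrix)
    # BLAST convention: a gap of length k costs open + k * extend
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def local_align(query_aa: str, subject_aa: str,
                params: AlignmentParams = AlignmentParams()
                ) -> tuple[float, tuple[int, int], tuple[int, int], float] | None:
    """Best affine-gap local alignment of two amino-acid strings.

    Returns (raw score, query interval, subject interval, identity fraction)
    with 1-based inclusive intervals, or None when no positive-scoring
    alignment exists.  The reported alignment is the aligner's deterministic
    first optimum (leftmost traceback), so results are reproducible.
    """
    if not query_aa or not subject_aa:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner(params)
    score = aligner.score(query_aa, subject_aa)
    if score <= 0:
        return None
    aln = aligner.align(query_aa, subject_aa)[0]
    qblocks, sblocks = aln.aligned
    qs, qe = int(qblocks[0][0]) + 1, int(qblocks[-1][1])
    ss, se = int(sblocks[0][0]) + 1, int(sblocks[-1][1])
    matches = 0
    columns = 0
    for (q0, q1), (s0, s1) in zip(qblocks, sblocks):
        for qi, si in zip(range(q0, q1), range(s0, s1)):
            columns += 1
            if query_aa[qi] == subject_aa[si]:
                matches += 1
    identity = matches / columns if columns else 0.0
    return float(score), (qs, qe), (ss, se), identity


def search_genome(genome: GenomeRecord,
                  proteins: Mapping[str, TransposaseProtein] | Sequence[TransposaseProtein],
                  params: AlignmentParams = AlignmentParams()
                  ) -> list[TransposaseHit]:
    """Search every contig frame against every protein.

    Emits one hit per (contig, frame, protein) local optimum whose bit
    score reaches ``params.min_bitscore``; minus-frame hits carry strand
    '-' and forward-strand nt coordinates.  Hit content is invariant to
    contig iteration order (results are sorted).
    """
    if not isinstance(proteins, Mapping):
        proteins = {p.protein_id: p for p in proteins}
    if not proteins:
        raise ValueError("empty protein set")
    hits: list[TransposaseHit] = []
    for contig_id, contig in genome.contigs.items():
        frames = six_frame_translate(contig)
        for frame, (aa, fmap) in frames.items():
            if not aa.strip("X*"):
                continue
            for pid, prot in proteins.items():
                res = local_align(aa, prot.sequence, params)
                if res is None:
                    continue
                raw, (qs_aa, qe_aa), (ss, se), identity = res
                bits = bitscore_from_raw(raw, params)
                if bits < params.min_bitscore:
                    continue
                ev = evalue_from_bitscore(bits, len(aa), prot.aa_length, params)
                nt_lo, nt_hi = fmap.to_nt(qs_aa, qe_aa)
                hits.append(TransposaseHit(
                    contig_id=contig_id, qstart=nt_lo, qend=nt_hi,
                    strand="+" if frame > 0 else "-",
                    protein_id=pid, sstart=ss, send=se,
                    evalue=ev, bitscore=bits, identity_pct=100.0 * identity,
                ))
    hits.sort(key=lambda h: (h.contig_id, h.qstart, h.qend, h.protein_id))
    return hits
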