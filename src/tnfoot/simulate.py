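"""Synthetic genomes with planted transposase copies and a truth table.

The generator emulates the genomic structures the pipeline is built to
annotate: high-GC (~69%) bacterial contigs carrying full-length, truncated
and fragmented transposase copies on both strands, optionally flanked by a
self-reverse-complementary 12-mer (CTAGCTAGCTAG) the way mobile nod regions
are bounded by inverted repeats.  Every planted element is recorded in a
machine-readable truth table, and "ideal" hit tables (exact coordinates,
100% identity) can be derived from the truth so each pipeline stage is
testable hermetically, without any external search tool or download.

What this emulates and what it does not: background composition is i.i.d.
with a GC target, planted copies are exact reverse-translations of the
database protein, and fragment gaps are fresh background.  Real IS elements
carry terminal inverted repeats, target-site duplications, sequence
divergence from the database representative and nested insertions; none of
those are modelled, so recovery results bound pipeline logic, not search
sensitivity on diverged elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .io import GenomeRecord, TransposaseHit, TransposaseProtein, revcomp

CTAG_IR = "CTAGCTAGCTAG"  # its own reverse complement

DEFAULT_GC = 0.69  # high-GC actinobacterial target

_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def _synonymous_codons() -> dict[str, list[str]]:
    table = CodonTable.unambiguous_dna_by_id[1].forward_table
    out: dict[str, list[str]] = {}
    for codon, aa in table.items():
        out.setdefault(aa, []).append(codon)
    for aa in out:
        out[aa].sort()
    return out


_CODONS = _synonymous_codons()


@dataclass(frozen=True)
class PlantSpec:
    """One planted transposase copy.

    insert_position: offset into the *original* background after which the
        insert is placed (0 <= position <= background length); positions of
        multiple specs on one contig must be strictly increasing so inserts
        cannot overlap.
    planted_fraction: fraction of the protein's coding length that is
        planted (N-terminal portion, so subject coordinates are
        deterministic).
    n_fragments / fragment_gaps: the planted portion is split into this
        many pieces separated by fresh background gaps of the given sizes.
    flank_with_ir: wrap the whole insert in the CTAGCTAGCTAG motif pair.
    """

    protein_id: str
    contig_id: str
    insert_position: int
    strand: str = "+"
    planted_fraction: float = 1.0
    n_fragments: int = 1
    fragment_gaps: tuple[int, ...] = ()
    flank_with_ir: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if not (0 < self.planted_fraction <= 1):
            raise ValueError("planted_fraction must be in (0, 1]")
        if self.n_fragments < 1:
            raise ValueError("n_fragments must be >= 1")
        if len(self.fragment_gaps) != self.n_fragments - 1:
            raise ValueError("need n_fragments - 1 fragment gaps")
        if any(g < 0 for g in self.fragment_gaps):
            raise ValueError("fragment gaps must be >= 0")


@dataclass
class TruthRecord:
    """Realised coordinates of one planted element (1-based inclusive)."""

    spec: PlantSpec
    fragments: list[tuple[int, int, int, int]] = field(default_factory=list)
    # each fragment: (start, end, sstart, send); sorted by genomic start

    @property
    def contig_id(self) -> str:
        return self.spec.contig_id

    @property
    def protein_id(self) -> str:
        return self.spec.protein_id

    @property
    def strand(self) -> str:
        return self.spec.strand


def generate_background(length: int, gc: float = DEFAULT_GC,
                        seed: int | np.random.Generator = 0) -> str:
    """I.i.d. nucleotide background with P(G) + P(C) = gc."""
    if length <= 0:
        raise ValueError("length must be > 0")
    if not (0 < gc < 1):
        raise ValueError("gc must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def reverse_translate(protein: str | TransposaseProtein,
                      seed: int | np.random.Generator = 0) -> str:
    """Random synonymous reverse-translation; frame +1 translation round-trips."""
    seq = protein.sequence if isinstance(protein, TransposaseProtein) else protein
    if not seq:
        raise ValueError("protein must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codons = []
    for aa in seq:
        choices = _CODONS.get(aa)
        if choices is None:
            raise ValueError(f"cannot reverse-translate residue {aa!r}")
        codons.append(choices[rng.integers(len(choices))])
    return "".join(codons)


def _protein_kmers(proteins: Mapping[str, TransposaseProtein], k: int = 12) -> set[str]:
    kmers: set[str] = set()
    for p in proteins.values():
        for i in range(len(p.sequence) - k + 1):
            kmers.add(p.sequence[i:i + k])
    return kmers


def _safe_background(length: int, gc: float, rng: np.random.Generator,
                     protein_kmers: set[str], k: int = 12,
                     max_tries: int = 20) -> str:
    """Background guaranteed (by rejection) not to encode any database
    protein 12-mer in any frame, so ideal-mode gaps cannot spawn hits."""
    from .search import six_frame_translate
    for _ in range(max_tries):
        cand = generate_background(length, gc, rng)
        if length < 3 * k:
            return cand
        dirty = False
        for aa, _ in six_frame_translate(cand).values():
            if any(aa[i:i + k] in protein_kmers for i in range(len(aa) - k + 1)):
                dirty = True
                break
        if not dirty:
            return cand
    raise RuntimeError("could not generate clean background")  # pragma: no cover


def plant_elements(background: str, specs: Sequence[PlantSpec],
                   proteins: Mapping[str, TransposaseProtein],
                   seed: int | np.random.Generator = 0,
                   gc: float = DEFAULT_GC) -> tuple[str, list[TruthRecord]]:
    """Insert planted elements into one background contig.

    Specs must share one contig_id and have strictly increasing
    insert_position values within the background.  Returns the assembled
    contig and truth records with realised coordinates (computed while
    assembling left to right, so later insertions are already accounted
    for).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not specs:
        return background, []
    contig_ids = {s.contig_id for s in specs}
    if len(contig_ids) > 1:
        raise ValueError(f"specs span several contigs: {sorted(contig_ids)}")
    positions = [s.insert_position for s in specs]
    if positions != sorted(positions) or len(set(positions)) != len(positions):
        raise ValueError("insert positions must be strictly increasing (no overlap)")
    if positions[-1] > len(background):
        raise ValueError("insert position beyond background")

    kmers = _protein_kmers(proteins)
    pieces: list[str] = []
    truths: list[TruthRecord] = []
    cursor = 0   # position in original background
    offset = 0   # length of assembled sequence so far

    for spec in specs:
        prot = proteins[spec.protein_id]
        pieces.append(background[cursor:spec.insert_position])
        offset += spec.insert_position - cursor
        cursor = spec.insert_position

        insert, local_frags = _build_insert(spec, prot, rng, gc, kmers)
        truth = TruthRecord(spec=spec)
        for (lo, hi, sa, sb) in local_frags:
            truth.fragments.append((offset + lo + 1, offset + hi + 1, sa, sb))
        truth.fragments.sort(key=lambda f: f[0])
        truths.append(truth)
        pieces.append(insert)
        offset += len(insert)

    pieces.append(background[cursor:])
    return "".join(pieces), truths


def _build_insert(spec: PlantSpec, prot: TransposaseProtein,
                  rng: np.random.Generator, gc: float,
                  kmers: set[str]) -> tuple[str, list[tuple[int, int, int, int]]]:
    """Assemble one insert; fragment coordinates are 0-based local."""
    total_aa = int(round(spec.planted_fraction * prot.aa_length))
    total_aa = max(total_aa, spec.n_fragments)
    rt = reverse_translate(prot, rng)[:3 * total_aa]

    base, extra = divmod(total_aa, spec.n_fragments)
    sizes = [base + (1 if i < extra else 0) for i in range(spec.n_fragments)]

    frag_nt: list[str] = []
    frag_subject: list[tuple[int, int]] = []
    aa_cursor = 0
    for size in sizes:
        frag_nt.append(rt[3 * aa_cursor:3 * (aa_cursor + size)])
        frag_subject.append((aa_cursor + 1, aa_cursor + size))
        aa_cursor += size

    core_parts: list[str] = []
    local: list[tuple[int, int, int, int]] = []  # on the forward core
    pos = 0
    for i, (nt, (sa, sb)) in enumerate(zip(frag_nt, frag_subject)):
        core_parts.append(nt)
        local.append((pos, pos + len(nt) - 1, sa, sb))
        pos += len(nt)
        if i < len(spec.fragment_gaps):
            gap = _safe_background(spec.fragment_gaps[i], gc, rng, kmers) \
                if spec.fragment_gaps[i] > 0 else ""
            core_parts.append(gap)
            pos += len(gap)
    core = "".join(core_parts)

    if spec.strand == "-":
        core = revcomp(core)
        L = len(core)
        local = [(L - 1 - hi, L - 1 - lo, sa, sb) for (lo, hi, sa, sb) in local]

    if spec.flank_with_ir:
        core = CTAG_IR + core + CTAG_IR
        local = [(lo + len(CTAG_IR), hi + len(CTAG_IR), sa, sb)
                 for (lo, hi, sa, sb) in local]
    return core, local


def ideal_hits(truths: Sequence[TruthRecord],
               proteins: Mapping[str, TransposaseProtein]) -> list[TransposaseHit]:
    """Perfect hit table implied by the truth: one hit per planted fragment
    with exact coordinates, 100% identity, bitscore proportional to the
    fragment's aa length and an e-value far below the retention cutoff."""
    hits: list[TransposaseHit] = []
    for t in truths:
        if t.protein_id not in proteins:
            raise KeyError(f"unknown protein {t.protein_id!r}")
        for (start, end, sa, sb) in t.fragments:
            aa_len = sb - sa + 1
            hits.append(TransposaseHit(
                contig_id=t.contig_id, qstart=start, qend=end, strand=t.strand,
                protein_id=t.protein_id, sstart=sa, send=sb,
                evalue=1e-10 * (aa_len / 10.0), bitscore=2.0 * aa_len,
                identity_pct=100.0,
            ))
    hits.sort(key=lambda h: (h.contig_id, h.qstart))
    return hits


def truth_table(truths: Sequence[TruthRecord]) -> pd.DataFrame:
    """Flatten truth records into one row per planted fragment."""
    rows = []
    for i, t in enumerate(truths):
        for j, (start, end, sa, sb) in enumerate(t.fragments):
            rows.append({
                "plant_id": i, "contig_id": t.contig_id,
                "protein_id": t.protein_id, "strand": t.strand,
                "planted_fraction": t.spec.planted_fraction,
                "n_fragments": t.spec.n_fragments, "fragment_index": j,
                "start": start, "end": end, "sstart": sa, "send": sb,
                "flank_with_ir": t.spec.flank_with_ir,
            })
    return pd.DataFrame(rows)


def bundled_transposase_proteins(n: int = 10,
                                 seed: int = 20150531) -> dict[str, TransposaseProtein]:
    """A small set of synthetic stand-in 'transposase' proteins.

    Deterministic random amino-acid sequences spanning realistic IS
    transposase lengths (120-450 aa).  They are synthetic: generated here,
    not drawn from any curated IS database, and carry no real transposase
    motifs; they exist so search, planting and annotation are exercised
    hermetically.
    """
    rng = np.random.default_rng(seed)
    lengths = [120, 150, 180, 210, 240, 270, 300, 340, 390, 450]
    out: dict[str, TransposaseProtein] = {}
    for i in range(n):
        L = lengths[i % len(lengths)] + (30 * (i // len(lengths)))
        seq = "".join(rng.choice(list(_AA_ALPHABET), size=L))
        pid = f"TNP_{i + 1:03d}"
        out[pid] = TransposaseProtein(pid, seq)
    return out


def simulate_genome(genome_id: str,
                    specs_by_contig: Mapping[str, Sequence[PlantSpec]],
                    contig_lengths: Mapping[str, int],
                    proteins: Optional[Mapping[str, TransposaseProtein]] = None,
                    gc: float = DEFAULT_GC,
                    seed: int = 0,
                    group: Optional[str] = None,
                    ) -> tuple[GenomeRecord, list[TruthRecord], list[TransposaseHit]]:
    """Build a whole synthetic genome plus its truth and ideal hit table."""
    if proteins is None:
        proteins = bundled_transposase_proteins()
    rng = np.random.default_rng(seed)
    contigs: dict[str, str] = {}
    truths: list[TruthRecord] = []
    for contig_id in sorted(contig_lengths):
        bg = generate_background(contig_lengths[contig_id], gc, rng)
        specs = list(specs_by_contig.get(contig_id, ()))
        seq, t = plant_elements(bg, specs, proteins, rng, gc)
        contigs[contig_id] = seq
        truths.extend(t)
    genome = GenomeRecord(genome_id=genome_id, contigs=contigs, group=group)
    return genome, truths, ideal_hits(truths, proteins)
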