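"""Readers and writers for the external formats the pipeline touches.

Formats handled here: FASTA (nucleotide and amino acid), the 12-column
tab-separated hit table produced by translated homology searches
(query, subject, %identity, length, mismatches, gapopens, qstart, qend,
sstart, send, evalue, bitscore), GFF3 annotation output, and the TSV
genome-metadata table.

Coordinate convention: every interval in this package is 1-based and
inclusive on both ends, matching the tabular search output; GFF3 uses the
same convention so no conversion happens at output time.  Strand is derived
solely from the orientation of qstart/qend in hit tables (a translated
search reports minus-strand hits with qstart > qend); after normalisation
qstart <= qend always holds and the strand field carries the orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_NT_ALLOWED = set("ACGTN")

HIT_TABLE_COLUMNS = [
    "query", "subject", "identity_pct", "length", "mismatches", "gapopens",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass
class GenomeRecord:
    """A named set of nucleotide contigs plus grouping metadata.

    ``size_mb`` is the externally reported assembly size in Mb; for
    metadata-only records (no contigs) it is the only size available and is
    the denominator of density statistics.  When contigs are present,
    ``total_length`` is their summed length in bp.
    """

    genome_id: str
    contigs: dict[str, str] = field(default_factory=dict)
    group: Optional[str] = None
    assembly_status: str = "draft"
    size_mb: Optional[float] = None

    def __post_init__(self) -> None:
        if self.assembly_status not in ("draft", "complete"):
            raise ValueError(
                f"assembly_status must be 'draft' or 'complete', got {self.assembly_status!r}"
            )

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def effective_size_mb(self) -> float:
        """Assembly size in Mb used for density normalisation.

        The reported size (Table-style metadata) wins over the contig sum
        when both exist; a discrepancy of >= 1% between the two is logged.
        """
        contig_mb = self.total_length / 1e6 if self.contigs else None
        if self.size_mb is not None:
            if contig_mb and abs(contig_mb - self.size_mb) / self.size_mb >= 0.01:
                logger.warning(
                    "genome %s: reported size %.3f Mb differs from contig sum %.3f Mb",
                    self.genome_id, self.size_mb, contig_mb,
                )
            return self.size_mb
        if contig_mb is None:
            raise ValueError(f"genome {self.genome_id} has neither contigs nor size_mb")
        return contig_mb


@dataclass(frozen=True)
class TransposaseProtein:
    """One database transposase; nt_length is the coding length (no stop)."""

    protein_id: str
    sequence: str

    @property
    def aa_length(self) -> int:
        return len(self.sequence)

    @property
    def nt_length(self) -> int:
        return 3 * len(self.sequence)


@dataclass
class TransposaseHit:
    """One local alignment between a contig interval and a transposase.

    Coordinates are 1-based inclusive with qstart <= qend and
    sstart <= send; strand records which genome strand encodes the match.
    """

    contig_id: str
    qstart: int
    qend: int
    strand: str
    protein_id: str
    sstart: int
    send: int
    evalue: float
    bitscore: float
    identity_pct: float = 100.0

    def __post_init__(self) -> None:
        if not (1 <= self.qstart <= self.qend):
            raise ValueError(f"bad query interval [{self.qstart},{self.qend}]")
        if not (1 <= self.sstart <= self.send):
            raise ValueError(f"bad subject interval [{self.sstart},{self.send}]")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        nt_span = self.qend - self.qstart + 1
        aa_span = self.send - self.sstart + 1
        if nt_span > 3 * aa_span + 60:  # generous gap allowance; warn only
            logger.warning(
                "hit %s:%d-%d spans %d nt but only %d aa on %s",
                self.contig_id, self.qstart, self.qend, nt_span, aa_span,
                self.protein_id,
            )

    @property
    def nt_span(self) -> int:
        return self.qend - self.qstart + 1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: str = "nt",
               strip_trailing_stop: bool = True) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence map.

    Ids are the first whitespace-delimited header token.  Sequences are
    uppercased.  For ``alphabet="nt"`` any character outside A/C/G/T/N is
    replaced by N (count logged).  For ``alphabet="aa"`` a single trailing
    ``*`` is stripped by default so lengths are coding lengths.
    """
    if alphabet not in ("nt", "aa"):
        raise ValueError(f"alphabet must be 'nt' or 'aa', got {alphabet!r}")
    out: dict[str, str] = {}
    n_replaced = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty record {rec.id!r}")
        if rec.id in out:
            raise FormatError(f"{path}: duplicate id {rec.id!r}")
        if alphabet == "nt":
            bad = [c for c in seq if c not in _NT_ALLOWED]
            if bad:
                n_replaced += len(bad)
                seq = "".join(c if c in _NT_ALLOWED else "N" for c in seq)
        else:
            if strip_trailing_stop and seq.endswith("*"):
                seq = seq[:-1]
            if not seq:
                raise FormatError(f"{path}: record {rec.id!r} is only a stop codon")
        out[rec.id] = seq
    if not out:
        raise FormatError(f"{path}: no FASTA records")
    if n_replaced:
        logger.info("%s: replaced %d non-ACGTN characters with N", path, n_replaced)
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_proteins(path: str | Path) -> dict[str, TransposaseProtein]:
    """Read an amino-acid FASTA into a protein_id -> TransposaseProtein map."""
    return {
        pid: TransposaseProtein(pid, seq)
        for pid, seq in read_fasta(path, alphabet="aa").items()
    }


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------

def normalize_hit_row(qstart: int, qend: int) -> tuple[int, int, str]:
    """Map raw query coordinates to (qstart<=qend, strand).

    Idempotent: already-normalised coordinates keep strand '+'.
    """
    if qstart > qend:
        return qend, qstart, "-"
    return qstart, qend, "+"


def read_hit_table(path: str | Path) -> list[TransposaseHit]:
    """Parse a 12-column tab-separated translated-search hit table.

    Rows with qstart > qend are normalised to qstart <= qend with strand
    '-'; '#' comment lines are skipped.  Coordinate parse failures raise
    FormatError naming the offending line.
    """
    hits: list[TransposaseHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"{path}:{lineno}: expected >=12 tab-separated fields, got {len(fields)}"
                )
            try:
                qs, qe = int(fields[6]), int(fields[7])
                ss, se = int(fields[8]), int(fields[9])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric coordinate") from exc
            try:
                ident = float(fields[2])
                evalue = float(fields[10])
                bits = float(fields[11])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric score field") from exc
            qs, qe, strand = normalize_hit_row(qs, qe)
            if ss > se:
                ss, se = se, ss
            hits.append(TransposaseHit(
                contig_id=fields[0], qstart=qs, qend=qe, strand=strand,
                protein_id=fields[1], sstart=ss, send=se,
                evalue=evalue, bitscore=bits, identity_pct=ident,
            ))
    return hits


def write_hit_table(hits: Iterable[TransposaseHit], path: str | Path) -> None:
    """Write hits back in the 12-column dialect (minus strand: qstart>qend)."""
    with open(path, "w") as fh:
        for h in hits:
            qs, qe = (h.qstart, h.qend) if h.strand == "+" else (h.qend, h.qstart)
            aa_span = h.send - h.sstart + 1
            mism = int(round(aa_span * (1.0 - h.identity_pct / 100.0)))
            fh.write("\t".join(str(x) for x in (
                h.contig_id, h.protein_id, f"{h.identity_pct:.2f}", aa_span,
                mism, 0, qs, qe, h.sstart, h.send,
                f"{h.evalue:.3g}", f"{h.bitscore:.1f}",
            )) + "\n")


# ---------------------------------------------------------------------------
# metadata table
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the genome metadata TSV (genome_id, group, assembly_status, size_mb)."""
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "group": str,
                                            "assembly_status": str})
    required = {"genome_id", "group", "assembly_status", "size_mb"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing metadata columns {sorted(missing)}")
    if df["genome_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate genome_id")
    df["size_mb"] = pd.to_numeric(df["size_mb"], errors="coerce")
    return df


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _gff_escape(v: str) -> str:
    return (str(v).replace("%", "%25").replace(";", "%3B")
            .replace("=", "%3D").replace(",", "%2C").replace("\t", "%09"))


def write_gff3(units: Sequence, repeats: Sequence, path: str | Path,
               contig_lengths: Optional[Mapping[str, int]] = None,
               source: str = "tnfoot") -> None:
    """Write transposase units and inverted-repeat pairs as GFF3.

    One ``mobile_element`` feature per unit (attributes: protein id(s),
    fraction, joined flag, fragment coordinates) and two ``inverted_repeat``
    features per pair sharing one ID (the GFF3 discontinuous-feature
    convention).  Output is ordered by (contig, start, end) so it is
    invariant to input ordering.
    """
    rows: list[tuple[str, int, int, str]] = []

    def _check_contig(cid: str, end: int) -> None:
        if contig_lengths is not None:
            if cid not in contig_lengths:
                raise ValueError(f"unknown contig {cid!r} in GFF3 output")
            if end > contig_lengths[cid]:
                raise ValueError(f"feature end {end} beyond contig {cid!r}")

    for i, u in enumerate(sorted(units, key=lambda u: (u.contig_id, u.start, u.end))):
        _check_contig(u.contig_id, u.end)
        frags = ",".join(f"{f.start}-{f.end}/{f.sstart}-{f.send}" for f in u.fragments)
        attrs = (
            f"ID=te{i + 1:05d};protein_id={_gff_escape('|'.join(u.protein_ids))};"
            f"fraction={u.fraction:.4f};joined={'true' if u.joined else 'false'};"
            f"fragments={frags}"
        )
        rows.append((u.contig_id, u.start, u.end,
                     f"{u.contig_id}\t{source}\tmobile_element\t{u.start}\t{u.end}"
                     f"\t{u.fraction:.4f}\t{u.strand}\t.\t{attrs}"))
    for i, r in enumerate(sorted(repeats, key=lambda r: (r.contig_id, r.arm1_start,
                                                         r.arm2_start))):
        _check_contig(r.contig_id, r.arm2_end)
        rid = f"ir{i + 1:05d}"
        for a_start, a_end in ((r.arm1_start, r.arm1_end), (r.arm2_start, r.arm2_end)):
            rows.append((r.contig_id, a_start, a_end,
                         f"{r.contig_id}\t{source}\tinverted_repeat\t{a_start}\t{a_end}"
                         f"\t{r.identity:.3f}\t+\t.\tID={rid};"
                         f"distance={r.distance};arm_length={r.arm_length}"))
    rows.sort(key=lambda t: (t[0], t[1], t[2]))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, _, _, line in rows:
            fh.write(line + "\n")


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read a GFF3 file written by :func:`write_gff3` into a DataFrame.

    Intended for round-trip checks and downstream tabulation, not as a
    general-purpose GFF3 parser.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise FormatError(f"{path}: malformed GFF3 line: {line!r}")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            rows.append({
                "contig_id": f[0], "source": f[1], "type": f[2],
                "start": int(f[3]), "end": int(f[4]),
                "score": None if f[5] == "." else float(f[5]),
                "strand": f[6], "attributes": attrs,
            })
    return pd.DataFrame(rows)


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N (or IUPAC) nucleotide string."""
    return str(Seq(seq).reverse_complement())
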