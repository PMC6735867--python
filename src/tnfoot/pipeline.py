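"""Config-driven orchestration of the annotation stages.

One :class:`RunConfig` drives, per genome: hit acquisition (external table
or built-in search) -> e-value filter -> footprints -> greedy assignment ->
fragment joining -> fractions -> GFF3 + TSV output; then densities, the
draft-group comparison and the genome-size summary across genomes.  A JSON
manifest records inputs, parameters, per-stage counts, output checksums and
collected warnings; runs are deterministic for fixed inputs and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io as tio
from .footprints import (JoinCriteria, assign_transposases, build_footprints,
                         filter_hits, join_fragments)
from .repeats import RepeatParams, find_inverted_repeats
from .search import AlignmentParams, search_genome
from .simulate import bundled_transposase_proteins
from .stats import DensityRecord, compare_groups, summarize_sizes

logger = logging.getLogger(__name__)


@dataclass
class Finding:
    severity: str  # "error" | "warning"
    message: str


@dataclass
class RunConfig:
    """Validated inputs and parameters of one pipeline run."""

    genomes: list[str] = field(default_factory=list)
    metadata: Optional[str] = None
    proteins: Optional[str] = None        # aa FASTA; None -> bundled synthetic set
    hit_tables: dict[str, str] = field(default_factory=dict)  # genome_id -> path
    builtin_search: bool = False
    evalue_cutoff: float = 1e-4
    min_remainder: int = 30
    min_fraction: float = 0.0
    join: JoinCriteria = field(default_factory=JoinCriteria)
    repeat_params: RepeatParams = field(default_factory=RepeatParams)
    find_repeats: bool = False
    outdir: str = "tnfoot_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        join = JoinCriteria(**raw.pop("join", {}))
        rep = RepeatParams(**raw.pop("repeat_params", {}))
        return cls(join=join, repeat_params=rep, **raw)


def validate(config: RunConfig) -> list[Finding]:
    """Static checks; returns findings instead of raising."""
    findings: list[Finding] = []
    if not config.genomes:
        findings.append(Finding("error", "no genome FASTA files configured"))
    for g in config.genomes:
        if not Path(g).exists():
            findings.append(Finding("error", f"genome FASTA missing: {g}"))
    if config.metadata is not None and not Path(config.metadata).exists():
        findings.append(Finding("error", f"metadata table missing: {config.metadata}"))
    if config.proteins is not None and not Path(config.proteins).exists():
        findings.append(Finding("error", f"protein FASTA missing: {config.proteins}"))
    for gid, p in config.hit_tables.items():
        if not Path(p).exists():
            findings.append(Finding("error", f"hit table missing for {gid}: {p}"))
    if config.evalue_cutoff <= 0:
        findings.append(Finding("error", "evalue_cutoff must be > 0"))
    if config.min_remainder < 0:
        findings.append(Finding("error", "min_remainder must be >= 0"))
    try:
        JoinCriteria(**dataclasses.asdict(config.join))
    except ValueError as exc:
        findings.append(Finding("error", f"join criteria: {exc}"))
    genome_ids = {Path(g).stem for g in config.genomes}
    if not config.builtin_search:
        for gid in genome_ids - set(config.hit_tables):
            findings.append(Finding(
                "warning",
                f"genome {gid} has no hit table and builtin search is off"))
    if config.metadata is not None and Path(config.metadata).exists():
        try:
            meta = tio.read_metadata(config.metadata)
        except Exception as exc:  # malformed table
            findings.append(Finding("error", f"metadata unreadable: {exc}"))
        else:
            for gid in set(meta["genome_id"]) - genome_ids:
                findings.append(Finding(
                    "warning", f"metadata genome {gid} absent from FASTA set"))
            for gid in genome_ids - set(meta["genome_id"]):
                findings.append(Finding(
                    "warning", f"genome {gid} has no metadata row"))
    return findings


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns (and writes) the run manifest."""
    errors = [f for f in validate(config) if f.severity == "error"]
    if errors:
        raise ValueError("configuration errors: " +
                         "; ".join(f.message for f in errors))

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    proteins = (tio.read_proteins(config.proteins) if config.proteins
                else bundled_transposase_proteins())
    meta = tio.read_metadata(config.metadata) if config.metadata else None
    meta_by_id = ({str(r["genome_id"]): r for _, r in meta.iterrows()}
                  if meta is not None else {})

    manifest: dict = {
        "parameters": {
            "evalue_cutoff": config.evalue_cutoff,
            "min_remainder": config.min_remainder,
            "min_fraction": config.min_fraction,
            "join": dataclasses.asdict(config.join),
            "repeat_params": dataclasses.asdict(config.repeat_params),
            "builtin_search": config.builtin_search,
            "seed": config.seed,
        },
        "genomes": {}, "outputs": {}, "warnings": [],
    }

    report_rows = []
    density_records: list[DensityRecord] = []

    for gpath in sorted(config.genomes):
        gid = Path(gpath).stem
        contigs = tio.read_fasta(gpath, alphabet="nt")
        row = meta_by_id.get(gid)
        size_mb = None
        group = None
        status = "draft"
        if row is not None:
            group = None if pd.isna(row.get("group")) else str(row["group"])
            status = str(row.get("assembly_status", "draft"))
            if not pd.isna(row.get("size_mb")):
                size_mb = float(row["size_mb"])
        genome = tio.GenomeRecord(genome_id=gid, contigs=contigs, group=group,
                                  assembly_status=status, size_mb=size_mb)

        if gid in config.hit_tables:
            hits = tio.read_hit_table(config.hit_tables[gid])
        elif config.builtin_search:
            hits = search_genome(genome, proteins, AlignmentParams())
        else:
            manifest["warnings"].append(f"{gid}: no hit source; skipped")
            continue

        retained = filter_hits(hits, config.evalue_cutoff)
        footprints = build_footprints(retained)
        segments = []
        for fp in footprints:
            segments.extend(assign_transposases(fp, config.min_remainder))
        units = join_fragments(segments, config.join, proteins=proteins)
        if config.min_fraction > 0:
            units = [u for u in units if u.fraction >= config.min_fraction]
        units.sort(key=lambda u: (u.contig_id, u.start))
        for u in units:
            if u.fraction > 1.0:
                manifest["warnings"].append(
                    f"{gid}:{u.contig_id}:{u.start}-{u.end} fraction "
                    f"{u.fraction:.3f} > 1")

        repeats = []
        if config.find_repeats:
            for cid in sorted(contigs):
                repeats.extend(find_inverted_repeats(
                    contigs[cid], config.repeat_params, contig_id=cid))

        gff_path = outdir / f"{gid}.gff3"
        contig_lengths = {cid: len(s) for cid, s in contigs.items()}
        tio.write_gff3(units, repeats, gff_path, contig_lengths=contig_lengths)

        eff_size = genome.effective_size_mb()
        fractions = sorted(u.fraction for u in units)
        quantiles = (pd.Series(fractions).quantile([0.25, 0.5, 0.75]).tolist()
                     if fractions else [float("nan")] * 3)
        n_joined = sum(1 for u in units if u.joined)
        report_rows.append({
            "genome_id": gid, "group": group, "assembly_status": status,
            "n_units": len(units), "n_joined": n_joined,
            "total_length": genome.total_length,
            "size_mb": round(eff_size, 3),
            "units_per_mbp": round(len(units) / eff_size, 3),
            "fraction_q25": round(quantiles[0], 3),
            "fraction_median": round(quantiles[1], 3),
            "fraction_q75": round(quantiles[2], 3),
            "n_inverted_repeats": len(repeats),
        })
        density_records.append(DensityRecord(
            genome_id=gid, group=group, assembly_status=status,
            n_units=len(units), size_mb=eff_size))
        manifest["genomes"][gid] = {
            "n_hits": len(hits), "n_retained": len(retained),
            "n_footprints": len(footprints), "n_segments": len(segments),
            "n_units": len(units), "n_joined": n_joined,
            "n_inverted_repeats": len(repeats),
        }
        manifest["outputs"][str(gff_path)] = _sha256(gff_path)

    report_path = outdir / "report.tsv"
    pd.DataFrame(report_rows).to_csv(report_path, sep="\t", index=False)
    manifest["outputs"][str(report_path)] = _sha256(report_path)

    groups = sorted({r.group for r in density_records
                     if r.group is not None and r.assembly_status == "draft"})
    if len(groups) == 2:
        test = compare_groups(density_records, groups[0], groups[1])
        manifest["group_comparison"] = {
            "groups": groups, "n1": test.n1, "n2": test.n2, "U": test.U,
            "p_two_sided": test.p_two_sided, "method": test.method,
        }
    sizes = [r.size_mb for r in density_records]
    if len(sizes) >= 2:
        s = summarize_sizes(sizes)
        manifest["size_summary_mb"] = {"n": s.n, "mean": s.mean, "sd": s.sd}

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
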