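"""Bundled reference tables.

The package ships the published metadata of the *Frankia* cluster-2
(meta-)genome panel: genome identifiers, geographic grouping (Eurasian,
North American, Southern hemisphere), assembly status, reported assembly
size in Mb, GC content and the number of major strains per (meta-)genome.
Sequence data and per-genome transposase annotations are not bundled; they
live in public repositories and the original study's supplementary data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def frankia_cluster2_metadata() -> pd.DataFrame:
    """The cluster-2 (meta-)genome metadata table."""
    ref = resources.files("tnfoot.data") / "frankia_cluster2_metadata.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    df["size_mb"] = pd.to_numeric(df["size_mb"], errors="coerce")
    df["n_major_strains"] = pd.to_numeric(df["n_major_strains"], errors="coerce")
    return df


def single_dominant_sizes(df: pd.DataFrame | None = None) -> list[float]:
    """Assembly sizes (Mb) of the (meta-)genomes with one dominant strain.

    These nine values underlie the headline genome-size summary of the
    cluster-2 panel.
    """
    if df is None:
        df = frankia_cluster2_metadata()
    sel = df[(df["n_major_strains"] == 1) & df["size_mb"].notna()]
    return sel["size_mb"].tolist()
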