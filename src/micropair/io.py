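"""Readers and writers for the plain-text input dialects.

All inputs are delimited text: abundance tables with a sample-ID first
column and taxon-ID header (a transposed taxa × samples dialect is
accepted via a flag), a lineage table, a two-column genome-length table,
sample metadata with a ``diagnosis`` column, and a three-column synonym
map (``rank, old_name, canonical_name``).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import RANKS, AbundanceTable, Lineage, PairedStudy
from .taxonomy import SynonymMap


def _read_delimited(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, comment="#")


def read_lineage_table(path: str | Path) -> dict[str, Lineage]:
    """Read ``taxon_id, phylum, …, species, named`` into Lineage objects."""
    df = _read_delimited(path)
    required = {"taxon_id", "named"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"lineage table missing columns: {sorted(missing)}")
    lineages = {}
    for _, row in df.iterrows():
        ranks = {r: str(row[r]) for r in RANKS
                 if r in df.columns and pd.notna(row[r]) and str(row[r]) != ""}
        named = str(row["named"]).strip().lower() in ("true", "1", "yes")
        lineages[str(row["taxon_id"])] = Lineage(ranks=ranks, named=named)
    return lineages


def read_abundance_table(
    path: str | Path,
    lineages: dict[str, Lineage],
    platform: str,
    genome_lengths: pd.Series | None = None,
    transposed: bool = False,
) -> AbundanceTable:
    """Read a counts table (samples × taxa; or taxa × samples if flagged)."""
    df = _read_delimited(path)
    df = df.set_index(df.columns[0])
    if transposed:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    known = [t for t in df.columns if t in lineages]
    unknown = sorted(set(df.columns) - set(known))
    if unknown:
        raise ValueError(f"taxa absent from the lineage table: {unknown[:5]}")
    lin = {t: lineages[t] for t in df.columns}
    if genome_lengths is not None:
        genome_lengths = genome_lengths.reindex(df.columns)
    return AbundanceTable(counts=df, lineages=lin, platform=platform,
                          genome_lengths=genome_lengths)


def read_genome_lengths(path: str | Path) -> pd.Series:
    df = _read_delimited(path)
    if df.shape[1] < 2:
        raise ValueError("genome-length table needs taxon_id and length_bp columns")
    s = df.set_index(df.columns[0]).iloc[:, 0].astype(float)
    s.index = s.index.astype(str)
    return s


def read_metadata(path: str | Path) -> pd.Series:
    df = _read_delimited(path)
    if "diagnosis" not in df.columns:
        raise ValueError("metadata table must contain a 'diagnosis' column")
    s = df.set_index(df.columns[0])["diagnosis"].astype(str)
    s.index = s.index.astype(str)
    return s


def read_synonym_map(path: str | Path) -> SynonymMap:
    """Read ``rank, old_name, canonical_name`` rows into a SynonymMap."""
    df = _read_delimited(path)
    needed = {"rank", "old_name", "canonical_name"}
    if not needed.issubset(df.columns):
        raise ValueError(f"synonym map needs columns {sorted(needed)}")
    entries: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        entries.setdefault(str(row["rank"]), {})[str(row["old_name"])] = \
            str(row["canonical_name"])
    return SynonymMap(entries=entries)


def load_study(
    shotgun_path: str | Path,
    amplicon_path: str | Path,
    lineage_path: str | Path,
    metadata_path: str | Path,
    genome_lengths_path: str | Path | None = None,
    transposed: bool = False,
) -> PairedStudy:
    """Assemble a PairedStudy from its on-disk parts."""
    lineages = read_lineage_table(lineage_path)
    lengths = read_genome_lengths(genome_lengths_path) if genome_lengths_path else None
    shotgun = read_abundance_table(shotgun_path, lineages, "shotgun",
                                   genome_lengths=lengths, transposed=transposed)
    amplicon = read_abundance_table(amplicon_path, lineages, "16S",
                                    transposed=transposed)
    diagnosis = read_metadata(metadata_path)
    return PairedStudy(shotgun=shotgun, amplicon=amplicon, diagnosis=diagnosis)
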