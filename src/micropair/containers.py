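"""Core data containers for paired-platform microbiome studies.

A study consists of two sample-matched abundance tables — one from shotgun
metagenomic sequencing and one from 16S rRNA amplicon sequencing — plus a
taxonomic lineage for every taxon and a three-level diagnosis label
(control / HRL / CRC) per sample.  Counts are held as a pandas DataFrame
with samples as rows and taxa as columns; taxon column labels double as
taxon identifiers and are keys into the lineage mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Taxonomic ranks from shallowest to deepest.
RANKS: tuple[str, ...] = ("phylum", "class", "order", "family", "genus", "species")

#: Diagnosis classes, ordered along the adenoma–carcinoma continuum.
DIAGNOSIS_CLASSES: tuple[str, ...] = ("control", "HRL", "CRC")

#: Accession-code prefixes marking taxa with no proper Linnaean name.
DEFAULT_UNNAMED_PREFIXES: tuple[str, ...] = ("MGYG",)


@dataclass(frozen=True)
class Lineage:
    """Ordered rank→name assignment for one taxon.

    ``ranks`` maps rank names (a subset of :data:`RANKS`) to taxon names;
    missing ranks are only allowed below the deepest assigned rank.  A 16S
    species that could not be resolved to a single candidate carries a
    slash-joined name such as ``"Blautia obeum/wexlerae"`` whose parts are
    alphabetically sorted; :attr:`candidates` expands it to the full
    candidate species names.  ``named`` is False when the identifier is only
    a database accession code (e.g. UHGG ``MGYG…`` genomes).
    """

    ranks: Mapping[str, str]
    named: bool = True

    def __post_init__(self) -> None:
        seen_missing = False
        for rank in RANKS:
            name = self.ranks.get(rank)
            if name is None or name == "":
                seen_missing = True
            elif seen_missing:
                raise ValueError(
                    f"rank {rank!r} assigned below a missing rank: {dict(self.ranks)}"
                )
        object.__setattr__(self, "ranks", dict(self.ranks))

    @property
    def deepest_rank(self) -> str:
        for rank in reversed(RANKS):
            if self.ranks.get(rank):
                return rank
        raise ValueError("lineage has no assigned ranks")

    @property
    def name(self) -> str:
        """Name at the deepest assigned rank (the taxon identifier)."""
        return self.ranks[self.deepest_rank]

    def name_at(self, rank: str) -> str | None:
        return self.ranks.get(rank) or None

    @property
    def is_ambiguous(self) -> bool:
        species = self.ranks.get("species")
        return bool(species) and "/" in species

    @property
    def candidates(self) -> tuple[str, ...]:
        """Candidate species names (full binomials), alphabetically sorted.

        ``"Blautia obeum/wexlerae"`` → ``("Blautia obeum", "Blautia wexlerae")``.
        """
        species = self.ranks.get("species")
        if not species:
            return ()
        genus, _, epithets = species.partition(" ")
        if not epithets:
            return (species,)
        return tuple(f"{genus} {ep}" for ep in sorted(epithets.split("/")))

    def truncated(self, rank: str) -> "Lineage":
        """Lineage cut down to ``rank`` (dropping deeper assignments)."""
        idx = RANKS.index(rank)
        kept = {r: n for r, n in self.ranks.items() if RANKS.index(r) <= idx and n}
        return Lineage(ranks=kept, named=self.named)


def make_species_name(genus: str, epithets: Sequence[str]) -> str:
    """Compose a (possibly slash-ambiguous) species name from epithets."""
    return f"{genus} {'/'.join(sorted(set(epithets)))}"


@dataclass
class AbundanceTable:
    """Samples × taxa abundance matrix for one sequencing platform.

    Parameters
    ----------
    counts
        Non-negative matrix; rows are samples, columns are taxa.  Integer
        read counts upstream of normalisation, reals afterwards.
    lineages
        Mapping from column label to :class:`Lineage`.
    platform
        ``"shotgun"`` or ``"16S"``.
    genome_lengths
        Optional per-taxon genome length in bases (shotgun only).
    """

    counts: pd.DataFrame
    lineages: dict[str, Lineage]
    platform: str
    genome_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative abundance entries")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate taxon identifiers")
        missing = [t for t in self.counts.columns if t not in self.lineages]
        if missing:
            raise ValueError(f"taxa without lineage: {missing[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def lineage_of(self, taxon: str) -> Lineage:
        return self.lineages[taxon]

    def with_counts(self, counts: pd.DataFrame) -> "AbundanceTable":
        """Same metadata, new count matrix restricted to shared columns."""
        lineages = {t: self.lineages[t] for t in counts.columns}
        lengths = None
        if self.genome_lengths is not None:
            lengths = self.genome_lengths.reindex(counts.columns)
        return AbundanceTable(
            counts=counts, lineages=lineages, platform=self.platform,
            genome_lengths=lengths,
        )

    def subset_taxa(self, taxa: Sequence[str]) -> "AbundanceTable":
        return self.with_counts(self.counts.loc[:, list(taxa)])

    def subset_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        sub = self.counts.loc[list(sample_ids)]
        return self.with_counts(sub)

    def detected_taxa(self) -> set[str]:
        """Taxa with a non-zero raw count in at least one sample."""
        nz = (self.counts > 0).any(axis=0)
        return set(nz.index[nz])


@dataclass
class PairedStudy:
    """Two sample-matched abundance tables plus diagnosis labels."""

    shotgun: AbundanceTable
    amplicon: AbundanceTable
    diagnosis: pd.Series  # sample_id -> label in DIAGNOSIS_CLASSES

    def __post_init__(self) -> None:
        sg = set(self.shotgun.sample_ids)
        am = set(self.amplicon.sample_ids)
        if sg != am:
            odd = sorted(sg.symmetric_difference(am))
            raise ValueError(f"sample mismatch between platforms: {odd[:10]}")
        md = set(self.diagnosis.index)
        if md != sg:
            odd = sorted(md.symmetric_difference(sg))
            raise ValueError(f"sample mismatch with metadata: {odd[:10]}")
        bad = sorted(set(self.diagnosis) - set(DIAGNOSIS_CLASSES))
        if bad:
            raise ValueError(f"unknown diagnosis labels: {bad}")
        # keep a consistent sample order across all three members
        order = list(self.shotgun.counts.index)
        self.amplicon = self.amplicon.subset_samples(order)
        self.diagnosis = self.diagnosis.loc[order]

    @property
    def sample_ids(self) -> list[str]:
        return self.shotgun.sample_ids

    def map_tables(self, fn) -> "PairedStudy":
        """Apply ``fn`` to both tables, keeping labels."""
        return PairedStudy(
            shotgun=fn(self.shotgun),
            amplicon=fn(self.amplicon),
            diagnosis=self.diagnosis,
        )
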