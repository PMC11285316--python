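"""Cross-platform taxonomy harmonisation.

16S (SILVA-derived) and shotgun (UHGG-derived) profiles name the same
organisms inconsistently: outdated synonyms, multi-candidate slash species
on the 16S side, and accession-code-only taxa on both sides.  This module
normalises names through user-supplied synonym maps, rolls counts up to a
chosen rank, merges transitively-overlapping ambiguous species sets, and
drops unnamed taxa prior to overlap accounting.  Every operation conserves
per-sample totals exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .containers import (
    RANKS,
    DEFAULT_UNNAMED_PREFIXES,
    AbundanceTable,
    Lineage,
    make_species_name,
)


@dataclass
class SynonymMap:
    """Per-rank old-name → canonical-name replacement table.

    The mapping must be idempotent: one application reaches a fixed point
    (canonical names map to themselves or are absent).  Chains or cycles
    (``A→B`` with ``B→C``) are rejected at construction.
    """

    entries: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rank, mapping in self.entries.items():
            if rank not in RANKS:
                raise ValueError(f"unknown rank {rank!r}")
            for old, canon in mapping.items():
                nxt = mapping.get(canon, canon)
                if nxt != canon:
                    raise ValueError(
                        f"synonym map not idempotent at rank {rank!r}: "
                        f"{old!r} → {canon!r} → {nxt!r}"
                    )

    def resolve(self, rank: str, name: str) -> str:
        return self.entries.get(rank, {}).get(name, name)

    def apply(self, lineage: Lineage) -> Lineage:
        new = {r: self.resolve(r, n) for r, n in lineage.ranks.items()}
        return Lineage(ranks=new, named=lineage.named)


def _merge_identical_lineages(
    counts: pd.DataFrame, lineages: dict[str, Lineage]
) -> tuple[pd.DataFrame, dict[str, Lineage]]:
    """Sum columns whose lineages are identical; relabel by deepest name."""
    key_of: dict[str, tuple] = {
        t: tuple(lin.ranks.get(r, "") for r in RANKS) + (lin.named,)
        for t, lin in lineages.items()
    }
    groups: dict[tuple, list[str]] = {}
    for t in counts.columns:
        groups.setdefault(key_of[t], []).append(t)

    out_cols, out_lineages = {}, {}
    for key, members in groups.items():
        lin = lineages[members[0]]
        label = lin.name
        if label in out_lineages:  # same deepest name, different upper ranks
            raise ValueError(f"conflicting lineages for taxon name {label!r}")
        out_cols[label] = counts[members].sum(axis=1)
        out_lineages[label] = lin
    merged = pd.DataFrame(out_cols, index=counts.index)
    return merged, out_lineages


def normalize_names(table: AbundanceTable, synonyms: SynonymMap) -> AbundanceTable:
    """Replace taxon names by canonical forms and merge resulting duplicates.

    Taxa whose canonical lineages become identical are summed column-wise;
    per-sample totals are conserved exactly.
    """
    new_lineages = {t: synonyms.apply(lin) for t, lin in table.lineages.items()}
    relevant = {t: new_lineages[t] for t in table.counts.columns}
    merged, out_lineages = _merge_identical_lineages(table.counts, relevant)

    lengths = None
    if table.genome_lengths is not None:
        # genome length of a merged taxon: count-weighted harmonic mean would
        # over-engineer; taxa merged by synonymy are the same organism, so
        # take the first member's length.
        length_of = {}
        for label, lin in out_lineages.items():
            for t, l2 in relevant.items():
                if l2.ranks == lin.ranks:
                    length_of[label] = table.genome_lengths[t]
                    break
        lengths = pd.Series(length_of).reindex(merged.columns)

    return AbundanceTable(
        counts=merged, lineages=out_lineages, platform=table.platform,
        genome_lengths=lengths,
    )


def unassigned_bucket(rank: str) -> str:
    """Label of the bucket collecting taxa that lack ``rank``."""
    return f"unassigned@{rank}"


def aggregate_rank(table: AbundanceTable, rank: str) -> AbundanceTable:
    """Roll counts up to ``rank``, summing columns sharing the rank's name.

    Taxa lacking the requested rank go to an explicit ``unassigned@rank``
    bucket which is flagged unnamed (so that overlap accounting, which runs
    on named taxa only, skips it) but keeps the composition closed.
    Per-sample totals are conserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    if rank == "species":
        return table

    bucket = unassigned_bucket(rank)
    out_cols: dict[str, pd.Series] = {}
    out_lineages: dict[str, Lineage] = {}
    for taxon in table.counts.columns:
        lin = table.lineages[taxon]
        name = lin.name_at(rank)
        if name is None:
            label = bucket
            new_lin = Lineage(ranks={RANKS[0]: bucket} if rank == RANKS[0] else
                              {r: lin.ranks.get(r, bucket) or bucket
                               for r in RANKS[: RANKS.index(rank) + 1]},
                              named=False)
        else:
            label = name
            new_lin = lin.truncated(rank)
        if label in out_cols:
            out_cols[label] = out_cols[label] + table.counts[taxon]
        else:
            out_cols[label] = table.counts[taxon].copy()
            out_lineages[label] = new_lin

    counts = pd.DataFrame(out_cols, index=table.counts.index)
    return AbundanceTable(counts=counts, lineages=out_lineages,
                          platform=table.platform, genome_lengths=None)


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def merge_ambiguous(table: AbundanceTable) -> AbundanceTable:
    """Merge 16S taxa whose candidate-species sets intersect.

    Overlap is taken transitively (union–find over shared candidates), so a
    chain ``A/B``, ``B/C``, ``C/D`` collapses to a single ``A/B/C/D`` taxon.
    The merged taxon is named by the alphabetically sorted candidate union;
    counts are summed.  Idempotent, and conserves per-sample totals.
    """
    uf = _UnionFind()
    owner: dict[str, str] = {}  # candidate species name -> representative taxon
    for taxon in table.counts.columns:
        lin = table.lineages[taxon]
        if not lin.ranks.get("species"):
            continue
        for cand in lin.candidates:
            if cand in owner:
                uf.union(owner[cand], taxon)
            else:
                owner[cand] = taxon
                uf.union(taxon, taxon)

    groups: dict[str, list[str]] = {}
    for taxon in table.counts.columns:
        lin = table.lineages[taxon]
        root = uf.find(taxon) if lin.ranks.get("species") else taxon
        groups.setdefault(root, []).append(taxon)

    out_cols, out_lineages = {}, {}
    for root, members in groups.items():
        if len(members) == 1:
            t = members[0]
            out_cols[t] = table.counts[t]
            out_lineages[t] = table.lineages[t]
            continue
        lins = [table.lineages[t] for t in members]
        genera = {l.ranks.get("genus") for l in lins}
        if len(genera) != 1:
            raise ValueError(
                f"ambiguous species spanning genera {sorted(map(str, genera))}"
            )
        all_cands = sorted({c for l in lins for c in l.candidates})
        epithets = [c.split(" ", 1)[1] for c in all_cands]
        genus = genera.pop()
        label = make_species_name(genus or all_cands[0].split(" ")[0], epithets)
        ranks = dict(lins[0].ranks)
        ranks["species"] = label
        out_cols[label] = table.counts[members].sum(axis=1)
        out_lineages[label] = Lineage(ranks=ranks, named=all(l.named for l in lins))

    counts = pd.DataFrame(out_cols, index=table.counts.index)
    return AbundanceTable(counts=counts, lineages=out_lineages,
                          platform=table.platform, genome_lengths=None)


def flag_unnamed(
    table: AbundanceTable,
    prefixes: tuple[str, ...] = DEFAULT_UNNAMED_PREFIXES,
) -> AbundanceTable:
    """Re-derive ``named`` flags from accession-prefix patterns."""
    lineages = {}
    for t, lin in table.lineages.items():
        named = lin.named and not any(lin.name.startswith(p) for p in prefixes)
        lineages[t] = Lineage(ranks=lin.ranks, named=named)
    return AbundanceTable(counts=table.counts, lineages=lineages,
                          platform=table.platform,
                          genome_lengths=table.genome_lengths)


def exclude_unnamed(table: AbundanceTable) -> AbundanceTable:
    """Keep only taxa with a proper name (``named`` flag True)."""
    keep = [t for t in table.counts.columns if table.lineages[t].named]
    if not keep:
        warnings.warn("no named taxa remain after exclusion", stacklevel=2)
    return table.subset_taxa(keep)
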