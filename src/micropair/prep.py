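"""Compositional preprocessing of abundance tables.

Raw taxon counts are compositional: only relative information is
meaningful.  The preparation chain is genome-length normalisation (shotgun
only), a prevalence/abundance filter (keep taxa at ≥ ``min_rel_abundance``
relative abundance in ≥ ``min_sample_fraction`` of samples), Bayesian-
multiplicative zero replacement with a square-root-of-depth prior strength,
and the centred log-ratio (clr) transform

    clr(x)_j = ln( x_j / g(x) ),   g(x) = (∏_j x_j)^(1/D),

which maps each sample to an unconstrained vector summing to zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AbundanceTable


@dataclass(frozen=True)
class FilterSpec:
    """Prevalence/abundance filter thresholds.

    ``min_sample_fraction`` — fraction of samples in which a taxon must
    reach ``min_rel_abundance`` relative abundance to be retained.
    Defaults 0.05 and 0.001 (present in at least 5% of samples at 0.1%
    abundance or higher).
    """

    min_sample_fraction: float = 0.05
    min_rel_abundance: float = 0.001

    def __post_init__(self) -> None:
        for v in (self.min_sample_fraction, self.min_rel_abundance):
            if not (0.0 <= v < 1.0):
                raise ValueError("filter thresholds must lie in [0, 1)")


def genome_length_normalize(table: AbundanceTable) -> AbundanceTable:
    """Divide shotgun counts by genome length, keeping library sizes.

    Longer genomes attract proportionally more shotgun reads per cell; the
    correction divides each taxon's counts by its genome length and then
    rescales every row back to its original total, so downstream
    compositional steps see corrected proportions on a read-like scale.
    """
    if table.platform != "shotgun":
        raise ValueError("genome-length normalisation applies to shotgun tables")
    if table.genome_lengths is None:
        raise ValueError("genome lengths missing")
    lengths = table.genome_lengths.reindex(table.counts.columns)
    bad = lengths.index[lengths.isna() | (lengths <= 0)]
    if len(bad):
        raise ValueError(f"missing or non-positive genome length for {list(bad[:5])}")

    scaled = table.counts / lengths
    orig_tot = table.counts.sum(axis=1)
    new_tot = scaled.sum(axis=1)
    factor = orig_tot.divide(new_tot).where(new_tot > 0, 0.0)
    counts = scaled.mul(factor, axis=0)
    return table.with_counts(counts)


def prevalence_filter(table: AbundanceTable, spec: FilterSpec = FilterSpec()) -> AbundanceTable:
    """Drop taxa below the prevalence/abundance thresholds.

    A taxon is retained iff its within-sample relative abundance reaches
    ``spec.min_rel_abundance`` in at least ``ceil(min_sample_fraction × n)``
    samples (rounding up keeps the guarantee true for non-divisible n).
    """
    totals = table.counts.sum(axis=1)
    rel = table.counts.div(totals.where(totals > 0, np.nan), axis=0).fillna(0.0)
    need = math.ceil(spec.min_sample_fraction * table.n_samples)
    need = max(need, 1)
    hits = (rel >= spec.min_rel_abundance).sum(axis=0)
    keep = list(hits.index[hits >= need])
    if not keep:
        warnings.warn("prevalence filter removed every taxon", stacklevel=2)
    return table.subset_taxa(keep)


def replace_zeros(table: AbundanceTable, max_delta_frac: float = 0.65) -> AbundanceTable:
    """Bayesian-multiplicative zero replacement (square-root prior strength).

    For a sample with depth ``n`` over ``D`` parts, zeros are imputed at the
    posterior value under a uniform Dirichlet prior with strength ``√n``:

        p0 = (√n / (n + √n)) · (1 / D),

    additionally capped at ``max_delta_frac`` times the sample's smallest
    observed proportion so an imputed part never reaches the detection
    limit.  The non-zero parts are then rescaled multiplicatively, leaving
    all their pairwise ratios untouched and the composition closed (rows
    sum to one).
    """
    X = table.counts.to_numpy(dtype=float)
    out = np.empty_like(X)
    for i, row in enumerate(X):
        n = row.sum()
        if n <= 0:
            raise ValueError(
                f"sample {table.counts.index[i]!r} has no positive counts"
            )
        D = row.size
        pos = row > 0
        props = row / n
        if pos.all():
            out[i] = props
            continue
        s = math.sqrt(n)
        p0 = (s / (n + s)) / D
        p0 = min(p0, max_delta_frac * props[pos].min())
        n_zero = (~pos).sum()
        shrink = 1.0 - n_zero * p0
        if shrink <= 0:  # pathological: nearly everything is zero
            p0 = 0.5 / n_zero * props[pos].min()
            shrink = 1.0 - n_zero * p0
        out[i] = np.where(pos, props * shrink, p0)
    counts = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return table.with_counts(counts)


def clr_transform(table: AbundanceTable | pd.DataFrame) -> pd.DataFrame:
    """Centred log-ratio transform; rows of the result sum to zero."""
    df = table.counts if isinstance(table, AbundanceTable) else table
    X = df.to_numpy(dtype=float)
    if (X <= 0).any():
        raise ValueError("clr requires strictly positive entries; replace zeros first")
    logX = np.log(X)
    clr = logX - logX.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=df.index, columns=df.columns)


def median_binarize(table: AbundanceTable | pd.DataFrame) -> pd.DataFrame:
    """Binarize each taxon against its across-sample median.

    Entry 1 where the count strictly exceeds the taxon's median, else 0
    (ties at the median count as 0).
    """
    df = table.counts if isinstance(table, AbundanceTable) else table
    med = df.median(axis=0)
    return (df > med).astype(int)


def closed_geometric_mean(table: AbundanceTable | pd.DataFrame) -> pd.Series:
    """Compositional centre: per-taxon geometric mean, closed to sum one."""
    df = table.counts if isinstance(table, AbundanceTable) else table
    X = df.to_numpy(dtype=float)
    if (X <= 0).any():
        raise ValueError("geometric means require strictly positive entries")
    gm = np.exp(np.log(X).mean(axis=0))
    return pd.Series(gm / gm.sum(), index=df.columns)
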