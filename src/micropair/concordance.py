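"""Taxonomic and abundance concordance between sequencing platforms.

Answers, per taxonomic rank: how many taxa does each platform detect, how
many are shared (globally and per sample), and how well do the platforms
agree on abundance — Spearman correlation of compositional centres over
shared taxa, per-sample Spearman of counts, and Cohen's kappa of
median-binarized profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceTable, PairedStudy
from .prep import closed_geometric_mean, median_binarize


def cohens_kappa(a, b) -> float:
    """Unweighted Cohen's kappa, κ = (p_o − p_e) / (1 − p_e).

    Expected agreement p_e uses the marginal products.  Returns NaN when
    p_e = 1 (both raters constant on the same single category), where the
    statistic is undefined.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D sequences")
    n = a.size
    if n < 2:
        raise ValueError("kappa needs at least two observations")
    cats = np.unique(np.concatenate([a, b]))
    po = float(np.mean(a == b))
    pe = 0.0
    for c in cats:
        pe += float(np.mean(a == c)) * float(np.mean(b == c))
    if pe >= 1.0 - 1e-15:
        return float("nan")
    return (po - pe) / (1.0 - pe)


def kappa_se(a, b) -> float:
    """Large-sample standard error of kappa, √(p_o(1−p_o)) / ((1−p_e)√n)."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = a.size
    po = float(np.mean(a == b))
    cats = np.unique(np.concatenate([a, b]))
    pe = sum(float(np.mean(a == c)) * float(np.mean(b == c)) for c in cats)
    if pe >= 1.0 - 1e-15:
        return float("nan")
    return math_sqrt(po * (1.0 - po) / n) / (1.0 - pe)


def math_sqrt(x: float) -> float:
    return float(np.sqrt(x))


@dataclass
class OverlapSummary:
    """Global platform overlap at one rank (Venn accounting)."""

    rank: str
    n_16s: int
    n_shotgun: int
    n_shared: int
    only_16s: frozenset = field(default_factory=frozenset)
    only_shotgun: frozenset = field(default_factory=frozenset)
    shared: frozenset = field(default_factory=frozenset)

    @property
    def shared_over_16s(self) -> float:
        return 100.0 * self.n_shared / self.n_16s if self.n_16s else float("nan")

    @property
    def shared_over_shotgun(self) -> float:
        return 100.0 * self.n_shared / self.n_shotgun if self.n_shotgun else float("nan")


def global_overlap(paired: PairedStudy, rank: str) -> OverlapSummary:
    """Venn accounting of taxa detected (non-zero anywhere) per platform.

    Both tables must already be harmonised, aggregated to ``rank`` and
    stripped of unnamed taxa; detection is judged on raw counts, before any
    zero replacement.
    """
    det_16s = paired.amplicon.detected_taxa()
    det_sg = paired.shotgun.detected_taxa()
    shared = det_16s & det_sg
    return OverlapSummary(
        rank=rank,
        n_16s=len(det_16s),
        n_shotgun=len(det_sg),
        n_shared=len(shared),
        only_16s=frozenset(det_16s - det_sg),
        only_shotgun=frozenset(det_sg - det_16s),
        shared=frozenset(shared),
    )


def per_sample_overlap(
    paired: PairedStudy,
    rank: str,
    unambiguous_only: bool = True,
) -> pd.DataFrame:
    """Per-sample overlap and agreement statistics.

    For each sample: the taxa detected by both platforms, their share of the
    sample's detected 16S and shotgun taxa, the Spearman rho of counts over
    the shared taxa, and Cohen's kappa of the median-binarized profiles
    (medians computed per platform over the full table, then restricted to
    the sample's shared taxa).  At species rank, slash-ambiguous 16S taxa
    are excluded from rho/kappa when ``unambiguous_only`` (the default).
    Undefined statistics are reported as NaN.
    """
    am, sg = paired.amplicon, paired.shotgun
    common = [t for t in am.taxa if t in set(sg.taxa)]
    bin_am = median_binarize(am.counts[common]) if common else pd.DataFrame(index=am.counts.index)
    bin_sg = median_binarize(sg.counts[common]) if common else pd.DataFrame(index=sg.counts.index)

    if unambiguous_only and rank == "species":
        stat_taxa = [t for t in common if "/" not in t]
    else:
        stat_taxa = common
    stat_taxa_set = set(stat_taxa)

    rows = []
    for sid in paired.sample_ids:
        row_am = am.counts.loc[sid]
        row_sg = sg.counts.loc[sid]
        nz_am = set(row_am.index[row_am > 0])
        nz_sg = set(row_sg.index[row_sg > 0])
        shared = sorted((nz_am & nz_sg) & set(common))
        rho = kap = float("nan")
        stat_shared = [t for t in shared if t in stat_taxa_set]
        if len(stat_shared) >= 2:
            x = row_am[stat_shared].to_numpy(float)
            y = row_sg[stat_shared].to_numpy(float)
            if np.ptp(x) > 0 and np.ptp(y) > 0:
                rho = float(stats.spearmanr(x, y).statistic)
            kap = cohens_kappa(
                bin_am.loc[sid, stat_shared].to_numpy(),
                bin_sg.loc[sid, stat_shared].to_numpy(),
            )
        rows.append({
            "sample_id": sid,
            "n_shared": len(shared),
            "pct_of_16s": 100.0 * len(shared) / len(nz_am) if nz_am else float("nan"),
            "pct_of_shotgun": 100.0 * len(shared) / len(nz_sg) if nz_sg else float("nan"),
            "spearman": rho,
            "kappa": kap,
        })
    return pd.DataFrame(rows).set_index("sample_id")


def summarize_per_sample(per_sample: pd.DataFrame) -> pd.DataFrame:
    """Median / range / quartiles of the per-sample statistics.

    Samples with undefined rho or kappa are excluded from the summaries and
    tallied in an ``n_undefined`` column.
    """
    out = {}
    for col in ("n_shared", "pct_of_16s", "pct_of_shotgun", "spearman", "kappa"):
        vals = per_sample[col].dropna()
        out[col] = {
            "median": float(vals.median()) if len(vals) else float("nan"),
            "min": float(vals.min()) if len(vals) else float("nan"),
            "max": float(vals.max()) if len(vals) else float("nan"),
            "q1": float(vals.quantile(0.25)) if len(vals) else float("nan"),
            "q3": float(vals.quantile(0.75)) if len(vals) else float("nan"),
            "n_undefined": int(per_sample[col].isna().sum()),
        }
    return pd.DataFrame(out).T


def abundance_correlation(
    table_16s: AbundanceTable, table_shotgun: AbundanceTable
) -> tuple[float, float]:
    """Spearman rho (and p) between the platforms' compositional centres.

    Both tables must be zero-replaced; the centres (closed geometric means)
    are computed over the taxa shared by the two platforms.
    """
    shared = [t for t in table_16s.taxa if t in set(table_shotgun.taxa)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared taxa for a correlation")
    c16 = closed_geometric_mean(table_16s.counts[shared])
    csg = closed_geometric_mean(table_shotgun.counts[shared])
    res = stats.spearmanr(c16.to_numpy(), csg.to_numpy())
    return float(res.statistic), float(res.pvalue)


def top_prevalent(table: AbundanceTable, k: int) -> list[str]:
    """Top-``k`` taxa by closed geometric mean, ties broken by name."""
    centre = closed_geometric_mean(table)
    order = sorted(centre.index, key=lambda t: (-centre[t], t))
    if k > len(order):
        warnings.warn(
            f"requested top {k} but only {len(order)} taxa present", stacklevel=2
        )
        k = len(order)
    return order[:k]
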