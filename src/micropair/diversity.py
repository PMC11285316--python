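"""Alpha diversity and sparsity comparison between platforms.

Shannon entropy is compared after rarefying every sample to its platform's
minimum depth (so unequal library sizes do not masquerade as diversity
differences); Chao1 richness is computed on raw counts because it models
the unobserved tail through singletons and doubletons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceTable, PairedStudy


def rarefy(sample_counts, depth: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Subsample ``depth`` reads without replacement from one sample.

    Multivariate-hypergeometric draw over the taxon counts; reproducible
    under a fixed seed.
    """
    counts = np.asarray(sample_counts)
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("rarefaction requires integer counts")
        counts = np.round(counts).astype(np.int64)
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds sample total {total}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, depth)


def shannon(counts) -> float:
    """Shannon index H = −Σ p_j ln p_j (nats) over positive proportions."""
    x = np.asarray(counts, dtype=float)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("Shannon index undefined for an all-zero sample")
    p = x / x.sum()
    return float(-(p * np.log(p)).sum())


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton/doubleton frequencies.

    Bias-corrected form S_obs + F1(F1−1)/(2(F2+1)) by default (defined even
    when there are no doubletons); the classic S_obs + F1²/(2 F2) is
    available with ``bias_corrected=False``.
    """
    x = np.asarray(counts)
    if not np.issubdtype(x.dtype, np.integer):
        if not np.allclose(x, np.round(x)):
            raise ValueError("Chao1 requires raw integer counts")
        x = np.round(x).astype(np.int64)
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        raise ZeroDivisionError("classic Chao1 undefined with no doubletons")
    return s_obs + f1 * f1 / (2.0 * f2)


def alpha_table(
    table: AbundanceTable,
    rank: str,
    rarefaction_depth: int | None = None,
    seed: int = 0,
    n_draws: int = 1,
) -> pd.DataFrame:
    """Per-sample Shannon (rarefied) and Chao1 (raw) for one platform.

    ``rarefaction_depth`` defaults to the platform's minimum sample depth.
    A single seeded rarefaction draw is used by default; ``n_draws`` > 1
    averages Shannon over repeated draws.
    """
    totals = table.counts.sum(axis=1)
    if rarefaction_depth is None:
        rarefaction_depth = int(totals.min())
    rng = np.random.default_rng(seed)
    rows = []
    for sid in table.sample_ids:
        raw = table.counts.loc[sid].to_numpy()
        hs = [shannon(rarefy(raw, rarefaction_depth, rng)) for _ in range(n_draws)]
        rows.append({
            "sample_id": sid,
            "platform": table.platform,
            "rank": rank,
            "shannon": float(np.mean(hs)),
            "chao1": chao1(raw),
            "depth_used": rarefaction_depth,
        })
    return pd.DataFrame(rows).set_index("sample_id")


def compare_alpha(
    values_16s: pd.Series,
    values_shotgun: pd.Series,
    diagnosis: pd.Series | None = None,
    paired_test: bool = False,
) -> dict:
    """Compare paired alpha-diversity values across platforms.

    Wilcoxon rank-sum (unpaired, as conventional when contrasting the two
    platforms' distributions; ``paired_test=True`` switches to the
    signed-rank test), plus Spearman and Pearson correlations of the paired
    values overall and per diagnosis stratum.
    """
    x = values_16s.dropna()
    y = values_shotgun.loc[x.index].dropna()
    x = x.loc[y.index]
    if len(x) < 3:
        raise ValueError("need at least 3 paired samples")
    if paired_test:
        w = stats.wilcoxon(x.to_numpy(), y.to_numpy())
    else:
        w = stats.mannwhitneyu(x.to_numpy(), y.to_numpy(), alternative="two-sided")
    sp = stats.spearmanr(x.to_numpy(), y.to_numpy())
    pr = stats.pearsonr(x.to_numpy(), y.to_numpy())
    out = {
        "wilcoxon_p": float(w.pvalue),
        "spearman_rho": float(sp.statistic),
        "spearman_p": float(sp.pvalue),
        "pearson_r": float(pr.statistic),
        "pearson_p": float(pr.pvalue),
        "n": int(len(x)),
        "by_group": {},
    }
    if diagnosis is not None:
        for g, idx in diagnosis.loc[x.index].groupby(diagnosis.loc[x.index]).groups.items():
            if len(idx) >= 3:
                sg = stats.spearmanr(x.loc[idx].to_numpy(), y.loc[idx].to_numpy())
                out["by_group"][g] = {
                    "spearman_rho": float(sg.statistic),
                    "spearman_p": float(sg.pvalue),
                    "n": int(len(idx)),
                }
    return out


def sparsity_profile(table: AbundanceTable) -> pd.Series:
    """Per-sample fraction of zero entries."""
    return (table.counts == 0).mean(axis=1)


def compare_sparsity(paired: PairedStudy, alpha: float = 0.05 / 12) -> dict:
    """Platform and diagnosis-group sparsity contrasts.

    Wilcoxon rank-sum between the platforms' per-sample zero fractions and
    Kruskal–Wallis across the three diagnosis groups within each platform;
    ``alpha`` carries the Bonferroni-adjusted guidance threshold used when
    the group test is repeated across ranks and platforms.
    """
    z16 = sparsity_profile(paired.amplicon)
    zsg = sparsity_profile(paired.shotgun)
    w = stats.mannwhitneyu(z16.to_numpy(), zsg.to_numpy(), alternative="two-sided")
    out = {
        "median_zero_16s": float(z16.median()),
        "median_zero_shotgun": float(zsg.median()),
        "wilcoxon_p": float(w.pvalue),
        "bonferroni_alpha": alpha,
        "kruskal": {},
    }
    for name, z in (("16S", z16), ("shotgun", zsg)):
        groups = [z.loc[paired.diagnosis == g].to_numpy()
                  for g in paired.diagnosis.unique()]
        if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
            kw = stats.kruskal(*groups)
            out["kruskal"][name] = {
                "H": float(kw.statistic),
                "p": float(kw.pvalue),
                "significant": bool(kw.pvalue < alpha),
            }
    return out
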