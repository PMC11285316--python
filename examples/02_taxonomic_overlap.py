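"""Quantify which taxa the two platforms detect in common.

After harmonisation (synonym normalisation, ambiguity merging, dropping
accession-code-only taxa) the tables are aggregated per rank and the Venn
accounting is computed globally and per sample.
"""

from micropair import (
    GeneratorConfig, generate, global_overlap, per_sample_overlap,
    summarize_per_sample,
)
from micropair.pipeline import harmonize_study, prepare_rank
from micropair.prep import FilterSpec, genome_length_normalize

study, _ = generate(GeneratorConfig(seed=3))
study = harmonize_study(study)
norm = genome_length_normalize(study.shotgun)

for rank in ("species", "genus", "family"):
    data = prepare_rank(study, rank, FilterSpec(), norm)
    g = global_overlap(data.named, rank)
    per = per_sample_overlap(data.named, rank)
    s = summarize_per_sample(per)
    print(f"{rank:8s} 16S={g.n_16s:4d} shotgun={g.n_shotgun:4d} "
          f"shared={g.n_shared:4d} "
          f"({g.shared_over_16s:.1f}% of 16S, {g.shared_over_shotgun:.1f}% of shotgun) | "
          f"per-sample rho median {s.loc['spearman', 'median']:.2f}, "
          f"kappa median {s.loc['kappa', 'median']:.2f}")
# Shared percentages shrink toward species level while per-sample rank
# correlations of shared-taxon counts stay moderate-to-strong.
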