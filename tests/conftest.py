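import numpy as np
import pandas as pd
import pytest

from micropair.containers import AbundanceTable, Lineage, PairedStudy


def make_lineage(species, genus=None, family=None, named=True):
    genus = genus or species.split(" ")[0]
    family = family or f"{genus}aceae"
    return Lineage(ranks={
        "phylum": "Bacillota", "class": "Clostridia", "order": "Eubacteriales",
        "family": family, "genus": genus, "species": species,
    }, named=named)


def make_table(counts: dict, platform="shotgun", lineages=None, sample_ids=None,
               genome_lengths=None):
    """Build a small AbundanceTable from {taxon: [counts per sample]}."""
    df = pd.DataFrame(counts)
    df.index = sample_ids or [f"s{i}" for i in range(len(df))]
    lins = lineages or {t: make_lineage(t) for t in df.columns}
    gl = pd.Series(genome_lengths) if genome_lengths else None
    return AbundanceTable(counts=df.astype(float), lineages=lins,
                          platform=platform, genome_lengths=gl)


@pytest.fixture(scope="session")
def small_study():
    """Tiny paired synthetic study shared across tests."""
    from micropair.simulate import GeneratorConfig, generate

    cfg = GeneratorConfig(n_control=10, n_hrl=10, n_crc=10, n_species=60,
                          depth_shotgun=20_000, depth_16s=2_000, seed=11)
    study, truth = generate(cfg)
    return study, truth


@pytest.fixture(scope="session")
def harmonized_rank_data(small_study):
    """Species-level prepared data for the small study."""
    from micropair.pipeline import harmonize_study, prepare_rank
    from micropair.prep import FilterSpec, genome_length_normalize

    study, _ = small_study
    h = harmonize_study(study)
    norm = genome_length_normalize(h.shotgun)
    return prepare_rank(h, "species", FilterSpec(), norm)
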