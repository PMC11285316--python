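"""Synthetic paired-platform study generator.

Emulates one underlying stool community observed through two sequencing
platforms with realistic distortions: a log-normal latent community per
sample; planted diagnosis effects on a subset of signature species (HRL
gets half the CRC shift, encoding the adenoma–carcinoma continuum);
shotgun counts drawn multinomially with probabilities proportional to
latent abundance × genome length; 16S counts drawn over a detectable
species subset with probabilities proportional to latent abundance × 16S
copy number, perturbed by platform noise scaled by (1 − coupling), then
partially collapsed into slash-named ambiguity groups within genera;
extra 16S-only species under lineages absent from the shotgun table; and
a fraction of unnamed (accession-code) shotgun species.  Depths differ by
an order of magnitude, reproducing the sparsity ordering of real paired
data (16S much sparser than shotgun).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AbundanceTable, Lineage, PairedStudy, make_species_name


@dataclass
class GeneratorConfig:
    """Study-condition knobs for the paired-platform generator.

    Defaults mirror a three-arm colorectal screening cohort (51 controls,
    54 high-risk-lesion patients, 51 CRC cases) profiled at scaled-down
    depths of 50,000 (shotgun) and 5,000 (16S) mean reads per sample.
    """

    n_control: int = 51
    n_hrl: int = 54
    n_crc: int = 51
    n_species: int = 240
    species_per_genus: int = 3
    genera_per_family: int = 4
    depth_shotgun: float = 50_000.0
    depth_16s: float = 5_000.0
    depth_cv: float = 0.3            # lognormal sigma of per-sample depth
    detect_frac_16s: float = 0.6     # fraction of species detectable by 16S
    frac_16s_only: float = 0.15      # extra 16S-only species, rel. to n_species
    frac_unnamed_shotgun: float = 0.1
    ambiguity_rate: float = 0.2      # fraction of 16S species in slash groups
    coupling: float = 0.8            # 1 = identical latent signal on both platforms
    platform_noise_sd: float = 1.0   # log-sd of 16S noise at coupling = 0
    n_signature: int = 10
    effect_size: float = 1.0         # clr-scale shift for CRC; HRL gets half
    base_log_sd: float = 1.5         # spread of species mean log-abundances
    sample_log_sd: float = 1.0       # within-species across-sample log-sd
    genome_length_range: tuple[float, float] = (1.0e6, 8.0e6)
    copy_number_range: tuple[int, int] = (1, 12)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("detect_frac_16s", "frac_16s_only", "ambiguity_rate",
                     "coupling", "frac_unnamed_shotgun"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.detect_frac_16s == 0:
            raise ValueError("detect_frac_16s must be positive")
        if self.depth_shotgun <= 0 or self.depth_16s <= 0:
            raise ValueError("depths must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")


_PHYLA = ("Bacillota", "Bacteroidota", "Actinomycetota", "Pseudomonadota",
          "Verrucomicrobiota", "Euryarchaeota")


def _taxonomy(cfg: GeneratorConfig, rng: np.random.Generator,
              offset: int = 0, n: int | None = None,
              tag: str = "") -> list[Lineage]:
    """Deterministic synthetic taxonomy: species→genus→family→…→phylum."""
    n = cfg.n_species if n is None else n
    lineages = []
    for j in range(n):
        sp_idx = offset + j
        g_idx = sp_idx // cfg.species_per_genus
        f_idx = g_idx // cfg.genera_per_family
        genus = f"{tag}Genus{g_idx:04d}"
        lineages.append(Lineage(ranks={
            "phylum": _PHYLA[f_idx % len(_PHYLA)],
            "class": f"{tag}Class{f_idx // 4:03d}",
            "order": f"{tag}Order{f_idx // 2:03d}",
            "family": f"{tag}Family{f_idx:03d}",
            "genus": genus,
            "species": f"{genus} sp{sp_idx:04d}",
        }))
    return lineages


def generate(cfg: GeneratorConfig) -> tuple[PairedStudy, dict]:
    """Generate a paired study plus a truth record.

    The truth record stores the latent per-sample log-abundances, the
    planted signature species, the 16S detectability set, the ambiguity
    grouping, the 16S-only species and the unnamed shotgun species.
    """
    rng = np.random.default_rng(cfg.seed)
    labels = (["control"] * cfg.n_control + ["HRL"] * cfg.n_hrl
              + ["CRC"] * cfg.n_crc)
    sample_ids = [f"S{i:04d}" for i in range(len(labels))]
    diagnosis = pd.Series(labels, index=sample_ids, name="diagnosis")
    n_samples = len(sample_ids)

    # --- shared latent community --------------------------------------
    lineages = _taxonomy(cfg, rng)
    species = [lin.name for lin in lineages]
    mu = rng.normal(0.0, cfg.base_log_sd, size=cfg.n_species)
    latent = mu + rng.normal(0.0, cfg.sample_log_sd,
                             size=(n_samples, cfg.n_species))

    signature = sorted(rng.choice(cfg.n_species, size=cfg.n_signature,
                                  replace=False))
    shift = np.zeros(n_samples)
    shift[np.asarray(labels) == "HRL"] = 0.5 * cfg.effect_size
    shift[np.asarray(labels) == "CRC"] = cfg.effect_size
    latent[:, signature] += shift[:, None]

    # --- shotgun observation ------------------------------------------
    lengths = rng.uniform(*cfg.genome_length_range, size=cfg.n_species)
    n_unnamed = int(round(cfg.frac_unnamed_shotgun * cfg.n_species))
    unnamed_idx = sorted(rng.choice(cfg.n_species, size=n_unnamed,
                                    replace=False)) if n_unnamed else []
    sg_lineages: dict[str, Lineage] = {}
    sg_names = []
    for j, lin in enumerate(lineages):
        if j in set(unnamed_idx):
            name = f"MGYG-SYN-{j:05d}"
            ranks = dict(lin.ranks)
            ranks["species"] = name
            sg_lineages[name] = Lineage(ranks=ranks, named=False)
            sg_names.append(name)
        else:
            sg_lineages[lin.name] = lin
            sg_names.append(lin.name)

    depths_sg = rng.lognormal(np.log(cfg.depth_shotgun), cfg.depth_cv,
                              size=n_samples).astype(np.int64)
    w_sg = np.exp(latent) * lengths
    p_sg = w_sg / w_sg.sum(axis=1, keepdims=True)
    counts_sg = np.vstack([rng.multinomial(depths_sg[i], p_sg[i])
                           for i in range(n_samples)])
    shotgun = AbundanceTable(
        counts=pd.DataFrame(counts_sg, index=sample_ids, columns=sg_names),
        lineages=sg_lineages,
        platform="shotgun",
        genome_lengths=pd.Series(lengths, index=sg_names),
    )

    # --- 16S observation ----------------------------------------------
    n_detect = max(1, int(round(cfg.detect_frac_16s * cfg.n_species)))
    detect_idx = sorted(rng.choice(cfg.n_species, size=n_detect, replace=False))
    copy_numbers = rng.integers(cfg.copy_number_range[0],
                                cfg.copy_number_range[1] + 1,
                                size=cfg.n_species)
    noise_sd = cfg.platform_noise_sd * (1.0 - cfg.coupling)
    noise = (rng.normal(0.0, noise_sd, size=(n_samples, n_detect))
             if noise_sd > 0 else 0.0)
    w_16s = np.exp(latent[:, detect_idx] + noise) * copy_numbers[detect_idx]

    # 16S-only species under their own (distinct) lineages
    n_extra = int(round(cfg.frac_16s_only * cfg.n_species))
    extra_lineages = _taxonomy(cfg, rng, offset=0, n=n_extra, tag="Amp") \
        if n_extra else []
    if n_extra:
        mu_x = rng.normal(0.0, cfg.base_log_sd, size=n_extra)
        latent_x = mu_x + rng.normal(0.0, cfg.sample_log_sd,
                                     size=(n_samples, n_extra))
        w_16s = np.hstack([w_16s, np.exp(latent_x)])

    names_16s = [species[j] for j in detect_idx] + [l.name for l in extra_lineages]
    lineage_16s: dict[str, Lineage] = {species[j]: lineages[j] for j in detect_idx}
    lineage_16s.update({l.name: l for l in extra_lineages})

    depths_16s = rng.lognormal(np.log(cfg.depth_16s), cfg.depth_cv,
                               size=n_samples).astype(np.int64)
    p_16s = w_16s / w_16s.sum(axis=1, keepdims=True)
    counts_16s = np.vstack([rng.multinomial(depths_16s[i], p_16s[i])
                            for i in range(n_samples)])
    table_16s = AbundanceTable(
        counts=pd.DataFrame(counts_16s, index=sample_ids, columns=names_16s),
        lineages=lineage_16s,
        platform="16S",
    )

    # --- slash-ambiguity within genera --------------------------------
    ambiguity_map: dict[str, list[str]] = {}
    by_genus: dict[str, list[str]] = {}
    for name in names_16s[:n_detect]:  # only shared-taxonomy species
        by_genus.setdefault(lineage_16s[name].ranks["genus"], []).append(name)
    n_ambiguous_target = int(round(cfg.ambiguity_rate * n_detect))
    n_grouped = 0
    for genus in sorted(by_genus):
        members = by_genus[genus]
        if len(members) < 2 or n_grouped >= n_ambiguous_target:
            continue
        group = members[:2] if len(members) == 2 else members[:3]
        epithets = [m.split(" ", 1)[1] for m in group]
        slash = make_species_name(genus, epithets)
        ambiguity_map[slash] = group
        n_grouped += len(group)
    if ambiguity_map:
        counts = table_16s.counts
        new_cols = {}
        new_lins = dict(table_16s.lineages)
        merged = {m for grp in ambiguity_map.values() for m in grp}
        for t in counts.columns:
            if t not in merged:
                new_cols[t] = counts[t]
        for slash, group in ambiguity_map.items():
            new_cols[slash] = counts[group].sum(axis=1)
            base = table_16s.lineages[group[0]]
            ranks = dict(base.ranks)
            ranks["species"] = slash
            new_lins[slash] = Lineage(ranks=ranks, named=True)
            for m in group:
                new_lins.pop(m, None)
        table_16s = AbundanceTable(
            counts=pd.DataFrame(new_cols, index=sample_ids),
            lineages=new_lins, platform="16S",
        )

    study = PairedStudy(shotgun=shotgun, amplicon=table_16s, diagnosis=diagnosis)
    truth = {
        "config": asdict(cfg),
        "signature_species": [species[j] for j in signature],
        "detectable_16s": [species[j] for j in detect_idx],
        "ambiguity_map": ambiguity_map,
        "amplicon_only_species": [l.name for l in extra_lineages],
        "unnamed_shotgun": [sg_names[j] for j in unnamed_idx],
        "latent_log_abundance": latent.tolist(),
    }
    return study, truth


def write_study(study: PairedStudy, truth: dict, directory: str | Path) -> dict[str, Path]:
    """Write the study in the exact text dialects the pipeline consumes.

    Emits two abundance tables (samples × taxa, TSV), a combined lineage
    table, shotgun genome lengths, sample metadata with the diagnosis
    column, and a JSON truth manifest.  Byte-identical under a fixed
    generator seed.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "shotgun": directory / "shotgun_counts.tsv",
        "amplicon": directory / "16s_counts.tsv",
        "lineage": directory / "lineage.tsv",
        "genome_lengths": directory / "genome_lengths.tsv",
        "metadata": directory / "metadata.tsv",
        "truth": directory / "truth.json",
    }
    study.shotgun.counts.to_csv(paths["shotgun"], sep="\t", index_label="sample_id")
    study.amplicon.counts.to_csv(paths["amplicon"], sep="\t", index_label="sample_id")

    rows = []
    seen = set()
    for table in (study.shotgun, study.amplicon):
        for taxon, lin in table.lineages.items():
            if taxon in seen:
                continue
            seen.add(taxon)
            rows.append({
                "taxon_id": taxon,
                **{r: lin.ranks.get(r, "") for r in
                   ("phylum", "class", "order", "family", "genus", "species")},
                "named": str(lin.named).lower(),
            })
    pd.DataFrame(rows).sort_values("taxon_id").to_csv(
        paths["lineage"], sep="\t", index=False)

    assert study.shotgun.genome_lengths is not None
    study.shotgun.genome_lengths.rename("length_bp").to_csv(
        paths["genome_lengths"], sep="\t", index_label="taxon_id")
    study.diagnosis.rename("diagnosis").to_csv(
        paths["metadata"], sep="\t", index_label="sample_id")

    slim = {k: v for k, v in truth.items() if k != "latent_log_abundance"}
    paths["truth"].write_text(json.dumps(slim, indent=1, sort_keys=True))
    return paths
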