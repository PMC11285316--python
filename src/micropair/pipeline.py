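"""End-to-end orchestration of the paired-platform comparison.

Stage order: harmonize → prep → overlap/concordance → diversity →
ordination → machine learning.  Each stage is an importable function
operating on in-memory objects; :func:`run_all` chains them, writes every
report as plain delimited text under the output directory, and records a
run manifest (config snapshot, seeds, input digests, stage outputs,
package version).  Reruns with identical config and seeds are
bit-identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import (
    DEFAULT_UNNAMED_PREFIXES,
    AbundanceTable,
    PairedStudy,
)
from .concordance import (
    abundance_correlation,
    global_overlap,
    per_sample_overlap,
    summarize_per_sample,
    top_prevalent,
)
from .diversity import alpha_table, compare_alpha, compare_sparsity, sparsity_profile
from .io import load_study, read_synonym_map
from .ml import (
    DEFAULT_RF_NODE_GRID,
    DEFAULT_RF_TREES_GRID,
    DEFAULT_SVM_COST_GRID,
    DEFAULT_TOP_K_BY_RANK,
    SplitSpec,
    accuracy,
    agreement_kappa,
    bootstrap_ci,
    signature_compare,
    stratified_split,
    sv_agreement,
    tune_and_train,
)
from .ordination import (
    OrdinationResult,
    aitchison_distance,
    anosim,
    pairwise_permanova,
    pcoa,
    permanova,
    procrustes_r,
    rv_coefficient,
    rv_matrix,
    rv_matrix_pca,
)
from .prep import (
    FilterSpec,
    clr_transform,
    genome_length_normalize,
    prevalence_filter,
    replace_zeros,
)
from .simulate import GeneratorConfig, generate, write_study
from .taxonomy import (
    SynonymMap,
    aggregate_rank,
    exclude_unnamed,
    flag_unnamed,
    merge_ambiguous,
    normalize_names,
)

ANALYSIS_RANKS = ("species", "genus", "family")


@dataclass
class PipelineConfig:
    """Everything a full run needs; loadable from YAML."""

    output_dir: str = "micropair_out"
    seed: int = 0
    ranks: tuple[str, ...] = ANALYSIS_RANKS
    # input files (omit to simulate)
    shotgun_counts: str | None = None
    amplicon_counts: str | None = None
    lineage: str | None = None
    metadata: str | None = None
    genome_lengths: str | None = None
    synonyms: str | None = None
    transposed: bool = False
    simulate: dict = field(default_factory=dict)
    unnamed_prefixes: tuple[str, ...] = DEFAULT_UNNAMED_PREFIXES
    min_sample_fraction: float = 0.05
    min_rel_abundance: float = 0.001
    n_permutations: int = 999
    test_per_class: int = 10
    svm_cost_grid: tuple[float, ...] = DEFAULT_SVM_COST_GRID
    rf_trees_grid: tuple[int, ...] = DEFAULT_RF_TREES_GRID
    rf_node_grid: tuple[int, ...] = DEFAULT_RF_NODE_GRID
    bootstrap_n: int = 2000
    cv_folds: int = 5
    top_k_by_rank: dict = field(default_factory=lambda: dict(DEFAULT_TOP_K_BY_RANK))
    run_ml: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    @property
    def filter_spec(self) -> FilterSpec:
        return FilterSpec(self.min_sample_fraction, self.min_rel_abundance)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def obtain_study(config: PipelineConfig) -> tuple[PairedStudy, dict]:
    """Load the study from files, or simulate one when no files are given."""
    if config.shotgun_counts:
        study = load_study(
            config.shotgun_counts, config.amplicon_counts, config.lineage,
            config.metadata, config.genome_lengths, transposed=config.transposed,
        )
        return study, {}
    gen_cfg = GeneratorConfig(**{"seed": config.seed, **config.simulate})
    return generate(gen_cfg)


def harmonize_study(
    study: PairedStudy,
    synonyms: SynonymMap | None = None,
    unnamed_prefixes: tuple[str, ...] = DEFAULT_UNNAMED_PREFIXES,
) -> PairedStudy:
    """Name normalisation, 16S ambiguity merging and unnamed flagging."""
    sg, am = study.shotgun, study.amplicon
    if synonyms is not None:
        sg = normalize_names(sg, synonyms)
        am = normalize_names(am, synonyms)
    am = merge_ambiguous(am)
    sg = flag_unnamed(sg, unnamed_prefixes)
    am = flag_unnamed(am, unnamed_prefixes)
    return PairedStudy(shotgun=sg, amplicon=am, diagnosis=study.diagnosis)


@dataclass
class RankData:
    """All per-rank derived tables used by the downstream stages."""

    rank: str
    raw: PairedStudy               # aggregated raw counts (diversity, detection)
    named: PairedStudy             # raw, unnamed taxa excluded (overlap)
    filtered: PairedStudy          # prevalence-filtered (normalized shotgun)
    composition: PairedStudy       # zero-replaced closed compositions
    clr_shotgun: pd.DataFrame
    clr_amplicon: pd.DataFrame


def prepare_rank(
    study: PairedStudy,
    rank: str,
    filter_spec: FilterSpec,
    normalized_shotgun: AbundanceTable | None = None,
) -> RankData:
    """Aggregate to ``rank`` and run the compositional preparation chain."""
    raw = study.map_tables(lambda t: aggregate_rank(t, rank))
    named = raw.map_tables(exclude_unnamed)

    sg_src = normalized_shotgun if normalized_shotgun is not None else study.shotgun
    sg_agg = aggregate_rank(sg_src, rank)
    am_agg = raw.amplicon

    sg_f = prevalence_filter(sg_agg, filter_spec)
    am_f = prevalence_filter(am_agg, filter_spec)
    filtered = PairedStudy(shotgun=sg_f, amplicon=am_f, diagnosis=study.diagnosis)
    composition = filtered.map_tables(replace_zeros)
    return RankData(
        rank=rank,
        raw=raw,
        named=named,
        filtered=filtered,
        composition=composition,
        clr_shotgun=clr_transform(composition.shotgun),
        clr_amplicon=clr_transform(composition.amplicon),
    )


def analyze_overlap(data: RankData) -> dict:
    """Global and per-sample overlap plus abundance concordance."""
    summary = global_overlap(data.named, data.rank)
    per_sample = per_sample_overlap(data.named, data.rank)
    named_comp = data.composition.map_tables(exclude_unnamed)
    try:
        rho, pval = abundance_correlation(named_comp.amplicon, named_comp.shotgun)
    except ValueError:
        rho, pval = float("nan"), float("nan")
    return {
        "global": summary,
        "per_sample": per_sample,
        "per_sample_summary": summarize_per_sample(per_sample),
        "centre_spearman_rho": rho,
        "centre_spearman_p": pval,
        "top_prevalent_shotgun": top_prevalent(
            data.composition.shotgun, min(50, data.composition.shotgun.n_taxa)),
        "top_prevalent_16s": top_prevalent(
            data.composition.amplicon, min(50, data.composition.amplicon.n_taxa)),
    }


def analyze_diversity(data: RankData, seed: int) -> dict:
    """Alpha diversity (rarefied Shannon, raw Chao1) and sparsity."""
    a_sg = alpha_table(data.raw.shotgun, data.rank, seed=seed)
    a_am = alpha_table(data.raw.amplicon, data.rank, seed=seed + 1)
    alpha = pd.concat([a_sg, a_am])
    shannon_cmp = compare_alpha(a_am["shannon"], a_sg["shannon"],
                                data.raw.diagnosis)
    chao1_cmp = compare_alpha(a_am["chao1"], a_sg["chao1"], data.raw.diagnosis)
    return {
        "alpha": alpha,
        "shannon_comparison": shannon_cmp,
        "chao1_comparison": chao1_cmp,
        "sparsity_raw": compare_sparsity(data.raw),
        "sparsity_filtered": compare_sparsity(data.filtered),
    }


def analyze_ordination(data: RankData, n_perm: int, seed: int) -> dict:
    """PCoA, group tests and cross-platform structure comparison."""
    out: dict = {}
    ordinations: dict[str, OrdinationResult] = {}
    for name, clr in (("shotgun", data.clr_shotgun), ("16S", data.clr_amplicon)):
        d = aitchison_distance(clr)
        ord_res = pcoa(d)
        groups = data.raw.diagnosis.loc[clr.index]
        r, p_r = anosim(d, groups, n_perm=n_perm, seed=seed)
        f, p_f = permanova(d, groups, n_perm=n_perm, seed=seed)
        pw = pairwise_permanova(d, groups, n_perm=n_perm, seed=seed)
        ordinations[name] = ord_res
        out[name] = {
            "pcoa": ord_res,
            "anosim_R": r, "anosim_p": p_r,
            "permanova_F": f, "permanova_p": p_f,
            "pairwise_permanova": pw,
        }
    pr, p_pr = procrustes_r(ordinations["shotgun"], ordinations["16S"],
                            n_perm=n_perm, seed=seed)
    rv, p_rv = rv_coefficient(ordinations["shotgun"], ordinations["16S"],
                              n_perm=n_perm, seed=seed)
    out["procrustes_r"] = pr
    out["procrustes_p"] = p_pr
    out["rv"] = rv
    out["rv_p"] = p_rv
    out["ordinations"] = ordinations
    return out


def analyze_ml(
    data: RankData,
    train_ids: list,
    test_ids: list,
    config: PipelineConfig,
) -> dict:
    """Train SVM and RF per platform and compare them across platforms."""
    out: dict = {"models": {}}
    diag = data.raw.diagnosis
    for platform, clr in (("shotgun", data.clr_shotgun), ("16S", data.clr_amplicon)):
        for algo in ("SVM", "RF"):
            model = tune_and_train(
                clr.loc[train_ids], diag, algo,
                platform=platform, rank=data.rank,
                svm_cost_grid=config.svm_cost_grid,
                rf_trees_grid=config.rf_trees_grid,
                rf_node_grid=config.rf_node_grid,
                cv_folds=config.cv_folds,
                seed=config.seed,
                test_table=clr.loc[test_ids],
            )
            out["models"][(platform, algo)] = model

    rows = []
    for (platform, algo), model in out["models"].items():
        fit_acc = accuracy(model.fitted_labels, diag.loc[train_ids])
        test_acc = accuracy(model.test_predictions, diag.loc[test_ids])
        lo, hi = bootstrap_ci(model.test_predictions, diag.loc[test_ids],
                              n_boot=config.bootstrap_n, seed=config.seed)
        rows.append({
            "rank": data.rank, "platform": platform, "algorithm": algo,
            "cv_accuracy": 100.0 * model.cv_accuracy,
            "fitted_accuracy": fit_acc, "test_accuracy": test_acc,
            "test_ci_lo": lo, "test_ci_hi": hi,
            **{f"hp_{k}": v for k, v in model.hyperparameters.items()},
        })
    out["accuracy_table"] = pd.DataFrame(rows)

    agree_rows, sig_rows = [], []
    top_k = config.top_k_by_rank.get(data.rank, 50)
    for algo in ("SVM", "RF"):
        m_sg = out["models"][("shotgun", algo)]
        m_am = out["models"][("16S", algo)]
        for stage, a, b in (
            ("training", m_sg.fitted_labels, m_am.fitted_labels),
            ("test", m_sg.test_predictions, m_am.test_predictions),
        ):
            ak = agreement_kappa(a.to_numpy(), b.to_numpy())
            agree_rows.append({"rank": data.rank, "algorithm": algo,
                               "stage": stage, **ak})
        sig = signature_compare(m_sg.importance, m_am.importance,
                                top_k=top_k, n_boot=config.bootstrap_n,
                                seed=config.seed)
        sig_rows.append({
            "rank": data.rank, "algorithm": algo,
            "kendall_tau": sig.tau, "tau_lo": sig.tau_ci[0],
            "tau_hi": sig.tau_ci[1], "tau_p": sig.tau_p,
            "top_k": sig.top_k, "top_k_agreement_pct": sig.top_k_agreement,
        })
        if algo == "SVM":
            out["sv_agreement"] = sv_agreement(m_sg, m_am)
    out["agreement_table"] = pd.DataFrame(agree_rows)
    out["signature_table"] = pd.DataFrame(sig_rows)
    return out


def _write_tsv(df: pd.DataFrame, path: Path, **kwargs) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", **kwargs)
    return path


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage and write reports plus a run manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "seeds": {"master": config.seed},
        "inputs": {},
        "outputs": {},
    }
    for key in ("shotgun_counts", "amplicon_counts", "lineage", "metadata",
                "genome_lengths", "synonyms"):
        path = getattr(config, key)
        if path:
            manifest["inputs"][key] = _sha256(Path(path))

    study, truth = obtain_study(config)
    synonyms = read_synonym_map(config.synonyms) if config.synonyms else None
    study = harmonize_study(study, synonyms, config.unnamed_prefixes)

    normalized_sg = None
    if study.shotgun.genome_lengths is not None:
        normalized_sg = genome_length_normalize(study.shotgun)

    results: dict = {"ranks": {}}
    split_spec = SplitSpec(test_per_class=config.test_per_class, seed=config.seed)
    train_ids, test_ids = stratified_split(study.diagnosis, split_spec)
    manifest["seeds"]["split"] = config.seed
    results["split"] = {"train": train_ids, "test": test_ids}

    pcoa_by_dataset: dict[str, OrdinationResult] = {}
    for rank in config.ranks:
        data = prepare_rank(study, rank, config.filter_spec, normalized_sg)
        rank_out: dict = {"data": data}

        ov = analyze_overlap(data)
        rank_out["overlap"] = ov
        g = ov["global"]
        _write_tsv(pd.DataFrame([{
            "rank": rank, "n_16s": g.n_16s, "n_shotgun": g.n_shotgun,
            "n_shared": g.n_shared, "shared_over_16s": g.shared_over_16s,
            "shared_over_shotgun": g.shared_over_shotgun,
            "centre_spearman_rho": ov["centre_spearman_rho"],
        }]), outdir / f"overlap_{rank}.tsv", index=False)
        _write_tsv(ov["per_sample"], outdir / f"overlap_per_sample_{rank}.tsv")

        dv = analyze_diversity(data, seed=config.seed)
        rank_out["diversity"] = dv
        _write_tsv(dv["alpha"], outdir / f"alpha_{rank}.tsv")

        od = analyze_ordination(data, n_perm=config.n_permutations,
                                seed=config.seed)
        rank_out["ordination"] = od
        for platform in ("shotgun", "16S"):
            pcoa_by_dataset[f"{platform}_{rank}"] = od[platform]["pcoa"]
        _write_tsv(pd.DataFrame([{
            "rank": rank,
            "anosim_R_shotgun": od["shotgun"]["anosim_R"],
            "anosim_R_16s": od["16S"]["anosim_R"],
            "permanova_p_shotgun": od["shotgun"]["permanova_p"],
            "permanova_p_16s": od["16S"]["permanova_p"],
            "procrustes_r": od["procrustes_r"], "procrustes_p": od["procrustes_p"],
            "rv": od["rv"], "rv_p": od["rv_p"],
        }]), outdir / f"beta_{rank}.tsv", index=False)

        if config.run_ml:
            ml = analyze_ml(data, train_ids, test_ids, config)
            rank_out["ml"] = ml
            _write_tsv(ml["accuracy_table"], outdir / f"ml_accuracy_{rank}.tsv",
                       index=False)
            _write_tsv(ml["agreement_table"], outdir / f"ml_agreement_{rank}.tsv",
                       index=False)
            _write_tsv(ml["signature_table"], outdir / f"ml_signature_{rank}.tsv",
                       index=False)
        results["ranks"][rank] = rank_out

    K = rv_matrix(pcoa_by_dataset)
    proj, eigvals = rv_matrix_pca(K)
    results["rv_matrix"] = K
    results["rv_pca"] = proj
    _write_tsv(K, outdir / "rv_matrix.tsv")
    _write_tsv(proj, outdir / "rv_pca.tsv")

    manifest["outputs"] = sorted(str(p.name) for p in outdir.glob("*.tsv"))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True))
    results["manifest"] = manifest
    return results
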