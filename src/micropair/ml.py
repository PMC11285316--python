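"""Cross-platform machine-learning model concordance.

Diagnosis classifiers (one-vs-one linear SVM and random forest) are
trained per platform and rank on clr-transformed abundances, with the same
stratified train/test split reused everywhere so that model fits, test
predictions, support vectors and importance rankings are compared over
identical sample sets.  Concordance is quantified with accuracy (plus
percentile-bootstrap CIs), prediction agreement, Cohen's kappa, support-
vector matching, Kendall tau-b of importance rankings and top-k signature
agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .containers import DIAGNOSIS_CLASSES
from .concordance import cohens_kappa

CLASS_PAIRS = tuple(combinations(DIAGNOSIS_CLASSES, 2))

DEFAULT_SVM_COST_GRID = (0.1, 1.0, 10.0, 100.0)
DEFAULT_RF_TREES_GRID = (500, 1000, 2000)
DEFAULT_RF_NODE_GRID = (2, 3)


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/test split: ``test_per_class`` samples held out."""

    test_per_class: int = 10
    seed: int = 0


@dataclass
class ModelResult:
    """Fitted classifier with everything needed for concordance checks."""

    platform: str
    rank: str
    algorithm: str  # "SVM" | "RF"
    hyperparameters: dict
    cv_accuracy: float
    fitted_labels: pd.Series        # predictions on the training samples
    test_predictions: pd.Series
    importance: pd.Series           # per-taxon, higher = more important
    decision_values: pd.DataFrame | None = None   # test × class pairs (SVM)
    support_vectors: pd.DataFrame | None = None   # train × class pairs, bool (SVM)
    per_pair_importance: pd.DataFrame | None = None  # taxa × class pairs (SVM)


def stratified_split(labels: pd.Series, spec: SplitSpec) -> tuple[list, list]:
    """Hold out exactly ``test_per_class`` samples per class, seeded.

    The split is deterministic under the seed and is intended to be reused
    for both platforms and all ranks, so every cross-platform comparison
    runs over identical train and test sets.
    """
    rng = np.random.default_rng(spec.seed)
    test: list = []
    for cls in sorted(labels.unique()):
        members = list(labels.index[labels == cls])
        if len(members) < spec.test_per_class:
            raise ValueError(
                f"class {cls!r} has {len(members)} samples, "
                f"fewer than test_per_class={spec.test_per_class}"
            )
        chosen = rng.choice(len(members), size=spec.test_per_class, replace=False)
        test.extend(members[i] for i in sorted(chosen))
    test_set = set(test)
    train = [s for s in labels.index if s not in test_set]
    return train, test


class OneVsOneSVM:
    """Three binary linear SVMs combined by majority vote.

    One model per class pair (control–HRL, control–CRC, HRL–CRC).  A
    cyclic three-way vote tie is broken by the largest summed absolute
    decision value over the binary models involving each candidate class,
    then by class order control < HRL < CRC.
    """

    def __init__(self, cost: float = 1.0):
        self.cost = cost
        self.models: dict[tuple[str, str], SVC] = {}
        self.classes_ = DIAGNOSIS_CLASSES

    def fit(self, X: pd.DataFrame, y: pd.Series) -> "OneVsOneSVM":
        self.feature_names_ = list(X.columns)
        self.train_index_ = list(X.index)
        for pair in CLASS_PAIRS:
            mask = y.isin(pair)
            svc = SVC(kernel="linear", C=self.cost)
            svc.fit(X.loc[mask].to_numpy(), y.loc[mask].to_numpy())
            self.models[pair] = svc
        return self

    def decision_values(self, X: pd.DataFrame) -> pd.DataFrame:
        cols = {}
        for pair, svc in self.models.items():
            cols["_vs_".join(pair)] = svc.decision_function(X.to_numpy())
        return pd.DataFrame(cols, index=X.index)

    def predict(self, X: pd.DataFrame) -> pd.Series:
        winners = {}
        margins = {}
        for pair, svc in self.models.items():
            d = svc.decision_function(X.to_numpy())
            # decision > 0 → svc.classes_[1]
            w = np.where(d > 0, svc.classes_[1], svc.classes_[0])
            winners[pair] = w
            margins[pair] = np.abs(d)
        preds = []
        for i in range(X.shape[0]):
            votes: dict[str, int] = {c: 0 for c in self.classes_}
            score: dict[str, float] = {c: 0.0 for c in self.classes_}
            for pair in CLASS_PAIRS:
                win = winners[pair][i]
                votes[win] += 1
                for c in pair:
                    score[c] += margins[pair][i]
            best = max(votes.values())
            tied = [c for c in self.classes_ if votes[c] == best]
            if len(tied) == 1:
                preds.append(tied[0])
            else:
                tied.sort(key=lambda c: (-score[c], self.classes_.index(c)))
                preds.append(tied[0])
        return pd.Series(preds, index=X.index)

    def support_vector_table(self) -> pd.DataFrame:
        out = pd.DataFrame(False, index=self.train_index_,
                           columns=["_vs_".join(p) for p in CLASS_PAIRS])
        for pair, svc in self.models.items():
            # indices are into the pair-restricted training subset
            pair_index = [s for s in self.train_index_
                          if s in set(self._pair_members[pair])]
            for idx in svc.support_:
                out.loc[pair_index[idx], "_vs_".join(pair)] = True
        return out

    def fit_with_members(self, X: pd.DataFrame, y: pd.Series) -> "OneVsOneSVM":
        self._pair_members = {
            pair: list(y.index[y.isin(pair)]) for pair in CLASS_PAIRS
        }
        return self.fit(X, y)

    def importance_table(self) -> pd.DataFrame:
        cols = {}
        for pair, svc in self.models.items():
            cols["_vs_".join(pair)] = np.abs(svc.coef_[0])
        return pd.DataFrame(cols, index=self.feature_names_)


def _cv_folds(y: pd.Series, n_folds: int, seed: int):
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y.to_numpy()))


def _cv_accuracy_svm(X: pd.DataFrame, y: pd.Series, cost: float,
                     folds) -> float:
    accs = []
    for tr, te in folds:
        model = OneVsOneSVM(cost=cost).fit(X.iloc[tr], y.iloc[tr])
        pred = model.predict(X.iloc[te])
        accs.append(float(np.mean(pred.to_numpy() == y.iloc[te].to_numpy())))
    return float(np.mean(accs))


def _cv_accuracy_rf(X: pd.DataFrame, y: pd.Series, n_trees: int, node: int,
                    folds, seed: int) -> float:
    accs = []
    for tr, te in folds:
        rf = RandomForestClassifier(n_estimators=n_trees, min_samples_leaf=node,
                                    random_state=seed, n_jobs=1)
        rf.fit(X.iloc[tr].to_numpy(), y.iloc[tr].to_numpy())
        pred = rf.predict(X.iloc[te].to_numpy())
        accs.append(float(np.mean(pred == y.iloc[te].to_numpy())))
    return float(np.mean(accs))


def tune_and_train(
    clr_table: pd.DataFrame,
    labels: pd.Series,
    algorithm: str,
    platform: str = "",
    rank: str = "",
    svm_cost_grid=DEFAULT_SVM_COST_GRID,
    rf_trees_grid=DEFAULT_RF_TREES_GRID,
    rf_node_grid=DEFAULT_RF_NODE_GRID,
    cv_folds: int = 5,
    seed: int = 0,
    test_table: pd.DataFrame | None = None,
    permutation_importance: bool = False,
) -> ModelResult:
    """Grid-search hyperparameters by 5-fold CV accuracy, refit, predict.

    Ties in CV accuracy resolve to the smallest cost (SVM) or the fewest
    trees then smallest node size (RF).  ``clr_table`` holds training
    samples only; ``test_table`` (optional) is scored with the refit model.
    """
    y = labels.loc[clr_table.index]
    folds = _cv_folds(y, cv_folds, seed)
    algorithm = algorithm.upper()

    if algorithm == "SVM":
        results = [( _cv_accuracy_svm(clr_table, y, c, folds), c)
                   for c in svm_cost_grid]
        best_acc = max(a for a, _ in results)
        best_cost = min(c for a, c in results if a >= best_acc - 1e-12)
        model = OneVsOneSVM(cost=best_cost).fit_with_members(clr_table, y)
        fitted = model.predict(clr_table)
        test_pred = model.predict(test_table) if test_table is not None else pd.Series(dtype=object)
        per_pair = model.importance_table()
        importance = per_pair.abs().mean(axis=1)
        return ModelResult(
            platform=platform, rank=rank, algorithm="SVM",
            hyperparameters={"cost": best_cost},
            cv_accuracy=best_acc,
            fitted_labels=fitted,
            test_predictions=test_pred,
            importance=importance,
            decision_values=(model.decision_values(test_table)
                             if test_table is not None else None),
            support_vectors=model.support_vector_table(),
            per_pair_importance=per_pair,
        )

    if algorithm == "RF":
        results = []
        for n_trees in rf_trees_grid:
            for node in rf_node_grid:
                acc = _cv_accuracy_rf(clr_table, y, n_trees, node, folds, seed)
                results.append((acc, n_trees, node))
        best_acc = max(a for a, _, _ in results)
        best = min(((t, m) for a, t, m in results if a >= best_acc - 1e-12))
        rf = RandomForestClassifier(n_estimators=best[0], min_samples_leaf=best[1],
                                    random_state=seed, n_jobs=1)
        rf.fit(clr_table.to_numpy(), y.to_numpy())
        fitted = pd.Series(rf.predict(clr_table.to_numpy()), index=clr_table.index)
        test_pred = (pd.Series(rf.predict(test_table.to_numpy()), index=test_table.index)
                     if test_table is not None else pd.Series(dtype=object))
        if permutation_importance:
            from sklearn.inspection import permutation_importance as _pi
            imp = _pi(rf, clr_table.to_numpy(), y.to_numpy(), n_repeats=10,
                      random_state=seed).importances_mean
        else:
            imp = rf.feature_importances_
        return ModelResult(
            platform=platform, rank=rank, algorithm="RF",
            hyperparameters={"n_trees": best[0], "min_node": best[1]},
            cv_accuracy=best_acc,
            fitted_labels=fitted,
            test_predictions=test_pred,
            importance=pd.Series(imp, index=clr_table.columns),
        )

    raise ValueError(f"unknown algorithm {algorithm!r}")


def accuracy(predictions, truth) -> float:
    """Percentage of correct predictions, 100 · correct / total."""
    p = np.asarray(predictions)
    t = np.asarray(truth)
    if p.size == 0:
        raise ValueError("empty prediction set")
    if p.shape != t.shape:
        raise ValueError("length mismatch")
    return 100.0 * float(np.mean(p == t))


def bootstrap_ci(predictions, truth, n_boot: int = 2000, seed: int = 0,
                 level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI for accuracy over resampled test indices."""
    p = np.asarray(predictions)
    t = np.asarray(truth)
    rng = np.random.default_rng(seed)
    n = p.size
    idx = rng.integers(0, n, size=(n_boot, n))
    accs = 100.0 * (p[idx] == t[idx]).mean(axis=1)
    lo, hi = np.percentile(accs, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return float(lo), float(hi)


def agreement(pred_a, pred_b) -> float:
    """Proportion of identical predictions between two platforms."""
    a = np.asarray(pred_a)
    b = np.asarray(pred_b)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    return float(np.mean(a == b))


def agreement_kappa(pred_a, pred_b, level: float = 0.95) -> dict:
    """Agreement plus Cohen's kappa with an asymptotic CI."""
    a = np.asarray(pred_a)
    b = np.asarray(pred_b)
    kap = cohens_kappa(a, b)
    n = a.size
    po = float(np.mean(a == b))
    cats = np.unique(np.concatenate([a, b]))
    pe = sum(float(np.mean(a == c)) * float(np.mean(b == c)) for c in cats)
    if np.isnan(kap):
        se = float("nan")
    else:
        se = np.sqrt(po * (1 - po) / n) / (1 - pe)
    z = stats.norm.ppf((1 + level) / 2)
    return {
        "agreement": po,
        "kappa": kap,
        "kappa_lo": kap - z * se if not np.isnan(kap) else float("nan"),
        "kappa_hi": kap + z * se if not np.isnan(kap) else float("nan"),
    }


def sv_agreement(model_a: ModelResult, model_b: ModelResult) -> pd.DataFrame:
    """Support-vector membership agreement per binary sub-model."""
    if model_a.algorithm != "SVM" or model_b.algorithm != "SVM":
        raise ValueError("support-vector comparison requires SVM models")
    sva, svb = model_a.support_vectors, model_b.support_vectors
    if list(sva.index) != list(svb.index):
        raise ValueError("models were not trained on the same training samples")
    rows = []
    for col in sva.columns:
        a = sva[col].to_numpy().astype(int)
        b = svb[col].to_numpy().astype(int)
        rows.append({
            "pair": col,
            "agreement": float(np.mean(a == b)),
            "kappa": cohens_kappa(a, b),
        })
    return pd.DataFrame(rows).set_index("pair")


def importance_ranking(model: ModelResult) -> list[str]:
    """Taxa sorted by importance, descending; ties broken by name."""
    imp = model.importance
    return sorted(imp.index, key=lambda t: (-imp[t], t))


@dataclass
class SignatureComparison:
    """Similarity of two importance rankings over shared taxa."""

    tau: float
    tau_ci: tuple[float, float]
    tau_p: float
    top_k: int
    top_k_agreement: float          # percent
    shared_top_taxa: frozenset


def signature_compare(
    importance_a: pd.Series,
    importance_b: pd.Series,
    top_k: int = 50,
    n_boot: int = 2000,
    seed: int = 0,
) -> SignatureComparison:
    """Kendall tau-b of importance ranks and top-k signature agreement.

    Both importance vectors are restricted to the taxa present in both
    models; tau-b is computed on those importances (rank-equivalent), its
    CI by bootstrap resampling of taxa; top-k agreement is the percentage
    of the two top-k sets that coincide.
    """
    shared = [t for t in importance_a.index if t in set(importance_b.index)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared taxa")
    a = importance_a.loc[shared].to_numpy(float)
    b = importance_b.loc[shared].to_numpy(float)
    kt = stats.kendalltau(a, b)
    rng = np.random.default_rng(seed)
    taus = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(shared), size=len(shared))
        if np.ptp(a[idx]) == 0 or np.ptp(b[idx]) == 0:
            continue
        taus.append(stats.kendalltau(a[idx], b[idx]).statistic)
    if taus:
        lo, hi = np.percentile(taus, [2.5, 97.5])
    else:
        lo = hi = float("nan")

    k = min(top_k, len(shared))
    top_a = set(sorted(shared, key=lambda t: (-importance_a[t], t))[:k])
    top_b = set(sorted(shared, key=lambda t: (-importance_b[t], t))[:k])
    inter = top_a & top_b
    return SignatureComparison(
        tau=float(kt.statistic),
        tau_ci=(float(lo), float(hi)),
        tau_p=float(kt.pvalue),
        top_k=k,
        top_k_agreement=100.0 * len(inter) / k,
        shared_top_taxa=frozenset(inter),
    )


#: Default signature sizes by rank (top-50 species, top-20 genera, top-10 families).
DEFAULT_TOP_K_BY_RANK = {"species": 50, "genus": 20, "family": 10}
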