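"""Beta-diversity and cross-platform ordination comparison.

The beta-diversity metric is the Aitchison distance (Euclidean distance
between clr-transformed compositions).  Group structure is tested with
ANOSIM and PERMANOVA (label permutation, seeded); cross-platform structure
is compared with symmetric Procrustes (r = √(1 − m²)) and the co-inertia
RV coefficient, and the six ordinations (2 platforms × 3 ranks) are
summarised by the spectral projection of their pairwise RV matrix K:
K = UΛ²Uᵀ, plotted coordinates UΛ.

ANOSIM and PERMANOVA are computed in-package with vectorised label
permutations so that every permutation stream is explicitly seeded and
large calibration sweeps stay cheap; scikit-bio's implementations back
them as cross-checks in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa
from statsmodels.stats.multitest import multipletests


@dataclass
class OrdinationResult:
    """PCoA output: sample coordinates, eigenvalues, % explained."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    explained: np.ndarray  # percent per axis

    @property
    def sample_ids(self) -> list[str]:
        return list(self.coordinates.index)


def aitchison_distance(clr_matrix: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Euclidean distance over clr-transformed rows."""
    X = clr_matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("clr matrix contains NaN")
    d = squareform(pdist(X, metric="euclidean"))
    return DistanceMatrix(d, ids=[str(i) for i in clr_matrix.index])


def pcoa(d: DistanceMatrix, negative_eig_tol: float = 1e-8) -> OrdinationResult:
    """Principal coordinates analysis (Gower double-centering).

    Euclidean-derived input (as Aitchison distances are) cannot produce
    genuinely negative eigenvalues, so any beyond floating-point noise is
    treated as an error rather than silently corrected.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _skbio_pcoa(d, method="eigh", number_of_dimensions=0)
    eig = res.eigvals.to_numpy()
    scale = max(abs(eig).max(), 1.0)
    if eig.min() < -negative_eig_tol * scale:
        raise ValueError(f"distance matrix is non-Euclidean (min eigenvalue {eig.min():.3g})")
    keep = np.flatnonzero(eig > negative_eig_tol * scale)
    coords = res.samples.iloc[:, keep].copy()
    coords.index = list(d.ids)
    return OrdinationResult(
        coordinates=coords,
        eigenvalues=eig[keep],
        explained=100.0 * res.proportion_explained.to_numpy()[keep],
    )


def _condensed_and_labels(d: DistanceMatrix, groups) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    dm = np.asarray(d.data if isinstance(d, DistanceMatrix) else d, dtype=float)
    n = dm.shape[0]
    labels = np.asarray(list(groups))
    if labels.size != n:
        raise ValueError("grouping length must match the distance matrix")
    vals, counts = np.unique(labels, return_counts=True)
    if len(vals) < 2:
        raise ValueError("need at least two groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least two samples")
    iu = np.triu_indices(n, 1)
    return dm[iu], labels, np.vstack(iu)


def _perm_labels(labels: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    reps = np.tile(labels, (n_perm, 1))
    return rng.permuted(reps, axis=1)


def anosim(d: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """ANOSIM R and permutation p-value.

    R = (mean between-group rank − mean within-group rank) / (n(n−1)/4),
    ranks taken over all pairwise distances.  The p-value counts
    permutations with R at least as large as observed, with the observed
    statistic included in the null set: p = (b + 1)/(m + 1).
    """
    dv, labels, pairs = _condensed_and_labels(d, groups)
    ranks = stats.rankdata(dv)
    n = labels.size
    denom = n * (n - 1) / 4.0

    def r_stat(li: np.ndarray, lj: np.ndarray) -> np.ndarray:
        within = li == lj
        rw = (ranks * within).sum(axis=-1) / within.sum(axis=-1)
        rb = (ranks * ~within).sum(axis=-1) / (~within).sum(axis=-1)
        return (rb - rw) / denom

    r_obs = float(r_stat(labels[pairs[0]], labels[pairs[1]]))
    rng = np.random.default_rng(seed)
    perms = _perm_labels(labels, n_perm, rng)
    r_null = r_stat(perms[:, pairs[0]], perms[:, pairs[1]])
    p = (np.count_nonzero(r_null >= r_obs - 1e-12) + 1) / (n_perm + 1)
    return r_obs, float(p)


def permanova(d: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """PERMANOVA pseudo-F and permutation p-value.

    pseudo-F = ((SS_T − SS_W)/(k − 1)) / (SS_W/(n − k)) with sums of
    squares computed from squared pairwise distances; p by label
    permutation with the (b+1)/(m+1) convention.
    """
    if n_perm < 99:
        warnings.warn("fewer than 99 permutations gives poor p-value resolution",
                      stacklevel=2)
    dv, labels, pairs = _condensed_and_labels(d, groups)
    d2 = dv ** 2
    n = labels.size
    values, counts = np.unique(labels, return_counts=True)
    k = len(values)
    ss_total = d2.sum() / n

    def ss_within(li: np.ndarray, lj: np.ndarray) -> np.ndarray:
        ssw = 0.0
        for g, ng in zip(values, counts):
            mask = (li == g) & (lj == g)
            ssw = ssw + (d2 * mask).sum(axis=-1) / ng
        return ssw

    def pseudo_f(ssw):
        return ((ss_total - ssw) / (k - 1)) / (ssw / (n - k))

    f_obs = float(pseudo_f(ss_within(labels[pairs[0]], labels[pairs[1]])))
    rng = np.random.default_rng(seed)
    perms = _perm_labels(labels, n_perm, rng)
    f_null = pseudo_f(ss_within(perms[:, pairs[0]], perms[:, pairs[1]]))
    p = (np.count_nonzero(f_null >= f_obs - 1e-12) + 1) / (n_perm + 1)
    return f_obs, float(p)


def pairwise_permanova(
    d: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0
) -> pd.DataFrame:
    """All pairwise group PERMANOVAs with Benjamini–Hochberg adjustment."""
    labels = pd.Series(list(groups), index=list(d.ids))
    values = sorted(labels.unique())
    rows = []
    rng = np.random.default_rng(seed)
    for i, a in enumerate(values):
        for b in values[i + 1:]:
            ids = list(labels.index[labels.isin([a, b])])
            sub = d.filter(ids)
            f, p = permanova(sub, labels.loc[ids], n_perm=n_perm,
                             seed=int(rng.integers(2**31 - 1)))
            rows.append({"group_a": a, "group_b": b, "pseudo_F": f, "p": p})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df


def _positive_axes(ord_res: OrdinationResult) -> np.ndarray:
    return ord_res.coordinates.to_numpy(dtype=float)


def procrustes_r(
    a: OrdinationResult | np.ndarray,
    b: OrdinationResult | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Symmetric Procrustes correlation between two configurations.

    Both configurations are truncated to their common number of
    positive-eigenvalue axes, optimally translated, scaled and rotated;
    r = √(1 − m²) where m² is the standardized residual sum of squares.
    Significance by row-permutation of the second configuration.
    """
    X = _positive_axes(a) if isinstance(a, OrdinationResult) else np.asarray(a, float)
    Y = _positive_axes(b) if isinstance(b, OrdinationResult) else np.asarray(b, float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("configurations must share samples")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    k = min(X.shape[1], Y.shape[1])
    X, Y = X[:, :k], Y[:, :k]

    def one_r(Yp: np.ndarray) -> float:
        _, _, m2 = _scipy_procrustes(X, Yp)
        return float(np.sqrt(max(0.0, 1.0 - m2)))

    r_obs = one_r(Y)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        r_p = one_r(Y[rng.permutation(Y.shape[0])])
        if r_p >= r_obs - 1e-12:
            count += 1
    return r_obs, (count + 1) / (n_perm + 1)


def rv_coefficient(
    x, y, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Co-inertia RV coefficient between two sample-matched matrices.

    RV = tr(XᵀY YᵀX) / √( tr((XᵀX)²) · tr((YᵀY)²) ) on column-centred
    matrices; equals 1 for identical configurations up to rotation/scale
    and 0 under zero cross-covariance.  Significance by row permutation.
    """
    X = np.asarray(x.coordinates if isinstance(x, OrdinationResult) else x, float)
    Y = np.asarray(y.coordinates if isinstance(y, OrdinationResult) else y, float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("matrices must share samples")
    X = X - X.mean(axis=0)
    Y = Y - Y.mean(axis=0)
    Wx = X @ X.T
    Wy = Y @ Y.T
    nx = float((Wx * Wx).sum())
    ny = float((Wy * Wy).sum())
    if nx <= 0 or ny <= 0:
        raise ValueError("zero-variance configuration")

    def one_rv(Wyp: np.ndarray) -> float:
        return float((Wx * Wyp).sum() / np.sqrt(nx * ny))

    rv_obs = one_rv(Wy)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(Y.shape[0])
        if one_rv(Wy[np.ix_(perm, perm)]) >= rv_obs - 1e-12:
            count += 1
    return rv_obs, (count + 1) / (n_perm + 1)


def rv_matrix(configs: dict[str, np.ndarray | pd.DataFrame | OrdinationResult]) -> pd.DataFrame:
    """Pairwise RV matrix K over named configurations; diagonal fixed to 1."""
    labels = list(configs)
    K = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            rv, _ = rv_coefficient(configs[a], configs[b], n_perm=0)
            K.loc[a, b] = K.loc[b, a] = rv
    return K.clip(0.0, 1.0)


def rv_matrix_pca(K: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Spectral projection of the RV matrix: K = UΛ²Uᵀ, coordinates UΛ.

    Eigenvalues are sorted descending; small negatives (> −1e-10·scale)
    are clipped to zero, a substantially indefinite K is rejected.
    """
    M = np.asarray(K, dtype=float)
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("K must be symmetric")
    lam, U = np.linalg.eigh(M)
    order = np.argsort(lam)[::-1]
    lam, U = lam[order], U[:, order]
    scale = max(abs(lam).max(), 1.0)
    if lam.min() < -1e-10 * scale:
        raise ValueError(f"K substantially indefinite (min eigenvalue {lam.min():.3g})")
    lam = np.clip(lam, 0.0, None)
    proj = U * np.sqrt(lam)
    cols = [f"PC{i + 1}" for i in range(proj.shape[1])]
    labels = list(K.index) if isinstance(K, pd.DataFrame) else list(range(M.shape[0]))
    return pd.DataFrame(proj, index=labels, columns=cols), lam
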