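"""Genetic-structure analysis: BIC-based cluster-number selection and DAPC.

Genotypes are encoded as a per-(locus, allele) dosage matrix, reduced by
PCA, and either clustered (k-means over a K range, scored by BIC) or
discriminated (linear discriminant analysis on group labels -- DAPC).  The
number of retained principal components can be chosen by the alpha-score:
observed leave-one-out reassignment success minus its expectation under
permuted labels, which penalizes overfitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .types import PopulationSample


def genotypes_to_matrix(
    populations: list[PopulationSample], scale: bool = True
) -> tuple[np.ndarray, list[str], list[str]]:
    """Allele-dosage encoding: one column per (locus, allele), values 0/1/2.

    Missing genotypes are imputed with the column mean; columns are centred
    and (optionally) scaled.  Returns (matrix, specimen ids, column names).
    """
    specimens = [s for p in populations for s in p.specimens]
    if len(specimens) < 2:
        raise ValueError("need >= 2 specimens for a genotype matrix")
    alleles: dict[str, set[int]] = {}
    for s in specimens:
        for g in s.genotypes:
            alleles.setdefault(g.locus, set()).update(g.alleles)
    columns = [
        (locus, a) for locus in sorted(alleles) for a in sorted(alleles[locus])
    ]
    if not columns:
        raise ValueError("no scored alleles in any specimen")
    col_index = {c: j for j, c in enumerate(columns)}
    mat = np.full((len(specimens), len(columns)), np.nan)
    for i, s in enumerate(specimens):
        for g in s.genotypes:
            if g.is_missing:
                continue
            for locus_allele in ((g.locus, a) for a in alleles[g.locus]):
                mat[i, col_index[locus_allele]] = 0.0
            for a in g.alleles:
                mat[i, col_index[(g.locus, a)]] += 1.0
    col_means = np.nanmean(mat, axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    idx = np.where(np.isnan(mat))
    mat[idx] = np.take(col_means, idx[1])
    if np.allclose(mat.std(axis=0), 0.0):
        raise ValueError("monomorphic panel: dosage matrix has no variance")
    mat = mat - mat.mean(axis=0)
    if scale:
        sd = mat.std(axis=0)
        sd[sd == 0] = 1.0
        mat = mat / sd
    ids = [s.id for s in specimens]
    names = [f"{locus}.{a}" for locus, a in columns]
    return mat, ids, names


@dataclass
class BICScan:
    bic: dict[int, float]
    best_k: int
    assignments: dict[int, np.ndarray] = field(default_factory=dict)


def find_clusters(
    matrix: np.ndarray,
    k_range: range | list[int],
    n_pcs: int | None = None,
    seed: int = 0,
    n_restarts: int = 10,
) -> BICScan:
    """K-means over principal components, scored by BIC(K).

    BIC(K) = n ln(W_K / n) + K ln(n), with W_K the total within-cluster sum
    of squares.  Each K uses ``n_restarts`` seeded k-means starts and keeps
    the best inertia.  K values above n are skipped.
    """
    n = matrix.shape[0]
    pcs = _pca_scores(matrix, n_pcs)
    bic: dict[int, float] = {}
    assignments: dict[int, np.ndarray] = {}
    for k in k_range:
        if k < 1 or k > n:
            continue
        if k == 1:
            w = float(((pcs - pcs.mean(axis=0)) ** 2).sum())
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(pcs)
            w = float(km.inertia_)
            labels = km.labels_
        w = max(w, 1e-12)
        bic[k] = n * np.log(w / n) + k * np.log(n)
        assignments[k] = labels
    if not bic:
        raise ValueError("no feasible K in range")
    best = min(bic, key=bic.get)
    return BICScan(bic=bic, best_k=best, assignments=assignments)


def _pca_scores(matrix: np.ndarray, n_pcs: int | None) -> np.ndarray:
    n_max = min(matrix.shape)
    k = n_max if n_pcs is None else min(n_pcs, n_max)
    return PCA(n_components=k).fit_transform(matrix)


@dataclass
class ClusterResult:
    groups: list[str]
    retained_pcs: int
    coordinates: np.ndarray  # discriminant coordinates, specimens x axes
    centroids: dict[str, np.ndarray]
    membership: np.ndarray  # specimens x groups, rows sum to 1
    group_order: list[str]


def dapc(
    matrix: np.ndarray,
    groups: list[str],
    n_pcs: int,
    n_da: int | None = None,
) -> ClusterResult:
    """Discriminant analysis of principal components.

    PCA reduces the dosage matrix to ``n_pcs`` axes; LDA on the group labels
    yields discriminant coordinates, group centroids and per-specimen
    membership probabilities.  ``n_pcs`` must stay below n - (number of
    groups) to avoid a perfectly overfitted discriminant space.
    """
    groups = list(groups)
    n = matrix.shape[0]
    if len(groups) != n:
        raise ValueError("one group label per specimen required")
    uniq = sorted(set(groups))
    if len(uniq) < 2:
        raise ValueError("DAPC needs >= 2 groups")
    if any(groups.count(g) < 2 for g in uniq):
        raise ValueError("every group needs >= 2 members")
    if n_pcs >= n - len(uniq):
        raise ValueError(
            f"n_pcs={n_pcs} too large for n={n} with {len(uniq)} groups (overfitting guard)"
        )
    pcs = _pca_scores(matrix, n_pcs)
    n_axes = min(n_da or len(uniq) - 1, len(uniq) - 1)
    lda = LinearDiscriminantAnalysis(n_components=n_axes)
    coords = lda.fit_transform(pcs, groups)
    if np.allclose(coords.std(axis=0), 0.0):
        raise ValueError("degenerate discriminant axis: groups are indistinguishable")
    membership = lda.predict_proba(pcs)
    centroids = {
        g: coords[np.array(groups) == g].mean(axis=0) for g in uniq
    }
    return ClusterResult(
        groups=groups, retained_pcs=n_pcs, coordinates=coords,
        centroids=centroids, membership=membership, group_order=list(lda.classes_),
    )


def _loo_reassignment_rate(pcs: np.ndarray, labels: np.ndarray) -> float:
    """Leave-one-out LDA self-assignment success rate."""
    n = pcs.shape[0]
    hits = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        train_labels = labels[mask]
        if len(set(train_labels)) < 2:
            continue
        lda = LinearDiscriminantAnalysis()
        lda.fit(pcs[mask], train_labels)
        hits += lda.predict(pcs[i : i + 1])[0] == labels[i]
    return hits / n


@dataclass
class AlphaScoreResult:
    curve: dict[int, float]
    best_n_pcs: int


def alpha_score(
    matrix: np.ndarray,
    groups: list[str],
    n_pcs_grid: list[int],
    n_perm: int = 10,
    seed: int = 0,
) -> AlphaScoreResult:
    """Alpha-score PC selection: true minus chance reassignment success.

    For each candidate number of PCs, alpha = (leave-one-out reassignment
    rate with the real labels) - (mean rate over ``n_perm`` random label
    permutations).  The grid point with the largest alpha wins.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(groups)
    n = matrix.shape[0]
    rng = np.random.default_rng(seed)
    curve: dict[int, float] = {}
    for n_pcs in n_pcs_grid:
        if n_pcs >= n - len(set(groups)):
            continue
        pcs = _pca_scores(matrix, n_pcs)
        observed = _loo_reassignment_rate(pcs, labels)
        null = np.mean(
            [_loo_reassignment_rate(pcs, rng.permutation(labels)) for _ in range(n_perm)]
        )
        curve[n_pcs] = observed - float(null)
    if not curve:
        raise ValueError("no grid point inside the overfitting guard")
    best = max(curve, key=curve.get)
    return AlphaScoreResult(curve=curve, best_n_pcs=best)
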